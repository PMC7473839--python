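"""Core containers shared by every pipeline stage.

The pipeline revolves around three objects: a :class:`Pedigree` (family
structure with affection status), a :class:`MarkerPanel` (genetic map with
allele frequencies) and a :class:`GenotypeTable` (individuals x markers
biallelic calls).  A :class:`DiseaseModel` parameterises the single-locus
disease model used both for simulation and for parametric linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

# Affection codes follow the PLINK PED dialect.
UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2

MALE = 1
FEMALE = 2

MISSING = -1  # missing allele code in GenotypeTable


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


class PedigreeLoopError(PedigreeError):
    """Pedigree contains a loop (inbreeding or inter-marriage).

    Exact likelihood routines here require loop-free pedigrees; break the
    loop manually (duplicate one loop individual and split their genotype
    data) before calling linkage functions.
    """


@dataclass
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: int
    affection: int = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """A validated, acyclic pedigree.

    Parents must either both be present or both be absent (founder); a
    referenced parent must exist, fathers must be male and mothers female.
    """

    def __init__(self, individuals: Iterable[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        for ind in self.individuals.values():
            g.add_node(ind.iid)
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"{ind.iid!r}: one parent given but not the other")
            for pid, want_sex, label in (
                    (ind.father, MALE, "father"), (ind.mother, FEMALE, "mother")):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise PedigreeError(f"{ind.iid!r}: {label} {pid!r} not in pedigree")
                if self.individuals[pid].sex != want_sex:
                    raise PedigreeError(
                        f"{ind.iid!r}: {label} {pid!r} has wrong sex")
                g.add_edge(pid, ind.iid)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError("pedigree contains an ancestry cycle")
        self._dag = g

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    @property
    def members(self) -> list[str]:
        return list(self.individuals)

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if not ind.is_founder]

    def topological_order(self) -> list[str]:
        """Members ordered parents-before-children (stable for ties)."""
        order = list(nx.lexicographical_topological_sort(
            self._dag, key=lambda x: list(self.individuals).index(x)))
        return order

    def children_of(self, iid: str) -> list[str]:
        return [c for c, ind in self.individuals.items()
                if ind.father == iid or ind.mother == iid]

    def has_loops(self) -> bool:
        """True if the marriage graph contains a cycle.

        Nodes are individuals plus one node per mating pair; a cycle in this
        undirected graph corresponds to a pedigree loop (consanguineous
        mating or two families joined by more than one marriage).
        """
        g = nx.Graph()
        for ind in self.individuals.values():
            if ind.father is None:
                continue
            couple = ("couple", ind.father, ind.mother)
            g.add_edge(couple, ind.father)
            g.add_edge(couple, ind.mother)
            g.add_edge(couple, ind.iid)
        try:
            nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return False
        return True

    def affected_members(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.affection == AFFECTED]


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease model.

    ``penetrance_by_genotype`` gives P(affected | 0, 1, 2 copies of the risk
    allele); index 0 is the phenocopy rate.
    """

    risk_allele_freq: float
    penetrance_by_genotype: tuple[float, float, float]

    def __post_init__(self):
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError("risk_allele_freq must be in [0, 1]")
        for f in self.penetrance_by_genotype:
            if not 0.0 <= f <= 1.0:
                raise ValueError("penetrances must be in [0, 1]")

    @classmethod
    def dominant(cls, risk_allele_freq: float = 0.01, penetrance: float = 0.99,
                 phenocopy: float = 0.005) -> "DiseaseModel":
        """Dominant model used for the linkage scan (q=0.01, f=0.99).

        The phenocopy rate defaults to a small non-zero value so that
        affection status in simulated families is informative but not a
        perfect carrier indicator.
        """
        return cls(risk_allele_freq, (phenocopy, penetrance, penetrance))

    @property
    def is_dominant(self) -> bool:
        f = self.penetrance_by_genotype
        return f[1] == f[2]


class MarkerPanel:
    """Ordered marker map: id, chromosome, bp, cM, alleles, founder MAF.

    Positions must be strictly increasing within each chromosome; allele
    frequencies (of allele ``a2``) must lie strictly inside (0, 1).
    """

    COLUMNS = ["marker", "chrom", "bp", "cm", "a1", "a2", "freq"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        table = table[self.COLUMNS].reset_index(drop=True)
        for chrom, sub in table.groupby("chrom", sort=False):
            bad = sub["marker"][sub["bp"].diff().fillna(1) <= 0]
            if len(bad):
                raise ValueError(
                    f"marker {bad.iloc[0]!r} on chrom {chrom} out of order "
                    "(bp positions must strictly increase)")
            bad = sub["marker"][sub["cm"].diff().fillna(1) < 0]
            if len(bad):
                raise ValueError(
                    f"marker {bad.iloc[0]!r} on chrom {chrom}: cM positions decrease")
        if ((table["freq"] <= 0) | (table["freq"] >= 1)).any():
            bad = table.loc[(table["freq"] <= 0) | (table["freq"] >= 1), "marker"]
            raise ValueError(f"marker {bad.iloc[0]!r}: frequency outside (0, 1)")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def index_of(self, marker: str) -> int:
        idx = self.table.index[self.table["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in panel")
        return int(idx[0])

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def subset(self, indices: Sequence[int]) -> "MarkerPanel":
        return MarkerPanel(self.table.iloc[list(indices)].reset_index(drop=True))

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())


class GenotypeTable:
    """Unordered biallelic calls for individuals x markers.

    ``alleles`` has shape (n_individuals, n_markers, 2) with values 0/1
    indexing the marker's (a1, a2) alleles, or :data:`MISSING`.  A call is
    either fully observed or fully missing.
    """

    def __init__(self, ids: Sequence[str], markers: Sequence[str],
                 alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(ids), len(markers), 2):
            raise ValueError("alleles shape does not match ids x markers")
        valid = np.isin(alleles, (MISSING, 0, 1))
        if not valid.all():
            raise ValueError("allele codes must be 0, 1 or missing (-1)")
        half = (alleles == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype calls are not allowed")
        self.ids = list(ids)
        self.markers = list(markers)
        self.alleles = alleles
        self._row = {iid: k for k, iid in enumerate(self.ids)}
        self._col = {m: k for k, m in enumerate(self.markers)}

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, iid: str) -> int:
        return self._row[iid]

    def col(self, marker: str) -> int:
        if marker not in self._col:
            raise KeyError(f"marker {marker!r} not in genotype table")
        return self._col[marker]

    def genotype(self, iid: str, marker: str) -> tuple[int, int]:
        a = self.alleles[self._row[iid], self.col(marker)]
        return int(a[0]), int(a[1])

    def dosage(self) -> np.ndarray:
        """Count of allele a2 per call (float, NaN where missing)."""
        d = self.alleles.sum(axis=2).astype(float)
        d[self.alleles[:, :, 0] == MISSING] = np.nan
        return d

    def missing_mask(self) -> np.ndarray:
        return self.alleles[:, :, 0] == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-individual fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        rows = [self._row[i] for i in ids]
        return GenotypeTable(list(ids), self.markers, self.alleles[rows])

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeTable":
        cols = [self.col(m) for m in markers]
        return GenotypeTable(self.ids, list(markers), self.alleles[:, cols])

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.ids, self.markers, self.alleles.copy())
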