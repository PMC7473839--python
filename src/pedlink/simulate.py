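"""Synthetic data generation for the whole pipeline.

Generates (i) multi-generation pedigrees segregating a planted dominant
disease locus, (ii) gene-dropped SNP genotypes linked to that locus,
(iii) WES-like rare-variant calls shared among sequenced family members and
(iv) multi-cohort case-control exome-chip data with a planted gene-level
signal on the liability scale.

All randomness flows from the mandatory ``SimConfig.seed``; each operation
derives its own child generator so that outputs are bit-reproducible and
independent of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import (AFFECTED, FEMALE, MALE, MISSING, UNAFFECTED, UNKNOWN,
                    DiseaseModel, GenotypeTable, Individual, MarkerPanel,
                    Pedigree)

# ----------------------------------------------------------------------
# map functions


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for a genetic distance in cM (no interference)."""
    return 0.5 * (1.0 - math.exp(-0.02 * d_cm))


def haldane_cm(theta: float) -> float:
    """Inverse Haldane map: distance in cM for a recombination fraction."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must be in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * theta)


# ----------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PedigreeTemplate:
    """Three-generation outbred family template.

    A founding couple has ``n_children`` children; the first ``n_married``
    of them each marry an unrelated founder and each such couple has the
    sibship size given by ``grandchildren``.  The default yields a
    20-member family (2 + 6 + 6 spouses + 6 grandchildren), comparable in
    size and depth to clinically ascertained multiplex ADHD families.
    """

    n_children: int = 6
    n_married: int = 6
    grandchildren: tuple[int, ...] = (1, 1, 1, 1, 1, 1)

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("template must define at least 2 generations")
        if self.n_married > self.n_children:
            raise ValueError("cannot marry more children than exist")
        if len(self.grandchildren) != self.n_married:
            raise ValueError("grandchildren must give one sibship per married child")
        if any(g < 0 for g in self.grandchildren):
            raise ValueError("sibship sizes must be non-negative")

    @property
    def n_members(self) -> int:
        return 2 + self.n_children + self.n_married + sum(self.grandchildren)


@dataclass(frozen=True)
class MarkerSpec:
    """Genome-wide marker panel specification."""

    n_chromosomes: int = 2
    markers_per_chromosome: int = 35
    spacing_cm: float = 2.0
    spacing_bp: int = 2_000_000
    maf_low: float = 0.2
    maf_high: float = 0.5
    ld_block_size: int = 1      # 1 = linkage-equilibrium founders
    ld_pool_size: int = 8       # haplotype pool per block when blocks > 1

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("marker counts must be positive")
        if not 0 < self.maf_low <= self.maf_high < 1:
            raise ValueError("MAF bounds must satisfy 0 < low <= high < 1")


@dataclass(frozen=True)
class WESSpec:
    """WES-like variant call specification for one family."""

    n_shared_in_region: int = 3     # rare variants shared by all sequenced members, near the locus
    n_shared_outside: int = 2       # shared rare variants elsewhere in the genome
    n_private_per_sample: int = 10  # private noise variants per sequenced individual
    depth_mean: float = 85.0        # mean read depth (matches deep exome coverage)
    depth_min: int = 5
    maf_rare_max: float = 0.005
    frac_common_noise: float = 0.3  # fraction of noise variants with MAF >= 1%
    frac_unknown_maf: float = 0.2   # fraction of rare variants absent from the MAF reference
    region_genes: tuple[str, ...] = ()  # gene names for the in-region shared variants


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("cohorts need at least 2 cases and 2 controls")


# Four-country adult case-control sample emulated by default.
DEFAULT_COHORTS = (
    CohortSpec("Spain", 615, 932),
    CohortSpec("Norway", 597, 2598),
    CohortSpec("Germany", 340, 2286),
    CohortSpec("Netherlands", 294, 1703),
)


@dataclass(frozen=True)
class CohortPanelSpec:
    """Gene/SNP panel shared by all cohorts (an exome-chip in miniature)."""

    n_genes: int = 400
    min_snps_per_gene: int = 2
    max_snps_per_gene: int = 12
    maf_low: float = 0.01
    maf_high: float = 0.4
    ld_rho: float = 0.4       # AR(1) haplotype correlation within a gene
    prevalence: float = 0.05  # population rate of the (persistent) phenotype


@dataclass(frozen=True)
class SimConfig:
    """Full synthetic study configuration.  ``seed`` is mandatory."""

    seed: int
    template: PedigreeTemplate = PedigreeTemplate()
    markers: MarkerSpec = MarkerSpec()
    disease: DiseaseModel = field(default_factory=DiseaseModel.dominant)
    planted_chrom: int = 1
    planted_marker: int = 17        # index within the planted chromosome
    plant_founder_carrier: bool = True
    unknown_fraction: float = 0.10
    min_affected: int = 8           # ascertainment: multiplex families only
    genotype_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    wes: WESSpec = WESSpec()
    cohorts: tuple[CohortSpec, ...] = DEFAULT_COHORTS
    cohort_panel: CohortPanelSpec = CohortPanelSpec()
    effect_genes: dict = field(default_factory=dict)  # gene -> liability beta per SNP

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if not 0 <= self.unknown_fraction < 1:
            raise ValueError("unknown_fraction must be in [0, 1)")
        if not (0 <= self.planted_marker < self.markers.markers_per_chromosome):
            raise ValueError("planted locus must lie on the marker map")
        if not (1 <= self.planted_chrom <= self.markers.n_chromosomes):
            raise ValueError("planted chromosome outside the simulated genome")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


# stage tags for child generators
_STAGE_PED, _STAGE_DROP, _STAGE_WES, _STAGE_COHORT = 11, 12, 13, 14


# ----------------------------------------------------------------------
# pedigree + disease locus


@dataclass
class FamilySim:
    """A simulated family: structure plus disease-locus ground truth.

    ``founder_disease_alleles`` maps founder id to its ordered pair of
    disease alleles (0 = wild-type, 1 = risk).  ``locus_bits`` maps
    (individual, side) -> which parental haplotype was transmitted at the
    planted locus (side 0 = from father, 1 = from mother); marker
    gene-dropping conditions on these bits so affection status and marker
    transmission stay linked.
    """

    pedigree: Pedigree
    founder_disease_alleles: dict
    locus_bits: dict
    disease_genotypes: dict  # iid -> ordered (paternal, maternal) risk-allele pair

    def carrier_counts(self) -> dict:
        return {i: int(sum(g)) for i, g in self.disease_genotypes.items()}

    def truth_frame(self) -> pd.DataFrame:
        rows = [{"iid": i,
                 "risk_copies": int(sum(self.disease_genotypes[i])),
                 "affection": self.pedigree[i].affection}
                for i in self.pedigree.members]
        return pd.DataFrame(rows)


def build_template_pedigree(template: PedigreeTemplate) -> list[Individual]:
    """Individuals (without affection) for the structured family template."""
    inds = [Individual("F1", None, None, MALE), Individual("F2", None, None, FEMALE)]
    for k in range(template.n_children):
        sex = MALE if k % 2 == 0 else FEMALE
        inds.append(Individual(f"C{k + 1}", "F1", "F2", sex))
    gid = 0
    for k in range(template.n_married):
        child = f"C{k + 1}"
        child_sex = MALE if k % 2 == 0 else FEMALE
        spouse_sex = FEMALE if child_sex == MALE else MALE
        spouse = f"S{k + 1}"
        inds.append(Individual(spouse, None, None, spouse_sex))
        father, mother = (child, spouse) if child_sex == MALE else (spouse, child)
        for _ in range(template.grandchildren[k]):
            gid += 1
            sex = MALE if gid % 2 == 0 else FEMALE
            inds.append(Individual(f"G{gid}", father, mother, sex))
    return inds


def _drop_disease(pedigree: Pedigree, model: DiseaseModel, rng,
                  plant_founder_carrier: bool):
    q = model.risk_allele_freq
    founder_alleles, locus_bits, genotypes = {}, {}, {}
    for iid in pedigree.founders:
        founder_alleles[iid] = (int(rng.random() < q), int(rng.random() < q))
    if plant_founder_carrier:
        # a heterozygous carrier: a homozygous founder would make every
        # descendant a carrier and leave the trait uninformative for linkage
        first = pedigree.founders[0]
        founder_alleles[first] = (1, 0)
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        if ind.is_founder:
            genotypes[iid] = founder_alleles[iid]
        else:
            bits = (int(rng.integers(2)), int(rng.integers(2)))
            locus_bits[(iid, 0)] = bits[0]
            locus_bits[(iid, 1)] = bits[1]
            genotypes[iid] = (genotypes[ind.father][bits[0]],
                              genotypes[ind.mother][bits[1]])
    return founder_alleles, locus_bits, genotypes


def simulate_pedigree(config: SimConfig,
                      individuals: list[Individual] | None = None) -> FamilySim:
    """Simulate a family: structure, disease-locus gene drop, affection.

    Affection is sampled from the penetrance of each member's simulated
    disease genotype; a random ``unknown_fraction`` of members is then
    masked to unknown status.  Families are ascertained the way multiplex
    study families are: simulation repeats until at least ``min_affected``
    members are affected (set ``min_affected=0`` to disable).
    """
    rng = config.rng(_STAGE_PED)
    base = individuals if individuals is not None else build_template_pedigree(
        config.template)
    pen = config.disease.penetrance_by_genotype
    for attempt in range(10_000):
        pedigree = Pedigree([replace(i, affection=UNKNOWN) for i in base])
        fa, bits, geno = _drop_disease(pedigree, config.disease, rng,
                                       config.plant_founder_carrier)
        n_affected = 0
        for iid in pedigree.members:
            copies = sum(geno[iid])
            affected = rng.random() < pen[copies]
            pedigree[iid].affection = AFFECTED if affected else UNAFFECTED
            n_affected += int(affected)
        if n_affected >= config.min_affected:
            break
    else:
        raise RuntimeError(
            "could not ascertain a family meeting min_affected; "
            "lower min_affected or raise penetrance")
    if config.unknown_fraction > 0:
        mask = rng.random(len(pedigree)) < config.unknown_fraction
        for iid, hide in zip(pedigree.members, mask):
            if hide:
                pedigree[iid].affection = UNKNOWN
    return FamilySim(pedigree, fa, bits, geno)


# ----------------------------------------------------------------------
# marker panel + gene dropping


def build_marker_panel(spec: MarkerSpec, rng=None,
                       seed: int | None = None) -> MarkerPanel:
    """Evenly spaced biallelic panel with founder MAFs drawn uniformly."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, spec.n_chromosomes + 1):
        for k in range(spec.markers_per_chromosome):
            rows.append({
                "marker": f"rs{c}_{k + 1}",
                "chrom": c,
                "bp": (k + 1) * spec.spacing_bp,
                "cm": k * spec.spacing_cm,
                "a1": "A",
                "a2": "C",
                "freq": float(rng.uniform(spec.maf_low, spec.maf_high)),
            })
    return MarkerPanel(pd.DataFrame(rows))


def _founder_haplotypes(n_haplotypes: int, freqs: np.ndarray, spec: MarkerSpec,
                        rng) -> np.ndarray:
    """Founder haplotypes (n_haplotypes x n_markers), optionally LD-blocked."""
    m = len(freqs)
    if spec.ld_block_size <= 1:
        return (rng.random((n_haplotypes, m)) < freqs).astype(np.int8)
    haps = np.empty((n_haplotypes, m), dtype=np.int8)
    for start in range(0, m, spec.ld_block_size):
        stop = min(start + spec.ld_block_size, m)
        pool = (rng.random((spec.ld_pool_size, stop - start))
                < freqs[start:stop]).astype(np.int8)
        picks = rng.integers(spec.ld_pool_size, size=n_haplotypes)
        haps[:, start:stop] = pool[picks]
    return haps


def _meiosis_bits(cms: np.ndarray, locus_pos: int | None, locus_bit: int,
                  rng) -> np.ndarray:
    """Inheritance indicator along one chromosome for a single meiosis.

    A Markov chain with Haldane switch probabilities between adjacent
    markers; when ``locus_pos`` is given the chain is conditioned on the
    known transmitted haplotype at the planted locus by simulating outward
    from that marker in both directions.
    """
    m = len(cms)
    bits = np.empty(m, dtype=np.int8)
    theta = np.array([haldane_theta(cms[i + 1] - cms[i]) for i in range(m - 1)])
    if locus_pos is None:
        bits[0] = rng.integers(2)
        flips = rng.random(m - 1) < theta
        for i in range(1, m):
            bits[i] = bits[i - 1] ^ flips[i - 1]
        return bits
    bits[locus_pos] = locus_bit
    for i in range(locus_pos + 1, m):
        bits[i] = bits[i - 1] ^ (rng.random() < theta[i - 1])
    for i in range(locus_pos - 1, -1, -1):
        bits[i] = bits[i + 1] ^ (rng.random() < theta[i])
    return bits


def gene_drop_genotypes(fam: FamilySim, panel: MarkerPanel,
                        config: SimConfig) -> GenotypeTable:
    """Drop founder haplotypes through the pedigree along the marker map.

    Recombination follows the Haldane map; on the planted chromosome the
    inheritance chain is conditioned on the disease-locus transmissions
    recorded in ``fam``, so the marker data carry the linkage signal that
    affection status was generated from.
    """
    rng = config.rng(_STAGE_DROP)
    pedigree = fam.pedigree
    spec = config.markers
    tab = panel.table
    members = pedigree.members
    n, m = len(members), len(panel)
    hap = np.empty((n, 2, m), dtype=np.int8)
    row = {iid: k for k, iid in enumerate(members)}

    founders = pedigree.founders
    fhaps = _founder_haplotypes(2 * len(founders), tab["freq"].to_numpy(), spec, rng)
    for k, iid in enumerate(founders):
        hap[row[iid], 0] = fhaps[2 * k]
        hap[row[iid], 1] = fhaps[2 * k + 1]

    chrom_cols = {c: panel.chrom_indices(c) for c in panel.chromosomes()}
    planted_chrom = config.planted_chrom
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        if ind.is_founder:
            continue
        for side, parent in ((0, ind.father), (1, ind.mother)):
            for c, cols in chrom_cols.items():
                cms = tab["cm"].to_numpy()[cols]
                if c == planted_chrom:
                    bits = _meiosis_bits(cms, config.planted_marker,
                                         fam.locus_bits[(iid, side)], rng)
                else:
                    bits = _meiosis_bits(cms, None, 0, rng)
                src = hap[row[parent]]
                hap[row[iid], side, cols] = np.where(bits, src[1, cols], src[0, cols])

    alleles = np.stack([hap[:, 0, :], hap[:, 1, :]], axis=2)
    if config.genotype_error_rate > 0:
        err = rng.random(alleles.shape) < config.genotype_error_rate
        alleles = np.where(err, 1 - alleles, alleles)
    if config.genotype_missing_rate > 0:
        drop = rng.random((n, m)) < config.genotype_missing_rate
        alleles = alleles.copy()
        alleles[drop] = MISSING
    return GenotypeTable(members, panel.markers, alleles)


# ----------------------------------------------------------------------
# WES-like variant calls


def simulate_wes_calls(fam: FamilySim, sequenced_ids: list[str],
                       config: SimConfig, panel: MarkerPanel) -> pd.DataFrame:
    """Per-(variant, sample) WES call records for selected family members.

    Emits a configurable number of rare variants shared by every sequenced
    member -- some placed inside the planted linkage region, some on other
    chromosomes -- plus per-sample private noise variants, a fraction of
    which are too common or absent from the population-frequency reference.
    Columns: chrom, pos, ref, alt, gene, effect, maf, sample, depth, genotype.
    """
    if not sequenced_ids:
        raise ValueError("sequenced_ids must not be empty")
    for iid in sequenced_ids:
        if iid not in fam.pedigree:
            raise KeyError(f"{iid!r} not in pedigree")
    rng = config.rng(_STAGE_WES)
    wes = config.wes
    tab = panel.table
    on_chrom = tab[tab["chrom"] == config.planted_chrom]
    locus_bp = int(on_chrom["bp"].iloc[config.planted_marker])
    chrom_len = {c: int(tab[tab["chrom"] == c]["bp"].max() + 1_000_000)
                 for c in panel.chromosomes()}

    def depth() -> int:
        return int(max(wes.depth_min, rng.poisson(wes.depth_mean)))

    def rare_maf() -> float:
        if rng.random() < wes.frac_unknown_maf:
            return math.nan
        return float(10 ** rng.uniform(-5, math.log10(wes.maf_rare_max)))

    records = []
    gene_counter = [0]

    def new_gene() -> str:
        gene_counter[0] += 1
        return f"GENE{gene_counter[0]:04d}"

    def add_variant(chrom, pos, maf, samples, shared_tag, gene=None):
        gene = gene or new_gene()
        ref, alt = "G", "T"
        for s in samples:
            records.append({
                "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                "gene": gene, "effect": "missense", "maf": maf,
                "sample": s, "depth": depth(), "genotype": "0/1",
                "shared": shared_tag,
            })

    # shared variants inside the planted region (within 2 Mb of the locus)
    for k in range(wes.n_shared_in_region):
        pos = locus_bp + int(rng.integers(-2_000_000, 2_000_000))
        gene = (wes.region_genes[k % len(wes.region_genes)]
                if wes.region_genes else None)
        add_variant(config.planted_chrom, max(1, pos), rare_maf(),
                    sequenced_ids, True, gene=gene)
    # shared variants elsewhere
    other = [c for c in panel.chromosomes() if c != config.planted_chrom] \
        or [config.planted_chrom]
    for k in range(wes.n_shared_outside):
        c = other[k % len(other)]
        add_variant(c, rng.integers(1, chrom_len[c]), rare_maf(),
                    sequenced_ids, True)
    # private noise
    for iid in sequenced_ids:
        for _ in range(wes.n_private_per_sample):
            c = int(rng.integers(1, config.markers.n_chromosomes + 1))
            maf = (float(rng.uniform(0.01, 0.3))
                   if rng.random() < wes.frac_common_noise else rare_maf())
            add_variant(c, rng.integers(1, chrom_len[c]), maf, [iid], False)

    df = pd.DataFrame(records).sort_values(
        ["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)
    return df


# ----------------------------------------------------------------------
# case-control cohorts


@dataclass
class Cohort:
    """One case-control cohort: dosages plus SNP annotations."""

    name: str
    dosage: np.ndarray      # (n_individuals x n_snps) risk-allele counts
    is_case: np.ndarray     # bool per individual
    snps: pd.DataFrame      # snp, gene, maf

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def n(self) -> int:
        return len(self.is_case)


def build_cohort_panel(spec: CohortPanelSpec, rng) -> pd.DataFrame:
    """SNP->gene panel with per-SNP MAFs (shared across cohorts)."""
    rows = []
    for g in range(spec.n_genes):
        gene = f"CG{g + 1:04d}"
        k = int(rng.integers(spec.min_snps_per_gene, spec.max_snps_per_gene + 1))
        for j in range(k):
            rows.append({
                "snp": f"{gene}_snp{j + 1}",
                "gene": gene,
                "maf": float(rng.uniform(spec.maf_low, spec.maf_high)),
            })
    return pd.DataFrame(rows)


def _gene_haplotypes(n_hap: int, mafs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Haplotypes with AR(1) Gaussian-copula LD across a gene's SNPs."""
    k = len(mafs)
    z = rng.standard_normal((n_hap, k))
    if k > 1 and rho > 0:
        for j in range(1, k):
            z[:, j] = rho * z[:, j - 1] + math.sqrt(1 - rho ** 2) * z[:, j]
    return (z < norm.ppf(mafs)).astype(np.int8)


def simulate_cohorts(config: SimConfig,
                     panel: pd.DataFrame | None = None) -> list[Cohort]:
    """Simulate case-control cohorts under a liability-threshold model.

    Each SNP contributes ``beta * dosage`` to a standard-normal liability;
    individuals above the population (1 - prevalence) liability quantile
    are cases.  ``config.effect_genes`` maps gene name -> per-SNP liability
    beta; all other SNPs are null.  Cases and controls are sampled from the
    same population, so under zero effect every SNP is null-distributed.
    """
    rng = config.rng(_STAGE_COHORT)
    spec = config.cohort_panel
    if panel is None:
        panel = build_cohort_panel(spec, rng)
    betas = np.array([config.effect_genes.get(g, 0.0) for g in panel["gene"]])
    genes = panel["gene"].to_numpy()
    mafs = panel["maf"].to_numpy()
    gene_slices = []
    start = 0
    for g, sub in pd.Series(genes).groupby(pd.Series(genes), sort=False):
        gene_slices.append(slice(start, start + len(sub)))
        start += len(sub)

    cohorts = []
    for cs in config.cohorts:
        need_cases, need_controls = cs.n_cases, cs.n_controls
        # draw a population pool large enough to contain the cases
        pool = int(max((need_cases / spec.prevalence) * 1.25,
                       need_cases + need_controls))
        dosage = np.empty((pool, len(panel)), dtype=np.int8)
        for sl in gene_slices:
            h = _gene_haplotypes(2 * pool, mafs[sl], spec.ld_rho, rng)
            dosage[:, sl] = h[0::2] + h[1::2]
        liab = dosage @ betas + rng.standard_normal(pool)
        cut = np.quantile(liab, 1.0 - spec.prevalence)
        case_idx = np.flatnonzero(liab > cut)
        ctrl_idx = np.flatnonzero(liab <= cut)
        if len(case_idx) < need_cases or len(ctrl_idx) < need_controls:
            raise RuntimeError("population pool too small; raise prevalence")
        keep = np.concatenate([case_idx[:need_cases], ctrl_idx[:need_controls]])
        is_case = np.zeros(len(keep), dtype=bool)
        is_case[:need_cases] = True
        cohorts.append(Cohort(cs.name, dosage[keep], is_case, panel.copy()))
    return cohorts
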