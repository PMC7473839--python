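"""Rare-variant selection funnel for family WES data.

Variants are kept when (i) every sequenced family member has >= 20
supporting reads, (ii) the population MAF is below 1% (variants absent
from the frequency reference count as rare by default -- truly novel
variants have no database entry), and (iii) the same alternate allele is
called in every sequenced member.  Surviving variants are intersected with
the family's linkage regions (padded by 1 Mb) and collapsed to per-family
candidate gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage.regions import LinkageRegion

MIN_DEPTH = 20
MAF_CEILING = 0.01
REGION_PAD = 1_000_000


def filter_shared_rare(variants: pd.DataFrame, sequenced_ids: list[str],
                       min_depth: int = MIN_DEPTH,
                       maf_ceiling: float = MAF_CEILING,
                       assume_novel: bool = True) -> pd.DataFrame:
    """Apply the three WES selection criteria; returns one row per variant.

    ``variants`` holds per-(variant, sample) records with columns chrom,
    pos, ref, alt, gene, maf, sample, depth.  A variant passes only if it
    is called in *all* ``sequenced_ids``, each call has >= ``min_depth``
    reads, and its population MAF is < ``maf_ceiling``.  Unknown MAF
    counts as rare when ``assume_novel`` is true (default), otherwise as
    failing the MAF criterion; either way the decision is recorded in the
    ``maf_status`` column.
    """
    if not sequenced_ids:
        raise ValueError("no sequenced individuals given")
    sequenced = set(sequenced_ids)
    keys = ["chrom", "pos", "ref", "alt"]
    rows = []
    for key, sub in variants.groupby(keys, sort=True):
        sub = sub[sub["sample"].isin(sequenced)]
        if set(sub["sample"]) != sequenced:
            continue  # not present in all sequenced members
        if (sub["depth"].isna() | (sub["depth"] < min_depth)).any():
            continue
        maf = float(sub["maf"].iloc[0])
        if math.isnan(maf):
            if not assume_novel:
                continue
            status = "assumed_novel"
        else:
            if maf >= maf_ceiling:
                continue
            status = "rare"
        first = sub.iloc[0]
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "gene": first["gene"], "maf": maf, "maf_status": status,
            "min_depth": float(sub["depth"].min()),
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "maf", "maf_status", "min_depth"])


def expand_and_intersect(variants: pd.DataFrame, regions: list[LinkageRegion],
                         family: str, pad: int = REGION_PAD) -> pd.DataFrame:
    """Keep variants inside a padded linkage region the family contributes to.

    Boundaries are inclusive: a variant exactly ``pad`` bases outside the
    region is kept.  Regions whose contributing-family labels do not
    include ``family`` are ignored.  Adds a ``region`` column naming the
    matched region.
    """
    fam_regions = [r for r in regions if family in r.families]
    if variants.empty:
        return variants.assign(region=pd.Series(dtype=str))
    hits = []
    for _, v in variants.iterrows():
        match = next((r for r in fam_regions
                      if r.contains(v["chrom"], int(v["pos"]), pad=pad)), None)
        if match is not None:
            rec = v.to_dict()
            rec["region"] = match.tag
            hits.append(rec)
    return pd.DataFrame(hits, columns=list(variants.columns) + ["region"])


@dataclass
class FamilyGeneSet:
    """Candidate genes for one family, with their supporting variants."""

    family: str
    genes: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    def n_variants(self) -> int:
        return int(sum(len(v) for v in self.genes.values()))


def build_family_gene_sets(per_family_variants: dict[str, pd.DataFrame],
                           cohort_genes: set[str] | None = None
                           ) -> tuple[dict[str, FamilyGeneSet], list[str],
                                      list[str]]:
    """Collapse in-region variants to per-family gene sets and their union.

    Variants without a gene annotation are excluded (they cannot enter a
    gene-based test).  When ``cohort_genes`` is given, union genes absent
    from the downstream cohort panel are flagged and returned separately
    (they stay in the union but cannot contribute association signal).
    """
    sets = {}
    union: list[str] = []
    for family, variants in per_family_variants.items():
        fgs = FamilyGeneSet(family)
        if not variants.empty:
            annotated = variants[variants["gene"].notna() & (variants["gene"] != "")]
            for gene, sub in annotated.groupby("gene", sort=False):
                fgs.genes[gene] = sub
                if gene not in union:
                    union.append(gene)
        sets[family] = fgs
    missing = [] if cohort_genes is None else \
        [g for g in union if g not in cohort_genes]
    return sets, union, missing
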