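"""Candidate validation: familial co-segregation and GO-term enrichment.

``carrier_summary`` tabulates, per affection group, how many genotyped
family members carry at least one (and all) of a small set of candidate
variants -- the in-silico counterpart of a Sanger segregation check.
``hypergeom_enrichment`` tests a candidate gene list for
over-representation in GMT gene sets against a protein-coding background
(default 19,264 genes) with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import AFFECTED, UNAFFECTED, UNKNOWN, Pedigree

BACKGROUND_SIZE = 19_264
GROUPS = {AFFECTED: "affected", UNAFFECTED: "unaffected", UNKNOWN: "unknown"}


@dataclass
class SegregationSummary:
    """Carrier counts per affection group among genotyped members.

    Percentages are rounded to the nearest integer, the convention used
    when reporting segregation in clinical pedigrees.
    """

    table: pd.DataFrame

    def pct(self, group: str, which: str = "any") -> int:
        row = self.table[self.table["group"] == group].iloc[0]
        return int(row[f"pct_{which}"])

    def count(self, group: str, which: str = "any") -> int:
        row = self.table[self.table["group"] == group].iloc[0]
        return int(row[f"n_{which}"])


def carrier_summary(pedigree: Pedigree, carriers: dict[str, set[str]],
                    genotyped_ids: list[str]) -> SegregationSummary:
    """Summarise co-segregation of candidate variants with affection.

    ``carriers`` maps variant label -> set of carrier individual ids.
    Only ``genotyped_ids`` enter the denominators; members of unknown
    affection are tallied separately, never mixed into the affected or
    unaffected groups.
    """
    if not genotyped_ids:
        raise ValueError("no genotyped individuals")
    variant_sets = list(carriers.values())
    rows = []
    for code, name in GROUPS.items():
        members = [i for i in genotyped_ids if pedigree[i].affection == code]
        n = len(members)
        n_any = sum(1 for i in members if any(i in s for s in variant_sets))
        n_all = sum(1 for i in members if all(i in s for s in variant_sets))
        rows.append({
            "group": name, "n": n, "n_any": n_any, "n_all": n_all,
            "pct_any": round(100 * n_any / n) if n else 0,
            "pct_all": round(100 * n_all / n) if n else 0,
        })
    return SegregationSummary(pd.DataFrame(rows))


def hypergeom_enrichment(query_genes: list[str], collection: dict[str, list[str]],
                         background_size: int = BACKGROUND_SIZE,
                         background: set[str] | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is tested for enrichment of ``query_genes`` against a
    background universe of ``background_size`` genes (when an explicit
    ``background`` set is given, query and sets are intersected with it
    first).  Returns one row per set with the raw upper-tail p-value and
    the BH-adjusted value; ``significant`` marks adjusted p < ``alpha``.
    """
    query = list(dict.fromkeys(query_genes))
    if background is not None:
        background_size = len(background)
        query = [g for g in query if g in background]
    if not query:
        raise ValueError("empty query gene list")
    rows = []
    for name, genes in collection.items():
        members = set(genes) if background is None else set(genes) & background
        overlap = len(members & set(query))
        # upper tail: P(X >= overlap), X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(overlap - 1, background_size, len(members),
                               len(query)))
        rows.append({
            "term": name, "overlap": overlap, "set_size": len(members),
            "query_size": len(query), "background_size": background_size,
            "p": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
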