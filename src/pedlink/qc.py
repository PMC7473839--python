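"""Pre-linkage genotype quality control.

Implements the standard family-study SNP filters -- individual call rate,
marker MAF, marker missingness, per-variant Mendelian-error rate, exact
Hardy-Weinberg test on founders -- and sliding-window LD pruning, with the
defaults used for the linkage scan (call rate >= 0.97, MAF >= 0.05,
missingness <= 0.05, Mendel rate <= 0.10, HWE p > 1e-6, r^2 ceiling 0.01
in 50-SNP windows stepping by 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeTable, MarkerPanel, Pedigree


@dataclass(frozen=True)
class QCConfig:
    call_rate_floor: float = 0.97
    maf_floor: float = 0.05
    missingness_ceiling: float = 0.05
    mendel_rate_ceiling: float = 0.10
    hwe_p_floor: float = 1e-6
    prune_window: int = 50
    prune_step: int = 5
    prune_r2_ceiling: float = 0.01
    ld_on_founders_only: bool = True

    def __post_init__(self):
        for name in ("call_rate_floor", "maf_floor", "missingness_ceiling",
                     "mendel_rate_ceiling", "hwe_p_floor", "prune_r2_ceiling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.prune_window < 2 or self.prune_step < 1:
            raise ValueError("prune window/step out of range")


# ----------------------------------------------------------------------
# individual filter


def filter_individuals(table: GenotypeTable, floor: float = 0.97
                       ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop individuals whose genotype call rate is below ``floor``.

    Returns the filtered table and a removal log (iid, call_rate).
    """
    if table.n_individuals == 0:
        raise ValueError("empty genotype table")
    rates = table.call_rate()
    keep = rates >= floor
    removed = pd.DataFrame({
        "iid": [i for i, k in zip(table.ids, keep) if not k],
        "call_rate": rates[~keep],
    })
    if not keep.any():
        raise ValueError("call-rate filter removed every individual")
    kept_ids = [i for i, k in zip(table.ids, keep) if k]
    return table.subset_individuals(kept_ids), removed


# ----------------------------------------------------------------------
# Mendelian consistency


def _trio_ok(child, father, mother):
    for a in father:
        other = list(child)
        if a in other:
            other.remove(a)
            if other[0] in mother:
                return True
    return False


def _duo_ok(child, parent):
    return bool(set(parent) & set(child))


def mendel_checks(pedigree: Pedigree, table: GenotypeTable, col: int
                  ) -> tuple[int, int, list[str]]:
    """(errors, informative checks, offending child ids) at marker column."""
    errors, checks, bad = 0, 0, []
    geno = {}
    for iid in table.ids:
        a = table.alleles[table.row(iid), col]
        geno[iid] = None if a[0] == MISSING else (int(a[0]), int(a[1]))
    for iid in pedigree.members:
        ind = pedigree[iid]
        if ind.is_founder or geno.get(iid) is None:
            continue
        f = geno.get(ind.father)
        m = geno.get(ind.mother)
        if f is None and m is None:
            continue
        checks += 1
        if f is not None and m is not None:
            ok = _trio_ok(geno[iid], f, m)
        else:
            ok = _duo_ok(geno[iid], f if f is not None else m)
        if not ok:
            errors += 1
            bad.append(iid)
    return errors, checks, bad


def mendel_error_rate(pedigree: Pedigree, table: GenotypeTable, marker: str
                      ) -> float:
    """Mendelian-error rate at one marker: errors / informative checks.

    A check is one genotyped non-founder with at least one genotyped
    parent; missing genotypes skip the check.  With zero informative
    checks the rate is 0 by convention.
    """
    errors, checks, _ = mendel_checks(pedigree, table, table.col(marker))
    return errors / checks if checks else 0.0


# ----------------------------------------------------------------------
# exact HWE test


def hwe_test(n_aa: int, n_ab: int, n_bb: int, midp: bool = False) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Enumerates the conditional distribution of the heterozygote count
    given the allele counts (the standard exact test); monomorphic markers
    return p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # log-probabilities over all feasible heterozygote counts (parity fixed)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    lg = math.lgamma
    logp = np.array([
        lg(n + 1) - lg(h + 1) - lg(r + 1) - lg(c + 1) + h * math.log(2)
        + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
        for h, r, c in zip(hets, homr, homc)
    ])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_ab
    idx = np.flatnonzero(hets == obs)
    if len(idx) == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = p[idx[0]]
    if midp:
        tail = p[p < p_obs].sum() + 0.5 * p[p == p_obs].sum()
    else:
        tail = p[p <= p_obs].sum()
    return float(min(1.0, tail))


def genotype_counts(table: GenotypeTable, col: int,
                    rows: list[int] | None = None) -> tuple[int, int, int]:
    a = table.alleles[:, col, :] if rows is None else table.alleles[rows, col, :]
    d = a.sum(axis=1)
    ok = a[:, 0] != MISSING
    d = d[ok]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


# ----------------------------------------------------------------------
# LD


def ld_r2(table: GenotypeTable, marker_i: str, marker_j: str,
          rows: list[int] | None = None) -> float:
    """Squared dosage correlation (composite LD, no phasing needed)."""
    d = table.dosage() if rows is None else table.dosage()[rows]
    x = d[:, table.col(marker_i)]
    y = d[:, table.col(marker_j)]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 complete genotype pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("marker monomorphic among used individuals")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pair_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise r^2 with pairwise-complete observations; NaN if undefined."""
    m = dos.shape[1]
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            x, y = dos[:, i], dos[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            out[i, j] = out[j, i] = r * r
    return out


def ld_prune(table: GenotypeTable, panel: MarkerPanel, cfg: QCConfig,
             rows: list[int] | None = None) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained marker names.

    Windows of ``prune_window`` markers slide by ``prune_step`` within each
    chromosome; within a window, while any retained pair exceeds the r^2
    ceiling, the member with higher missingness (tie: later map position)
    of the first offending pair is removed.  Deterministic.
    """
    dos_all = table.dosage() if rows is None else table.dosage()[rows]
    cols = [table.col(m) for m in panel.markers]
    dos = dos_all[:, cols]
    missing = np.isnan(dos).mean(axis=0)
    removed = np.zeros(len(panel), dtype=bool)
    tab = panel.table
    for chrom in panel.chromosomes():
        idx = panel.chrom_indices(chrom)
        for start in range(0, len(idx), cfg.prune_step):
            win = idx[start:start + cfg.prune_window]
            if len(win) < 2:
                continue
            while True:
                live = [i for i in win if not removed[i]]
                r2 = _pair_r2_matrix(dos[:, live])
                hit = None
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        if r2[a, b] > cfg.prune_r2_ceiling:
                            hit = (live[a], live[b])
                            break
                    if hit:
                        break
                if hit is None:
                    break
                i, j = hit
                if missing[i] > missing[j]:
                    removed[i] = True
                elif missing[j] > missing[i]:
                    removed[j] = True
                else:
                    removed[max(i, j)] = True
    return [m for m, r in zip(panel.markers, removed) if not r]


# ----------------------------------------------------------------------
# full QC stage


@dataclass
class QCResult:
    panel: MarkerPanel
    table: GenotypeTable
    removed_individuals: pd.DataFrame
    marker_report: pd.DataFrame
    cleaned_genotypes: list = field(default_factory=list)


def apply_qc(pedigree: Pedigree, panel: MarkerPanel, table: GenotypeTable,
             cfg: QCConfig | None = None) -> QCResult:
    """Run the full marker/individual QC and LD pruning.

    Markers failing MAF, missingness, Mendel-rate or founder-HWE filters
    are dropped; individual Mendelian-inconsistent genotypes at retained
    markers are set to missing (and logged).  The returned report has one
    row per input marker with every statistic and the final decision.
    """
    cfg = cfg or QCConfig()
    table, removed_ind = filter_individuals(table, cfg.call_rate_floor)
    founder_rows = [table.row(i) for i in pedigree.founders if i in table.ids]

    rows = []
    cleaned = []
    keep_mask = []
    alleles = table.alleles.copy()
    for m_idx, marker in enumerate(panel.markers):
        col = table.col(marker)
        d = alleles[:, col, :].sum(axis=1).astype(float)
        obs = alleles[:, col, 0] != MISSING
        maf = float(d[obs].mean() / 2.0) if obs.any() else math.nan
        maf = min(maf, 1.0 - maf)
        missingness = float(1.0 - obs.mean())
        errors, checks, bad_ids = mendel_checks(pedigree, table, col)
        mendel_rate = errors / checks if checks else 0.0
        caa, cab, cbb = genotype_counts(table, col, founder_rows)
        hwe_p = hwe_test(caa, cab, cbb)
        ok = (maf >= cfg.maf_floor and missingness <= cfg.missingness_ceiling
              and mendel_rate <= cfg.mendel_rate_ceiling
              and hwe_p > cfg.hwe_p_floor)
        if ok and errors:
            for iid in bad_ids:
                alleles[table.row(iid), col] = MISSING
                cleaned.append((marker, iid))
        keep_mask.append(ok)
        rows.append({"marker": marker, "maf": maf, "missingness": missingness,
                     "mendel_rate": mendel_rate, "hwe_p": hwe_p,
                     "filter_pass": ok})
    table = GenotypeTable(table.ids, table.markers, alleles)

    kept = [m for m, k in zip(panel.markers, keep_mask) if k]
    panel_kept = panel.subset([panel.index_of(m) for m in kept])
    rows_for_ld = (founder_rows if cfg.ld_on_founders_only else None)
    retained = ld_prune(table.subset_markers(kept), panel_kept, cfg,
                        rows=rows_for_ld)
    retained_set = set(retained)
    report = pd.DataFrame(rows)
    report["prune_keep"] = [m in retained_set for m in report["marker"]]
    final_panel = panel.subset([panel.index_of(m) for m in retained])
    final_table = table.subset_markers(retained)
    return QCResult(final_panel, final_table, removed_ind, report, cleaned)
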