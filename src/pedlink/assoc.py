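"""Gene-based and gene-set association with cross-cohort meta-analysis.

Per SNP, a Cochran-Armitage trend test on allele dosage; per gene, the
mean of the SNP chi-squares whose null distribution is the matching
mixture of chi-squares weighted by the eigenvalues of the inter-SNP LD
(dosage-correlation) matrix, evaluated by Imhof numerical integration
with a Satterthwaite moment-matching fallback.  Gene p-values are mapped
to probit Z-scores, meta-analysed across cohorts with sqrt(sample-size)
fixed-effect weights, and gene sets are tested both self-contained (mean
set Z > 0) and competitively (set membership regressed on Z with gene-size
covariates).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import chi2, norm, t as t_dist

log = logging.getLogger(__name__)

Z_CAP = 8.0  # |Z| bound when converting extreme p-values


class MonomorphicSNPError(ValueError):
    """SNP has no variation in the analysed sample."""


# ----------------------------------------------------------------------
# per-SNP statistic


def snp_trend_stat(case_counts, control_counts) -> tuple[float, float]:
    """Cochran-Armitage trend test on genotype counts (scores 0, 1, 2).

    ``case_counts`` and ``control_counts`` are (n_AA, n_Aa, n_aa) with the
    trend taken in the direction of the a-allele dosage.  Returns
    (chi-square, signed Z); the sign is positive when cases carry more
    copies of the a allele than controls.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.sum() == 0 or s.sum() == 0:
        raise ValueError("both groups must be non-empty")
    tsc = np.array([0.0, 1.0, 2.0])
    n = r + s
    N = n.sum()
    R = r.sum()
    num = N * (tsc * r).sum() - R * (tsc * n).sum()
    den = R * (N - R) * (N * (tsc ** 2 * n).sum() - ((tsc * n).sum()) ** 2)
    if den <= 0:
        raise MonomorphicSNPError("SNP monomorphic; no trend statistic")
    chi = N * num ** 2 / den
    sign = 1.0 if num > 0 else (-1.0 if num < 0 else 0.0)
    return float(chi), float(sign * math.sqrt(chi))


# ----------------------------------------------------------------------
# mixture-of-chi-squares null for the SNP-wise mean statistic


def _imhof_tail(x: float, lam: np.ndarray) -> tuple[float, float]:
    """P(sum lam_i * chi2_1 > x) by Imhof's integral, with error estimate."""

    lam_list = [float(v) for v in lam]

    def integrand(u):
        theta = -0.5 * x * u
        rho = 1.0
        for lv in lam_list:
            lu = lv * u
            theta += 0.5 * math.atan(lu)
            rho *= (1.0 + lu * lu) ** 0.25
        return math.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf, limit=500,
                                  epsabs=1e-10, epsrel=1e-8)
    return 0.5 + val / math.pi, err / math.pi


def _satterthwaite_tail(x: float, lam: np.ndarray) -> float:
    s1, s2 = lam.sum(), (lam ** 2).sum()
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(chi2.sf(x / scale, df))


def mixture_chi2_sf(x: float, lam: np.ndarray, tol: float = 1e-9) -> float:
    """Upper tail of a nonnegative chi-square mixture at ``x``.

    Imhof integration, falling back to Satterthwaite moment matching when
    the integral misbehaves (non-convergence or value outside [0, 1]).
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(chi2.sf(x / lam[0], 1))
    try:
        p, err = _imhof_tail(x, lam)
    except Exception:
        return _satterthwaite_tail(x, lam)
    if not np.isfinite(p) or err > 1e-3 or not (-tol <= p <= 1 + tol) \
            or p < 1e-10:
        # Imhof loses accuracy in the far tail; moments are stabler there
        return max(_satterthwaite_tail(x, lam), 1e-300)
    return float(min(max(p, 1e-300), 1.0))


@dataclass
class GeneStat:
    gene: str
    n_snps: int
    stat: float       # mean SNP chi-square
    p: float
    z: float
    cohort: str = ""


def _nearest_psd_eigvals(corr: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvalsh(corr)
    if vals.min() < -1e-8:
        log.warning("LD matrix not PSD (min eigenvalue %.3g); clipping", vals.min())
    return np.clip(vals, 0.0, None)


def gene_p_snpwise_mean(snp_chi2: np.ndarray, ld_corr: np.ndarray,
                        gene: str = "", cohort: str = "") -> GeneStat:
    """Gene p-value from the mean of its SNP chi-squares, LD-corrected.

    Under the null the statistic is distributed as (1/k) * sum of
    chi-square(1) variables weighted by the eigenvalues of the SNP
    correlation matrix; its upper tail gives the gene p-value.
    """
    snp_chi2 = np.asarray(snp_chi2, dtype=float)
    k = snp_chi2.size
    if k == 0:
        raise ValueError("gene has no usable SNPs")
    ld_corr = np.atleast_2d(np.asarray(ld_corr, dtype=float))
    if ld_corr.shape != (k, k):
        raise ValueError("LD matrix does not match the SNP list")
    lam = _nearest_psd_eigvals(ld_corr)
    stat = float(snp_chi2.mean())
    p = mixture_chi2_sf(k * stat, lam)
    return GeneStat(gene, k, stat, p, gene_z(p), cohort)


def gene_z(p: float, cap: float = Z_CAP) -> float:
    """Probit transform Z = Phi^-1(1 - p), clipped to +-``cap``."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    return float(np.clip(norm.isf(p), -cap, cap))


# ----------------------------------------------------------------------
# gene-set tests


def set_test_self_contained(zs: np.ndarray) -> float:
    """One-sided test of mean gene Z > 0 (intercept-only normal model)."""
    zs = np.asarray(zs, dtype=float)
    n = zs.size
    if n < 2:
        raise ValueError("need >= 2 genes; use a gene-based lookup for one gene")
    mean = zs.mean()
    sd = zs.std(ddof=1)
    if sd == 0:
        return 0.5 if mean == 0 else (0.0 if mean > 0 else 1.0)
    tstat = mean / (sd / math.sqrt(n))
    return float(t_dist.sf(tstat, n - 1))


def set_test_competitive(z_all: np.ndarray, in_set: np.ndarray,
                         covariates: pd.DataFrame | None = None) -> float:
    """One-sided test that set genes score higher than the other genes.

    Linear model of Z on set membership plus covariates (by convention
    gene size and log gene size); the one-sided t p-value on the
    membership coefficient is returned.  Constant or collinear covariate
    columns are dropped with a warning.
    """
    z_all = np.asarray(z_all, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    if in_set.all() or not in_set.any():
        raise ValueError("set and complement must both be non-empty")
    cols = [np.ones(z_all.size), in_set.astype(float)]
    names = ["const", "set"]
    if covariates is not None:
        for name in covariates.columns:
            v = covariates[name].to_numpy(dtype=float)
            trial = np.column_stack(cols + [v])
            if np.linalg.matrix_rank(trial) <= len(cols):
                log.warning("dropping collinear covariate %r", name)
                continue
            cols.append(v)
            names.append(name)
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, z_all, rcond=None)
    resid = z_all - X @ beta
    df = z_all.size - X.shape[1]
    if df < 1:
        raise ValueError("more covariates than genes")
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tstat = beta[1] / math.sqrt(cov[1, 1])
    return float(t_dist.sf(tstat, df))


# ----------------------------------------------------------------------
# meta-analysis


def meta_analyze(zs, ns) -> tuple[float, float]:
    """Fixed-effect combination with sqrt(sample-size) weights.

    Z_meta = sum(w_i Z_i) / sqrt(sum w_i^2) with w_i = sqrt(N_i); the
    p-value is the one-sided upper normal tail.
    """
    zs = np.asarray(zs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if zs.size == 0:
        raise ValueError("no cohorts to combine")
    w = np.sqrt(ns)
    zm = float((w * zs).sum() / math.sqrt((w ** 2).sum()))
    return zm, float(norm.sf(zm))


def bonferroni_lookup(gene_ps: dict[str, float], alpha: float = 0.05
                      ) -> tuple[float, dict[str, bool]]:
    """Gene-wide significance threshold alpha / n_genes, strict inequality."""
    if not gene_ps:
        raise ValueError("empty gene list")
    threshold = alpha / len(gene_ps)
    return threshold, {g: p < threshold for g, p in gene_ps.items()}


# ----------------------------------------------------------------------
# cohort-level driver


def cohort_gene_stats(dosage: np.ndarray, is_case: np.ndarray,
                      snps: pd.DataFrame, genes: list[str] | None = None,
                      cohort: str = "") -> list[GeneStat]:
    """SNP-wise-mean gene statistics for one case-control cohort.

    ``snps`` maps dosage columns to genes (columns snp, gene).  The LD
    correlation per gene is estimated from the cohort's controls.
    Monomorphic SNPs are excluded (logged); genes with no usable SNP are
    skipped.
    """
    out = []
    wanted = snps["gene"].unique() if genes is None else genes
    ctrl = dosage[~is_case]
    for gene in wanted:
        cols = np.flatnonzero((snps["gene"] == gene).to_numpy())
        if cols.size == 0:
            continue
        chis, kept = [], []
        for c in cols:
            d = dosage[:, c]
            counts_case = [int(((dosage[is_case, c]) == g).sum()) for g in (0, 1, 2)]
            counts_ctrl = [int(((dosage[~is_case, c]) == g).sum()) for g in (0, 1, 2)]
            try:
                chi, _ = snp_trend_stat(counts_case, counts_ctrl)
            except MonomorphicSNPError:
                log.info("cohort %s: SNP %s monomorphic; excluded",
                         cohort, snps["snp"].iloc[c])
                continue
            chis.append(chi)
            kept.append(c)
        if not chis:
            log.info("cohort %s: gene %s has no polymorphic SNP; skipped",
                     cohort, gene)
            continue
        sub = ctrl[:, kept].astype(float)
        if len(kept) == 1:
            corr = np.ones((1, 1))
        else:
            corr = np.corrcoef(sub, rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
        out.append(gene_p_snpwise_mean(np.array(chis), corr, gene, cohort))
    return out


def meta_gene_table(per_cohort: dict[str, list[GeneStat]],
                    cohort_sizes: dict[str, int]) -> pd.DataFrame:
    """Meta-analysed gene table across cohorts.

    Genes missing from a cohort (e.g. no polymorphic variant on the chip
    there) are combined over the cohorts that do carry them; the log notes
    the omission.  Columns: gene, n_snps, n_cohorts, z_meta, p_meta.
    """
    by_gene: dict[str, list[GeneStat]] = {}
    for cohort, stats in per_cohort.items():
        for gs in stats:
            by_gene.setdefault(gs.gene, []).append(gs)
    rows = []
    n_cohorts = len(per_cohort)
    for gene, stats in by_gene.items():
        if len(stats) < n_cohorts:
            log.info("gene %s present in %d/%d cohorts", gene, len(stats),
                     n_cohorts)
        zm, pm = meta_analyze([g.z for g in stats],
                              [cohort_sizes[g.cohort] for g in stats])
        rows.append({"gene": gene, "n_snps": int(np.max([g.n_snps for g in stats])),
                     "n_cohorts": len(stats), "z_meta": zm, "p_meta": pm})
    return pd.DataFrame(rows)


def gene_set_tests(meta_table: pd.DataFrame, set_genes: list[str]
                   ) -> dict[str, float]:
    """Self-contained and competitive tests for one gene set on meta Zs."""
    present = meta_table[meta_table["gene"].isin(set_genes)]
    zs = present["z_meta"].to_numpy()
    result = {"n_genes": int(len(present)),
              "p_self_contained": set_test_self_contained(zs)}
    in_set = meta_table["gene"].isin(set_genes).to_numpy()
    cov = pd.DataFrame({"n_snps": meta_table["n_snps"],
                        "log_n_snps": np.log(meta_table["n_snps"])})
    result["p_competitive"] = set_test_competitive(
        meta_table["z_meta"].to_numpy(), in_set, cov)
    return result
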