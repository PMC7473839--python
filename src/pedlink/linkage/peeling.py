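"""Exact two-locus pedigree likelihoods by Elston-Stewart peeling.

The disease locus (biallelic, parameterised by a :class:`DiseaseModel`) and
one biallelic marker are modelled jointly.  Each individual's latent state
is an ordered pair of two-locus haplotypes (4 haplotypes -> 16 states);
founders carry Hardy-Weinberg / linkage-equilibrium priors and
transmissions recombine with fraction ``theta``.  The likelihood is
computed by variable elimination over individuals in reverse topological
order, which for loop-free pedigrees peels nuclear families bottom-up and
keeps intermediate factors small.
"""

from __future__ import annotations

import math
import numpy as np

from ..types import (AFFECTED, MISSING, UNAFFECTED, DiseaseModel,
                     GenotypeTable, Pedigree, PedigreeLoopError)

# state s = 4*hp + hm; haplotype h = 2*d + m  (d: disease allele, m: marker allele)
_HP = np.arange(16) // 4
_HM = np.arange(16) % 4
_D_COUNT = (_HP // 2) + (_HM // 2)          # risk-allele copies per state
_M_PAT = _HP % 2                            # marker allele on paternal haplotype
_M_MAT = _HM % 2


def _penetrance_vector(affection: int, model: DiseaseModel) -> np.ndarray:
    pen = np.asarray(model.penetrance_by_genotype)
    if affection == AFFECTED:
        return pen[_D_COUNT]
    if affection == UNAFFECTED:
        return 1.0 - pen[_D_COUNT]
    return np.ones(16)


def _marker_evidence(genotype: tuple[int, int] | None) -> np.ndarray:
    if genotype is None:
        return np.ones(16)
    want = tuple(sorted(genotype))
    have = np.stack([np.minimum(_M_PAT, _M_MAT), np.maximum(_M_PAT, _M_MAT)], 1)
    return ((have[:, 0] == want[0]) & (have[:, 1] == want[1])).astype(float)


def _founder_prior(model: DiseaseModel, marker_freq: float) -> np.ndarray:
    """State prior: independent haplotypes, linkage equilibrium."""
    q = model.risk_allele_freq
    fd = np.array([1 - q, q])
    fm = np.array([1 - marker_freq, marker_freq])
    hap = np.array([fd[h // 2] * fm[h % 2] for h in range(4)])
    return hap[_HP] * hap[_HM]


def _gamete_matrix(theta: float) -> np.ndarray:
    """P(gamete haplotype | parent state) with recombination ``theta``."""
    g = np.zeros((16, 4))
    for s in range(16):
        h1, h2 = s // 4, s % 4
        for di, hd in ((0, h1), (1, h2)):
            for mi, hm in ((0, h1), (1, h2)):
                gam = 2 * (hd // 2) + (hm % 2)
                g[s, gam] += (1 - theta) / 2 if di == mi else theta / 2
    return g


class _Factor:
    __slots__ = ("vars", "arr")

    def __init__(self, vars_, arr):
        self.vars = tuple(vars_)
        self.arr = arr


def _multiply(factors: list[_Factor]) -> _Factor:
    out = factors[0]
    for f in factors[1:]:
        union = list(out.vars) + [v for v in f.vars if v not in out.vars]
        if len(union) > 4:
            raise PedigreeLoopError(
                "pedigree structure too entangled for simple peeling; "
                "break loops and retry")
        a = out.arr.reshape(out.arr.shape + (1,) * (len(union) - len(out.vars)))
        perm = [union.index(v) for v in f.vars] + \
               [k for k, v in enumerate(union) if v not in f.vars]
        b = np.transpose(
            f.arr.reshape(f.arr.shape + (1,) * (len(union) - len(f.vars))),
            np.argsort(perm))
        out = _Factor(union, a * b)
    return out


def pedigree_likelihood(pedigree: Pedigree, genotypes: dict, model: DiseaseModel,
                        marker_freq: float, theta: float) -> float:
    """Natural-log likelihood of phenotypes + one marker at recombination theta.

    ``genotypes`` maps individual id -> unordered allele pair (0/1 codes) or
    None for untyped individuals.  Individuals with unknown affection
    contribute a penetrance factor of 1 (transmission information only).
    Raises :class:`PedigreeLoopError` for looped pedigrees; returns ``-inf``
    when the data are impossible at this ``theta``.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    if pedigree.has_loops():
        raise PedigreeLoopError(
            "pedigree contains loops; break them (duplicate one loop member) "
            "before linkage analysis")
    gam = _gamete_matrix(theta)
    prior = _founder_prior(model, marker_freq)

    factors: list[_Factor] = []
    for iid in pedigree.members:
        ind = pedigree[iid]
        unary = _penetrance_vector(ind.affection, model) * \
            _marker_evidence(genotypes.get(iid))
        if ind.is_founder:
            unary = unary * prior
        factors.append(_Factor((iid,), unary))
        if not ind.is_founder:
            # T[c, f, m] = P(child state | parent states)
            tcfm = np.zeros((16, 16, 16))
            # child state index = 4*hp + hm with hp from father, hm from mother
            for hp in range(4):
                for hm in range(4):
                    tcfm[4 * hp + hm] = np.outer(gam[:, hp], gam[:, hm])
            factors.append(_Factor((iid, ind.father, ind.mother), tcfm))

    order = list(reversed(pedigree.topological_order()))
    log_scale = 0.0
    for var in order:
        group = [f for f in factors if var in f.vars]
        if not group:
            continue
        for f in group:
            factors.remove(f)
        prod = _multiply(group)
        axis = prod.vars.index(var)
        arr = prod.arr.sum(axis=axis)
        remaining = tuple(v for v in prod.vars if v != var)
        if remaining:
            peak = arr.max()
            if peak <= 0.0:
                return -math.inf  # data impossible at this theta
            arr = arr / peak
            log_scale += math.log(peak)
            factors.append(_Factor(remaining, arr))
        else:
            if arr <= 0.0:
                return -math.inf
            log_scale += math.log(float(arr))
    return log_scale


def lod_single_point(pedigree: Pedigree, genotypes: dict, model: DiseaseModel,
                     marker_freq: float, theta_grid=None) -> dict[float, float]:
    """Single-marker LOD scores: log10 L(theta) - log10 L(0.5).

    ``theta_grid`` defaults to (0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5);
    0.5 is always evaluated (it anchors the no-linkage likelihood).
    """
    if theta_grid is None:
        theta_grid = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    grid = sorted(set(float(t) for t in theta_grid) | {0.5})
    ll_null = pedigree_likelihood(pedigree, genotypes, model, marker_freq, 0.5)
    if ll_null == -math.inf:
        raise ValueError(
            "zero likelihood at theta = 0.5: genotype data inconsistent with "
            "the pedigree (Mendelian error?)")
    out = {}
    for t in grid:
        if t == 0.5:
            out[t] = 0.0
        else:
            ll = pedigree_likelihood(pedigree, genotypes, model, marker_freq, t)
            out[t] = (ll - ll_null) / math.log(10)
    return out


def marker_genotypes(table: GenotypeTable, marker: str) -> dict:
    """Extract the per-individual unordered genotype dict for one marker."""
    col = table.col(marker)
    out = {}
    for iid in table.ids:
        a = table.alleles[table.row(iid), col]
        out[iid] = None if a[0] == MISSING else (int(a[0]), int(a[1]))
    return out


def founder_allele_freq(table: GenotypeTable, pedigree: Pedigree, marker: str,
                        smoothing: float = 1.0) -> float:
    """Founder frequency of allele code 1 with add-``smoothing`` correction."""
    col = table.col(marker)
    rows = [table.row(i) for i in pedigree.founders if i in table.ids]
    alle = table.alleles[rows, col, :].ravel()
    alle = alle[alle != MISSING]
    return (float((alle == 1).sum()) + smoothing) / (len(alle) + 2 * smoothing)
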