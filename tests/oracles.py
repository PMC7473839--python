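"""Independent brute-force oracles used by unit and acceptance tests.

Everything here recomputes quantities by exhaustive enumeration or plain
closed forms, deliberately avoiding the package's own algorithms
(peeling, HMM forward-backward, union-find emissions, Imhof integration).
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product
from math import comb

import numpy as np

from pedlink.simulate import haldane_theta
from pedlink.types import AFFECTED, UNAFFECTED, Pedigree

# ----------------------------------------------------------------------
# two-locus pedigree likelihood by full joint enumeration (16^n states)


def _haplotype_freqs(model, marker_freq):
    q = model.risk_allele_freq
    fm = np.array([1 - marker_freq, marker_freq])
    fd = np.array([1 - q, q])
    return np.array([fd[h // 2] * fm[h % 2] for h in range(4)])


def brute_two_locus_loglik(pedigree: Pedigree, genotypes: dict, model,
                           marker_freq: float, theta: float) -> float:
    """Log-likelihood by multiplying factors over the full 16^n state tensor."""
    members = pedigree.members
    n = len(members)
    idx = {m: k for k, m in enumerate(members)}
    hap = _haplotype_freqs(model, marker_freq)
    prior16 = np.array([hap[s // 4] * hap[s % 4] for s in range(16)])
    pen = np.asarray(model.penetrance_by_genotype)
    dcount = np.array([(s // 4) // 2 + (s % 4) // 2 for s in range(16)])
    mpair = [tuple(sorted(((s // 4) % 2, (s % 4) % 2))) for s in range(16)]

    # gamete distribution per parent state
    gam = np.zeros((16, 4))
    for s in range(16):
        h = (s // 4, s % 4)
        for di in range(2):
            for mi in range(2):
                g = 2 * (h[di] // 2) + (h[mi] % 2)
                gam[s, g] += ((1 - theta) if di == mi else theta) / 2

    joint = np.ones((16,) * n)

    def axis_view(arr, k):
        shape = [1] * n
        shape[k] = 16
        return arr.reshape(shape)

    for iid in members:
        ind = pedigree[iid]
        u = np.ones(16)
        if ind.affection == AFFECTED:
            u *= pen[dcount]
        elif ind.affection == UNAFFECTED:
            u *= 1 - pen[dcount]
        g = genotypes.get(iid)
        if g is not None:
            want = tuple(sorted(g))
            u *= np.array([1.0 if mpair[s] == want else 0.0 for s in range(16)])
        if ind.is_founder:
            u *= prior16
        joint *= axis_view(u, idx[iid])
        if not ind.is_founder:
            t = np.zeros((16, 16, 16))  # child, father, mother
            for hp in range(4):
                for hm in range(4):
                    t[4 * hp + hm] = np.outer(gam[:, hp], gam[:, hm])
            shape = [1] * n
            kc, kf, km = idx[iid], idx[ind.father], idx[ind.mother]
            view = np.ones((16,) * n)
            # broadcast t into the joint's axes
            order = sorted([(kc, 0), (kf, 1), (km, 2)])
            perm = [o[1] for o in order]
            tt = np.transpose(t, perm)
            shape = [16 if k in (kc, kf, km) else 1 for k in range(n)]
            joint *= tt.reshape(shape)
    total = joint.sum()
    return math.log(total) if total > 0 else -math.inf


# ----------------------------------------------------------------------
# multipoint likelihood by enumerating raw meiosis vectors at every locus


def _raw_descent(pedigree, founders, vec_bits, members):
    """Haplotype slot per person given raw per-meiosis bits (dict)."""
    slot = {}
    for k, f in enumerate(founders):
        slot[f] = (2 * k, 2 * k + 1)
    for iid in members:
        ind = pedigree[iid]
        if ind.is_founder:
            continue
        bp = vec_bits[(iid, 0)]
        bm = vec_bits[(iid, 1)]
        slot[iid] = (slot[ind.father][bp], slot[ind.mother][bm])
    return slot


def brute_multipoint_lod(pedigree: Pedigree, cms, freqs, genotypes, model,
                         disease_cm: float) -> float:
    """Multipoint LOD at one position by exhaustive enumeration.

    Enumerates the raw inheritance vector (2 bits per non-founder) at every
    marker and at the disease position, with Haldane transition
    probabilities, and sums founder-allele assignments per locus.  Only
    feasible for very small pedigrees.
    """
    members = pedigree.members
    founders = pedigree.founders
    nonf = pedigree.nonfounders
    nb = 2 * len(nonf)
    n_slots = 2 * len(founders)
    q = model.risk_allele_freq
    pen = np.asarray(model.penetrance_by_genotype)

    def bits_dict(v):
        d = {}
        for k, iid in enumerate(nonf):
            d[(iid, 0)] = (v >> (2 * k)) & 1
            d[(iid, 1)] = (v >> (2 * k + 1)) & 1
        return d

    def marker_emission(v, mi):
        slot = _raw_descent(pedigree, founders, bits_dict(v), members)
        fr = freqs[mi]
        total = 0.0
        for alleles in product((0, 1), repeat=n_slots):
            p = 1.0
            for a in alleles:
                p *= fr if a == 1 else 1 - fr
            for iid in members:
                g = genotypes[iid][mi]
                if g is None:
                    continue
                got = tuple(sorted((alleles[slot[iid][0]], alleles[slot[iid][1]])))
                if got != tuple(sorted(g)):
                    p = 0.0
                    break
            total += p
        return total

    def disease_emission(v):
        slot = _raw_descent(pedigree, founders, bits_dict(v), members)
        total = 0.0
        for alleles in product((0, 1), repeat=n_slots):
            p = 1.0
            for a in alleles:
                p *= q if a == 1 else 1 - q
            for iid in members:
                g = alleles[slot[iid][0]] + alleles[slot[iid][1]]
                aff = pedigree[iid].affection
                if aff == AFFECTED:
                    p *= pen[g]
                elif aff == UNAFFECTED:
                    p *= 1 - pen[g]
            total += p
        return total

    def trans(a, b, theta):
        x = a ^ b
        nf = bin(x).count("1")
        return (theta ** nf) * ((1 - theta) ** (nb - nf))

    positions = [(c, "M", i) for i, c in enumerate(cms)] + [(disease_cm, "D", -1)]
    positions.sort(key=lambda t: (t[0], t[1]))
    nv = 1 << nb

    def chain_total(include_disease):
        pos = positions if include_disease else \
            [p for p in positions if p[1] == "M"]
        total = 0.0
        for vecs in product(range(nv), repeat=len(pos)):
            p = 1.0 / nv
            for t in range(1, len(pos)):
                p *= trans(vecs[t - 1], vecs[t],
                           haldane_theta(pos[t][0] - pos[t - 1][0]))
                if p == 0.0:
                    break
            for t, (c, kind, mi) in enumerate(pos):
                if p == 0.0:
                    break
                if kind == "M":
                    p *= marker_emission(vecs[t], mi)
                else:
                    p *= disease_emission(vecs[t])
            total += p
        return total

    num = chain_total(True)
    p_markers = chain_total(False)
    p_pheno = sum(disease_emission(v) for v in range(nv)) / nv
    return math.log10(num / (p_markers * p_pheno))


# ----------------------------------------------------------------------
# exact HWE tail via rational arithmetic


def hwe_exact_fraction(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    def weight(h):
        r = (rare - h) // 2
        return Fraction(comb(n, h) * comb(n - h, r) * 2 ** h)

    hs = list(range(rare % 2, rare + 1, 2))
    ws = {h: weight(h) for h in hs}
    total = sum(ws.values())
    obs = ws[n_ab]
    return float(sum(w for w in ws.values() if w <= obs) / total)


# ----------------------------------------------------------------------
# greedy LD pruning, naive reimplementation


def naive_ld_prune(dosage: np.ndarray, chroms, window: int, step: int,
                   ceiling: float, missing_frac: np.ndarray) -> list[int]:
    m = dosage.shape[1]
    removed = np.zeros(m, dtype=bool)

    def r2(i, j):
        x, y = dosage[:, i], dosage[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            return np.nan
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            return np.nan
        return np.corrcoef(xs, ys)[0, 1] ** 2

    for chrom in dict.fromkeys(chroms):
        idx = [k for k in range(m) if chroms[k] == chrom]
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            while True:
                live = [i for i in win if not removed[i]]
                hit = None
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        v = r2(live[a], live[b])
                        if not np.isnan(v) and v > ceiling:
                            hit = (live[a], live[b])
                            break
                    if hit:
                        break
                if hit is None:
                    break
                i, j = hit
                if missing_frac[i] > missing_frac[j]:
                    removed[i] = True
                elif missing_frac[j] > missing_frac[i]:
                    removed[j] = True
                else:
                    removed[max(i, j)] = True
    return [k for k in range(m) if not removed[k]]


# ----------------------------------------------------------------------
# Monte-Carlo tail of the eigenvalue chi-square mixture


def mc_mixture_tail(x: float, corr: np.ndarray, n_draws: int,
                    rng: np.random.Generator) -> tuple[float, float]:
    """(estimate, standard error) of P(sum_i chi2 from MVN(0, corr) > x)."""
    k = corr.shape[0]
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    hits = 0
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        z = rng.standard_normal((m, k)) @ chol.T
        hits += int(((z ** 2).sum(axis=1) > x).sum())
        done += m
    p = hits / n_draws
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return p, se
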