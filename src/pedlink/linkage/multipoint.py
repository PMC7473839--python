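"""Multipoint parametric linkage via the inheritance-vector HMM.

The hidden state at each map position is the inheritance vector: one bit
per meiosis recording which parental haplotype was transmitted.  One
meiosis per founder is fixed (founder-phase symmetry), giving
``2*nonfounders - founders`` informative bits; transitions between loci
factorise per bit with Haldane recombination fractions, marker emissions
sum over founder-allele assignments (computed with a union-find over
founder allele slots, compiled with numba), and the disease-locus
phenotype emission is computed once per pedigree by peeling conditional on
the vector.  Exact computation is bounded at ``MAX_BITS`` bits; larger
pedigrees must be split rather than silently approximated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ..simulate import haldane_theta
from ..types import (AFFECTED, MISSING, UNAFFECTED, DiseaseModel,
                     GenotypeTable, MarkerPanel, Pedigree, PedigreeLoopError)

MAX_BITS = 20


class PedigreeTooLargeError(ValueError):
    """Inheritance-vector space exceeds the exact-computation bound.

    Split the pedigree into sub-pedigrees (e.g. by branch) and combine the
    resulting LOD curves additively.
    """


# ----------------------------------------------------------------------
# inheritance-vector bookkeeping


class InheritanceModel:
    """Bit layout and founder-allele descent for one pedigree."""

    def __init__(self, pedigree: Pedigree, max_bits: int = MAX_BITS):
        if pedigree.has_loops():
            raise PedigreeLoopError(
                "pedigree contains loops; break them before multipoint analysis")
        self.pedigree = pedigree
        self.members = pedigree.topological_order()
        self.index = {iid: k for k, iid in enumerate(self.members)}
        founders = [i for i in self.members if pedigree[i].is_founder]
        self.founder_slot = {}
        for k, iid in enumerate(founders):
            self.founder_slot[iid] = 2 * k
        self.n_slots = 2 * len(founders)

        # Assign meiosis bits; the first meiosis out of each founder is fixed
        # (founder-phase symmetry).  The remaining meioses from that founder
        # are then phase-relative to the fixed one, so their transition
        # kernel is a mixture over the fixed meiosis' recombination state;
        # ``founder_bit_groups`` records which bits share a founder parent.
        self.bit_of: dict[tuple[str, int], int | None] = {}
        seen_founder: dict[str, list[int]] = {}
        nbits = 0
        for iid in self.members:
            ind = pedigree[iid]
            if ind.is_founder:
                continue
            for side, parent in ((0, ind.father), (1, ind.mother)):
                if pedigree[parent].is_founder and parent not in seen_founder:
                    seen_founder[parent] = []
                    self.bit_of[(iid, side)] = None  # fixed to 0
                else:
                    self.bit_of[(iid, side)] = nbits
                    if pedigree[parent].is_founder:
                        seen_founder[parent].append(nbits)
                    nbits += 1
        self.founder_bit_groups = [g for g in seen_founder.values() if g]
        grouped = {b for g in self.founder_bit_groups for b in g}
        self.free_bits = [b for b in range(nbits) if b not in grouped]
        self.n_bits = nbits
        if nbits > max_bits:
            raise PedigreeTooLargeError(
                f"{nbits} meiosis bits exceed the exact bound of {max_bits}; "
                "split the pedigree and add per-branch LOD curves")
        self.n_vectors = 1 << nbits

    # ------------------------------------------------------------------
    def bit_values(self, iid: str, side: int) -> np.ndarray:
        """Meiosis indicator for every inheritance vector (0/1 array)."""
        b = self.bit_of[(iid, side)]
        v = np.arange(self.n_vectors, dtype=np.int64)
        if b is None:
            return np.zeros(self.n_vectors, dtype=np.int8)
        return ((v >> b) & 1).astype(np.int8)

    def slot_arrays(self) -> np.ndarray:
        """Founder-slot of each person's (paternal, maternal) allele.

        Shape (n_vectors, n_members, 2), uint8.
        """
        nv = self.n_vectors
        slots = np.empty((nv, len(self.members), 2), dtype=np.uint8)
        for iid in self.members:
            k = self.index[iid]
            ind = self.pedigree[iid]
            if ind.is_founder:
                slots[:, k, 0] = self.founder_slot[iid]
                slots[:, k, 1] = self.founder_slot[iid] + 1
            else:
                for side, parent in ((0, ind.father), (1, ind.mother)):
                    bits = self.bit_values(iid, side)
                    pk = self.index[parent]
                    slots[:, k, side] = np.where(
                        bits, slots[:, pk, 1], slots[:, pk, 0])
        return slots


# ----------------------------------------------------------------------
# marker emissions (founder-allele sum via union-find with parity)


@njit(cache=True)
def _marker_emission_kernel(slots, geno, freqs, out):  # pragma: no cover
    nvec, npers = slots.shape[0], slots.shape[1]
    nmark = geno.shape[0]
    nslot = int(slots.max()) + 1
    V = nslot  # virtual node pinning allele 0
    parent = np.empty(nslot + 1, dtype=np.int16)
    parity = np.empty(nslot + 1, dtype=np.int8)
    n0 = np.empty(nslot + 1, dtype=np.int16)
    n1 = np.empty(nslot + 1, dtype=np.int16)
    for m in range(nmark):
        p = 1.0 - freqs[m]
        q = freqs[m]
        for v in range(nvec):
            for s in range(nslot + 1):
                parent[s] = s
                parity[s] = 0
            ok = True
            pa_a = np.empty(2, dtype=np.int64)
            pa_b = np.empty(2, dtype=np.int64)
            pa_p = np.empty(2, dtype=np.int64)
            for j in range(npers):
                g = geno[m, j]
                if g < 0:
                    continue
                sp = int(slots[v, j, 0])
                sm = int(slots[v, j, 1])
                if g == 1:
                    npairs = 1
                    pa_a[0] = sp; pa_b[0] = sm; pa_p[0] = 1
                else:
                    npairs = 2
                    allele = 0 if g == 0 else 1
                    pa_a[0] = sp; pa_b[0] = V; pa_p[0] = allele
                    pa_a[1] = sm; pa_b[1] = V; pa_p[1] = allele
                for pi in range(npairs):
                    a = pa_a[pi]
                    b = pa_b[pi]
                    par = pa_p[pi]
                    ra, pa = a, 0
                    while parent[ra] != ra:
                        pa ^= parity[ra]
                        ra = parent[ra]
                    rb, pb = b, 0
                    while parent[rb] != rb:
                        pb ^= parity[rb]
                        rb = parent[rb]
                    if ra == rb:
                        if (pa ^ pb) != par:
                            ok = False
                            break
                    else:
                        parent[rb] = ra
                        parity[rb] = pa ^ pb ^ par
                if not ok:
                    break
            if not ok:
                out[m, v] = 0.0
                continue
            # component products
            for s in range(nslot + 1):
                n0[s] = 0
                n1[s] = 0
            rv = V
            pv = 0
            while parent[rv] != rv:
                pv ^= parity[rv]
                rv = parent[rv]
            for s in range(nslot):
                r, pr = s, 0
                while parent[r] != r:
                    pr ^= parity[r]
                    r = parent[r]
                if pr == 0:
                    n0[r] += 1
                else:
                    n1[r] += 1
            prob = 1.0
            for r in range(nslot + 1):
                c0, c1 = n0[r], n1[r]
                if c0 + c1 == 0:
                    continue
                if r == rv:
                    # allele(s) = parity(s) xor pv
                    if pv == 0:
                        a0, a1 = c0, c1
                    else:
                        a0, a1 = c1, c0
                    term = (p ** a0) * (q ** a1)
                else:
                    term = (p ** c0) * (q ** c1) + (p ** c1) * (q ** c0)
                prob *= term
            out[m, v] = prob


def marker_emissions(im: InheritanceModel, table: GenotypeTable,
                     panel: MarkerPanel, markers: list[str]) -> np.ndarray:
    """P(observed genotypes | inheritance vector) per marker; (M, n_vectors)."""
    slots = im.slot_arrays()
    geno = np.full((len(markers), len(im.members)), -1, dtype=np.int8)
    for mi, m in enumerate(markers):
        col = table.col(m)
        for iid in table.ids:
            if iid not in im.index:
                continue
            a = table.alleles[table.row(iid), col]
            if a[0] != MISSING:
                geno[mi, im.index[iid]] = int(a[0]) + int(a[1])
    freqs = np.array([float(panel.table["freq"][panel.index_of(m)])
                      for m in markers])
    out = np.empty((len(markers), im.n_vectors))
    _marker_emission_kernel(slots, geno, freqs, out)
    return out


# ----------------------------------------------------------------------
# disease emission: peel phenotypes conditional on the inheritance vector


def disease_emission(im: InheritanceModel, model: DiseaseModel) -> np.ndarray:
    """P(phenotypes | inheritance vector), shape (n_vectors,).

    Individuals are peeled in reverse topological order; each person's
    state is its ordered pair of disease alleles (4 states) and, given the
    vector, transmission is a deterministic selection from the parents'
    alleles, implemented as a vectorised gather over all vectors at once.
    """
    ped = im.pedigree
    q = model.risk_allele_freq
    pen = np.asarray(model.penetrance_by_genotype)
    # state = 2*a_p + a_m; risk copies = a_p + a_m
    copies = np.array([0, 1, 1, 2])
    prior = np.array([(1 - q) * (1 - q), (1 - q) * q, q * (1 - q), q * q])
    nv = im.n_vectors

    def unary(iid):
        aff = ped[iid].affection
        if aff == AFFECTED:
            u = pen[copies]
        elif aff == UNAFFECTED:
            u = 1.0 - pen[copies]
        else:
            u = np.ones(4)
        return u

    factors: list[tuple[tuple, np.ndarray]] = []  # (vars, arr (nvec|1, 4, ...))
    for iid in im.members:
        u = unary(iid)
        if ped[iid].is_founder:
            u = u * prior
        factors.append(((iid,), u[None, :]))

    F = np.arange(4)[:, None]
    M = np.arange(4)[None, :]

    def combine(group):
        vars_ = []
        for vs, _ in group:
            vars_ += [v for v in vs if v not in vars_]
        arr = None
        for vs, a in group:
            pad = a.reshape(a.shape + (1,) * (len(vars_) - (a.ndim - 1)))
            perm = [0] + [1 + vars_.index(v) for v in vs] + \
                [1 + k for k, v in enumerate(vars_) if v not in vs]
            pad = np.transpose(pad, np.argsort(perm))
            arr = pad if arr is None else arr * pad
        return vars_, arr

    log_scale = 0.0
    scalar = np.ones(1)
    for iid in reversed(im.members):
        group = [f for f in factors if iid in f[0]]
        for f in group:
            factors.remove(f)
        vars_, arr = combine(group)
        ax = 1 + vars_.index(iid)
        ind = ped[iid]
        if ind.is_founder:
            new = arr.sum(axis=ax)
            new_vars = tuple(v for v in vars_ if v != iid)
        else:
            # gather: child state determined by parent states and meiosis bits
            bp = im.bit_values(iid, 0).astype(np.int64)
            bm = im.bit_values(iid, 1).astype(np.int64)
            tf = (F >> (1 - bp[:, None, None])) & 1
            tm = (M >> (1 - bm[:, None, None])) & 1
            idx = (2 * tf + tm)  # (nvec, 4, 4) child state per (father, mother)
            arr = np.moveaxis(arr, ax, 1)  # (nv?, child, extra...)
            if arr.shape[0] == 1 and idx.shape[0] > 1:
                arr = np.broadcast_to(arr, (idx.shape[0],) + arr.shape[1:])
            vrows = np.arange(arr.shape[0])[:, None, None]
            new = arr[vrows, idx]  # (nvec, 4, 4, extra...)
            new_vars = (ind.father, ind.mother) + tuple(
                v for v in vars_ if v != iid)
        if new_vars:
            peak = new.max()
            if peak > 0:
                new = new / peak
                log_scale += math.log(peak)
            factors.append((new_vars, new))
        else:
            scalar = scalar * new.reshape(-1)
    if scalar.shape[0] == 1:
        scalar = np.broadcast_to(scalar, (nv,)).copy()
    return scalar * math.exp(log_scale)


# ----------------------------------------------------------------------
# HMM machinery


def _apply_bits(y: np.ndarray, theta: float, axes) -> np.ndarray:
    for ax in axes:
        y = (1 - theta) * y + theta * np.flip(y, axis=ax)
    return y


def transition(x: np.ndarray, theta: float, im: InheritanceModel) -> np.ndarray:
    """Apply the inter-locus recombination kernel to a state distribution.

    Free meiosis bits recombine independently with probability ``theta``.
    Bits sharing a founder parent with that founder's fixed meiosis are
    phase-relative, so their kernel mixes over the fixed meiosis'
    (unobserved) recombination: with probability 1-theta the fixed strand
    did not recombine (relative bits flip at rate theta), with probability
    theta it did (relative bits flip at rate 1-theta).
    """
    n_bits = im.n_bits
    if n_bits == 0 or theta == 0.0:
        return x.copy()
    lead = x.shape[:-1]
    y = x.reshape(lead + (2,) * n_bits)
    off = len(lead)

    def axis(b):  # bit b is the b-th least-significant -> axis from the right
        return off + (n_bits - 1 - b)

    y = _apply_bits(y, theta, [axis(b) for b in im.free_bits])
    for group in im.founder_bit_groups:
        axes = [axis(b) for b in group]
        y = (1 - theta) * _apply_bits(y, theta, axes) \
            + theta * _apply_bits(y, 1 - theta, axes)
    return y.reshape(x.shape)


@dataclass
class LODCurve:
    """Multipoint LOD evaluations along one chromosome."""

    chrom: object
    bp: np.ndarray
    cm: np.ndarray
    lod: np.ndarray
    label: str = ""

    def peak(self) -> tuple[int, float]:
        k = int(np.argmax(self.lod))
        return k, float(self.lod[k])


def _log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def lod_multipoint(pedigree: Pedigree, panel: MarkerPanel, table: GenotypeTable,
                   model: DiseaseModel, chrom=None, window_size: int = 10,
                   step: int = 1, eval_midpoints: bool = True,
                   label: str = "", max_bits: int = MAX_BITS) -> LODCurve:
    """Windowed multipoint LOD curve for one chromosome.

    Markers are analysed in sliding windows of ``window_size`` (step
    ``step``); within a window the disease locus is evaluated at every
    marker position and, optionally, window midpoints, against the
    unlinked likelihood.  Where windows overlap, each position takes its
    value from the window whose centre is nearest.
    """
    tab = panel.table
    if chrom is None:
        chroms = panel.chromosomes()
        if len(chroms) != 1:
            raise ValueError("specify chrom for a multi-chromosome panel")
        chrom = chroms[0]
    idx = panel.chrom_indices(chrom)
    markers = [panel.markers[i] for i in idx]
    cms = tab["cm"].to_numpy()[idx]
    bps = tab["bp"].to_numpy()[idx]

    im = InheritanceModel(pedigree, max_bits=max_bits)
    nb, nv = im.n_bits, im.n_vectors
    emis = marker_emissions(im, table, panel, markers)
    e_dis = disease_emission(im, model)
    null_dis = float(e_dis.mean())  # uniform prior over vectors
    if null_dis <= 0:
        raise ValueError("phenotype configuration impossible under the model")

    m = len(markers)
    w = min(window_size, m)
    starts = list(range(0, m - w + 1, step))
    if starts[-1] != m - w:
        starts.append(m - w)

    best: dict[float, tuple[float, float, float]] = {}  # cm -> (dist, lod, bp)
    for s0 in starts:
        win = list(range(s0, s0 + w))
        center = 0.5 * (cms[win[0]] + cms[win[-1]])
        # forward (alpha includes emission at its marker) and backward passes
        alphas, logca = [], [0.0]
        x = np.full(nv, 1.0 / nv) * emis[win[0]]
        c = x.sum()
        if c <= 0:
            raise ValueError("marker data impossible (Mendelian error?)")
        alphas.append(x / c)
        for t in range(1, w):
            th = haldane_theta(cms[win[t]] - cms[win[t - 1]])
            x = transition(alphas[-1], th, im) * emis[win[t]]
            c2 = x.sum()
            alphas.append(x / c2)
            logca.append(logca[-1] + _log(c2))
        log_markers = _log(c) + logca[-1]

        betas = [None] * w
        logcb = [0.0] * w
        betas[w - 1] = np.ones(nv)
        for t in range(w - 2, -1, -1):
            th = haldane_theta(cms[win[t + 1]] - cms[win[t]])
            x = transition(betas[t + 1] * emis[win[t + 1]], th, im)
            c2 = x.max()
            betas[t] = x / c2
            logcb[t] = logcb[t + 1] + _log(c2)

        def record(pos_cm, pos_bp, loglike):
            lod = (loglike - (log_markers + _log(null_dis))) / math.log(10)
            d = abs(pos_cm - center)
            cur = best.get(pos_cm)
            if cur is None or d < cur[0]:
                best[pos_cm] = (d, lod, pos_bp)

        for t in range(w):
            val = float((alphas[t] * e_dis * betas[t]).sum())
            ll = _log(val) + _log(c) + logca[t] + logcb[t]
            record(float(cms[win[t]]), float(bps[win[t]]), ll)
        if eval_midpoints:
            for t in range(w - 1):
                dmid = 0.5 * (cms[win[t + 1]] - cms[win[t]])
                th = haldane_theta(dmid)
                a_mid = transition(alphas[t], th, im)
                b_mid = transition(betas[t + 1] * emis[win[t + 1]], th, im)
                val = float((a_mid * e_dis * b_mid).sum())
                ll = _log(val) + _log(c) + logca[t] + logcb[t + 1]
                record(float(0.5 * (cms[win[t]] + cms[win[t + 1]])),
                       float(0.5 * (bps[win[t]] + bps[win[t + 1]])), ll)

    pos = sorted(best)
    return LODCurve(chrom,
                    np.array([best[p][2] for p in pos]),
                    np.array(pos),
                    np.array([best[p][1] for p in pos]),
                    label=label)


def combine_curves(curves: list[LODCurve], label: str = "") -> LODCurve:
    """Sum per-family LOD curves at identical positions (locus homogeneity)."""
    base = curves[0]
    for c in curves[1:]:
        if c.chrom != base.chrom or not np.allclose(c.cm, base.cm):
            raise ValueError("curves evaluated on different position grids")
    total = np.sum([c.lod for c in curves], axis=0)
    return LODCurve(base.chrom, base.bp.copy(), base.cm.copy(), total,
                    label=label or "+".join(c.label for c in curves))
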