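"""Haplotype reconstruction within a linkage region.

Finds the maximum-likelihood inheritance-vector path across the region's
markers (Viterbi over the inheritance HMM) and then assigns founder
alleles per marker by maximum likelihood.  Positions where the founder
allele is not pinned down by the data are flagged as ambiguous.

Dense Viterbi transition matrices limit this to pedigrees with at most
``MAX_VITERBI_BITS`` meiosis bits; larger pedigrees should be split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..simulate import haldane_theta
from ..types import MISSING, GenotypeTable, MarkerPanel, Pedigree
from .multipoint import (InheritanceModel, PedigreeTooLargeError,
                         marker_emissions, transition)

MAX_VITERBI_BITS = 12


def _dense_transition(im: InheritanceModel, theta: float) -> np.ndarray:
    """Row-stochastic inter-locus transition matrix (rows = source state)."""
    return transition(np.eye(im.n_vectors), theta, im)


def _assign_founder_alleles(slots: np.ndarray, geno: np.ndarray, freq: float,
                            n_slots: int) -> tuple[np.ndarray, np.ndarray]:
    """ML founder-slot alleles for one marker given a fixed vector.

    ``slots`` is (n_persons, 2); ``geno`` per-person coded -1/0/1/2.
    Returns (alleles per slot, ambiguous flag per slot).
    """
    parent = list(range(n_slots + 1))
    parity = [0] * (n_slots + 1)
    V = n_slots

    def find(x):
        p = 0
        while parent[x] != x:
            p ^= parity[x]
            x = parent[x]
        return x, p

    def union(a, b, par):
        ra, pa = find(a)
        rb, pb = find(b)
        if ra == rb:
            if (pa ^ pb) != par:
                raise ValueError("genotypes inconsistent with inheritance vector")
            return
        parent[rb] = ra
        parity[rb] = pa ^ pb ^ par

    for j in range(len(geno)):
        g = geno[j]
        if g < 0:
            continue
        sp, sm = int(slots[j, 0]), int(slots[j, 1])
        if g == 1:
            union(sp, sm, 1)
        else:
            allele = 0 if g == 0 else 1
            union(sp, V, allele)
            union(sm, V, allele)

    rv, pv = find(V)
    comp: dict[int, list[tuple[int, int]]] = {}
    for s in range(n_slots):
        r, p = find(s)
        comp.setdefault(r, []).append((s, p))

    alleles = np.zeros(n_slots, dtype=np.int8)
    ambiguous = np.zeros(n_slots, dtype=bool)
    p0, p1 = 1 - freq, freq
    for r, members in comp.items():
        if r == rv:
            for s, p in members:
                alleles[s] = p ^ pv
        else:
            n0 = sum(1 for _, p in members if p == 0)
            n1 = len(members) - n0
            like_a = (p0 ** n0) * (p1 ** n1)   # parity-0 slots get allele 0
            like_b = (p0 ** n1) * (p1 ** n0)
            pick = 0 if like_a >= like_b else 1
            for s, p in members:
                alleles[s] = p ^ pick
                ambiguous[s] = True
    return alleles, ambiguous


def reconstruct_haplotypes(pedigree: Pedigree, panel: MarkerPanel,
                           table: GenotypeTable,
                           markers: list[str] | None = None) -> pd.DataFrame:
    """Most-likely ordered haplotypes for every pedigree member.

    Returns a tidy frame with one row per (individual, marker): columns
    iid, marker, allele_paternal, allele_maternal, ambiguous.  Alleles are
    0/1 codes against the panel's (a1, a2).
    """
    markers = markers or panel.markers
    sub = panel.subset([panel.index_of(m) for m in markers])
    if len(sub.chromosomes()) != 1:
        raise ValueError("haplotype reconstruction works per chromosome")
    im = InheritanceModel(pedigree, max_bits=MAX_VITERBI_BITS)
    nb, nv = im.n_bits, im.n_vectors
    emis = marker_emissions(im, table, panel, markers)
    cms = sub.table["cm"].to_numpy()
    freqs = sub.table["freq"].to_numpy()

    with np.errstate(divide="ignore"):
        log_emis = np.log(emis)
    delta = np.full(nv, -np.log(nv)) + log_emis[0]
    back = np.zeros((len(markers), nv), dtype=np.int64)
    for t in range(1, len(markers)):
        theta = haldane_theta(cms[t] - cms[t - 1])
        with np.errstate(divide="ignore"):
            logT = np.log(_dense_transition(im, theta))
        scores = delta[:, None] + logT
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(nv)] + log_emis[t]
    if not np.isfinite(delta.max()):
        raise ValueError("marker data impossible on every inheritance vector")
    path = np.empty(len(markers), dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(len(markers) - 1, 0, -1):
        path[t - 1] = back[t, path[t]]

    slots_all = im.slot_arrays()
    geno = np.full((len(markers), len(im.members)), -1, dtype=np.int8)
    for mi, m in enumerate(markers):
        col = table.col(m)
        for iid in table.ids:
            if iid in im.index:
                a = table.alleles[table.row(iid), col]
                if a[0] != MISSING:
                    geno[mi, im.index[iid]] = int(a[0]) + int(a[1])

    rows = []
    for mi, m in enumerate(markers):
        v = path[mi]
        slots = slots_all[v]
        alleles, amb = _assign_founder_alleles(slots, geno[mi], float(freqs[mi]),
                                               im.n_slots)
        for iid in im.members:
            k = im.index[iid]
            sp, sm = int(slots[k, 0]), int(slots[k, 1])
            rows.append({
                "iid": iid, "marker": m,
                "allele_paternal": int(alleles[sp]),
                "allele_maternal": int(alleles[sm]),
                "ambiguous": bool(amb[sp] or amb[sm]),
            })
    return pd.DataFrame(rows)
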