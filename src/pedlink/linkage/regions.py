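"""Candidate-region selection from LOD curves.

A region is a maximal contiguous run of evaluations reaching the selection
threshold (default LOD >= 2); its boundaries are the 1-LOD support
interval around the run's peak, clipped at chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multipoint import LODCurve

SELECTION_THRESHOLD = 2.0
SIGNIFICANCE_THRESHOLD = 3.3


@dataclass
class LinkageRegion:
    chrom: object
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_cm: float
    peak_lod: float
    families: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.start_bp <= self.peak_bp <= self.end_bp:
            raise ValueError("region peak outside its bounds")

    def contains(self, chrom, bp: int, pad: int = 0) -> bool:
        return (chrom == self.chrom
                and self.start_bp - pad <= bp <= self.end_bp + pad)

    @property
    def tag(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


def one_lod_interval(curve: LODCurve, peak_index: int) -> tuple[int, int]:
    """Index bounds of the 1-LOD support interval around a local peak.

    Extends from the peak in each direction while the score stays within
    one LOD unit of the peak, stopping at the first drop below peak - 1
    (a shoulder re-crossing the cutoff further out is not rejoined) and
    clipping at the chromosome ends.
    """
    lod = curve.lod
    peak = lod[peak_index]
    lo = peak_index
    while lo > 0 and lod[lo - 1] >= peak - 1.0:
        lo -= 1
    hi = peak_index
    while hi < len(lod) - 1 and lod[hi + 1] >= peak - 1.0:
        hi += 1
    return lo, hi


def select_regions(curves: list[LODCurve],
                   threshold: float = SELECTION_THRESHOLD) -> list[LinkageRegion]:
    """Candidate regions from one or more (family or combined) LOD curves.

    Each maximal contiguous run of evaluations with LOD >= threshold
    yields one region whose bounds come from the 1-LOD interval around the
    run peak; the contributing family label is taken from the curve.
    """
    regions = []
    for curve in curves:
        above = curve.lod >= threshold
        k = 0
        n = len(above)
        while k < n:
            if not above[k]:
                k += 1
                continue
            j = k
            while j + 1 < n and above[j + 1]:
                j += 1
            run_peak = k + int(np.argmax(curve.lod[k:j + 1]))
            lo, hi = one_lod_interval(curve, run_peak)
            families = tuple(curve.label.split("+")) if curve.label else ()
            regions.append(LinkageRegion(
                curve.chrom, int(curve.bp[lo]), int(curve.bp[hi]),
                int(curve.bp[run_peak]), float(curve.cm[run_peak]),
                float(curve.lod[run_peak]), families))
            k = j + 1
    return regions


def regions_frame(regions: list[LinkageRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": r.tag, "chrom": r.chrom, "start_bp": r.start_bp,
        "end_bp": r.end_bp, "peak_bp": r.peak_bp, "peak_lod": r.peak_lod,
        "families": "+".join(r.families),
    } for r in regions])
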