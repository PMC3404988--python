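"""Electropherogram peak QC, T-RF assignment and relative-abundance profiling.

A fragment-analysis run yields, per sample, a chromatogram quality value
(QV) and a table of peaks (called fragment size in bp, fluorescence height).
Chromatograms with QV <= 75 are discarded; fragments outside 100-1200 bp are
treated as noise.  Surviving peaks are matched to in silico predicted T-RF
lengths within a size tolerance and converted to relative abundances,

    RA(%) = H_TRF / H_total * 100,

where H_total by default includes unassigned peaks (reported as an
"unassigned" percentage so each profile sums to 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedProfileError
from .seqlib import TRFPrediction

#: Default thresholds: quality value cutoff (strictly greater retained) and
#: the size window outside which peaks are considered noise.
QV_MIN = 75.0
SIZE_MIN = 100.0
SIZE_MAX = 1200.0
#: Default size-match tolerance (bp) between an observed and a predicted T-RF.
SIZE_TOLERANCE = 1.5


@dataclass(frozen=True)
class Peak:
    """One electropherogram peak: called size (bp) and fluorescence height."""

    size: float
    height: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise InputError(f"peak size must be positive, got {self.size}")
        if self.height < 0:
            raise InputError(f"peak height must be non-negative, got {self.height}")


@dataclass(frozen=True)
class Chromatogram:
    """Per-sample electropherogram: QV, collection month and peak list."""

    sample_id: str
    collection_month: str
    qv: float
    peaks: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        if self.qv < 0:
            raise InputError(f"QV must be non-negative, got {self.qv}")
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass(frozen=True)
class Profile:
    """Per-sample relative-abundance vector over T-RF categories (percent)."""

    sample_id: str
    collection_month: str
    ra: dict[str, float]
    unassigned_pct: float

    def __post_init__(self) -> None:
        total = sum(self.ra.values()) + self.unassigned_pct
        if abs(total - 100.0) > 1e-9:
            raise InputError(f"profile percentages sum to {total}, expected 100")
        if any(not 0 <= v <= 100 for v in self.ra.values()):
            raise InputError("relative abundances must lie in [0, 100]")


def qc_chromatogram(
    chrom: Chromatogram,
    qv_min: float = QV_MIN,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
) -> Optional[Chromatogram]:
    """Apply quality filtering; returns None when the chromatogram is rejected.

    The whole chromatogram is rejected unless QV is strictly greater than
    ``qv_min``; surviving peaks must satisfy size_min <= size <= size_max.
    """
    if not chrom.qv > qv_min:
        return None
    kept = tuple(p for p in chrom.peaks if size_min <= p.size <= size_max)
    return replace(chrom, peaks=kept)


@dataclass(frozen=True)
class PeakAssignment:
    """A peak with its category label (None if unassigned) and ambiguity flag."""

    peak: Peak
    category: Optional[str]
    ambiguous: bool = False


def assign_peaks(
    chrom: Chromatogram,
    predictions: Sequence[TRFPrediction],
    tolerance: float = SIZE_TOLERANCE,
) -> list[PeakAssignment]:
    """Match each peak to the nearest predicted T-RF within ``tolerance`` bp.

    A category with several predicted lengths (e.g. the two-subtype clade)
    matches on any of them and accumulates into one label.  A peak exactly
    equidistant from two different categories is flagged ambiguous and left
    unassigned; peaks with no prediction within tolerance are unassigned.
    Deterministic and independent of peak order.
    """
    if not predictions:
        raise InputError("empty prediction list")
    targets = [(l, p.category_label) for p in predictions for l in sorted(p.trf_lengths)]
    out = []
    for peak in chrom.peaks:
        dists = [(abs(peak.size - l), cat) for l, cat in targets]
        dmin = min(d for d, _ in dists)
        if dmin > tolerance:
            out.append(PeakAssignment(peak, None))
            continue
        winners = {cat for d, cat in dists if abs(d - dmin) <= 1e-9}
        if len(winners) > 1:
            out.append(PeakAssignment(peak, None, ambiguous=True))
        else:
            out.append(PeakAssignment(peak, winners.pop()))
    return out


def relative_abundance(
    chrom: Chromatogram,
    assignments: Sequence[PeakAssignment],
    include_unassigned_in_total: bool = True,
) -> Profile:
    """Convert assigned peak heights into a percent relative-abundance profile.

    By default H_total is the total height of all retained peaks, so
    unassigned peaks appear as ``unassigned_pct``; with
    ``include_unassigned_in_total=False`` they are dropped from the
    denominator and the assigned categories alone sum to 100.
    """
    if include_unassigned_in_total:
        pool = list(assignments)
    else:
        pool = [a for a in assignments if a.category is not None]
    total = sum(a.peak.height for a in pool)
    if total <= 0:
        raise UndefinedProfileError(
            f"sample {chrom.sample_id!r}: total peak height is zero"
        )
    ra: dict[str, float] = {}
    unassigned = 0.0
    for a in pool:
        pct = a.peak.height / total * 100.0
        if a.category is None:
            unassigned += pct
        else:
            ra[a.category] = ra.get(a.category, 0.0) + pct
    return Profile(
        sample_id=chrom.sample_id,
        collection_month=chrom.collection_month,
        ra=ra,
        unassigned_pct=unassigned,
    )


def profile_chromatogram(
    chrom: Chromatogram,
    predictions: Sequence[TRFPrediction],
    tolerance: float = SIZE_TOLERANCE,
    qv_min: float = QV_MIN,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
    include_unassigned_in_total: bool = True,
) -> Optional[Profile]:
    """QC -> peak assignment -> relative abundance; None if QC rejects."""
    qcd = qc_chromatogram(chrom, qv_min=qv_min, size_min=size_min, size_max=size_max)
    if qcd is None:
        return None
    assignments = assign_peaks(qcd, predictions, tolerance=tolerance)
    return relative_abundance(
        qcd, assignments, include_unassigned_in_total=include_unassigned_in_total
    )


#: Months with fewer profiles than this are flagged low-n in summaries.
LOW_N = 3

#: Quartile convention used by aggregate_by_month, reported in metadata.
QUARTILE_METHOD = "linear"


def aggregate_by_month(
    profiles: Iterable[Profile],
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Per-month, per-category five-number summaries of relative abundance.

    A profile that lacks a category observed elsewhere contributes 0% for
    it.  Returns (summary frame, metadata); metadata records the quartile
    convention (linear interpolation between order statistics) and the low-n
    threshold.  Months with fewer than three profiles are flagged ``low_n``.
    """
    profiles = list(profiles)
    meta = {"quartile_method": QUARTILE_METHOD, "low_n_threshold": LOW_N}
    columns = ["month", "category", "n", "low_n", "min", "q1", "median", "q3", "max"]
    if not profiles:
        return pd.DataFrame(columns=columns), meta
    categories = sorted({c for p in profiles for c in p.ra})
    rows = []
    for p in profiles:
        for c in categories:
            rows.append((p.collection_month, c, p.ra.get(c, 0.0)))
        rows.append((p.collection_month, "unassigned", p.unassigned_pct))
    long = pd.DataFrame(rows, columns=["month", "category", "ra"])
    out = []
    for (month, cat), grp in long.groupby(["month", "category"], sort=True):
        v = grp["ra"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        out.append(
            {
                "month": month,
                "category": cat,
                "n": len(v),
                "low_n": len(v) < LOW_N,
                "min": float(v.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(out, columns=columns), meta
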