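"""Junction filtering by offset entropy, average mismatches, intron length.

Annotated junctions are treated as a trusted positive set: plotting their
offset entropy against mean mismatches, and their intron-length histogram,
motivates three per-junction filters that together discard poorly supported
putative junctions (read stacks, high-mismatch alignments, short deletions
masquerading as introns) while retaining most of the annotated set:

* entropy >= ``entropy_min`` (default 0.75),
* average mismatches <= ``mismatch_max`` (default 1.5 for 75 bp single-end
  libraries, 1.0 for 2x50 bp paired-end),
* intron length >= ``intron_min`` (default 50 nt, the lower bound of known
  intron sizes; shorter gaps are more likely small deletions).

The 0.75 entropy threshold presumes log base 2: under natural log a junction
supported equally at just two offsets scores ln 2 ~ 0.693 and would always
fail, which is inconsistent with retaining ~75% of annotated junctions.  The
base is configurable in the catalog module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import JunctionKey, JunctionStats

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "apply_filters",
    "calibration_profiles",
    "CalibrationProfiles",
    "suggest_thresholds",
]

RULES = ("entropy", "mismatch", "intron_length")


@dataclass(frozen=True)
class FilterThresholds:
    entropy_min: float = 0.75
    mismatch_max: float = 1.5
    intron_min: int = 50

    def __post_init__(self):
        if self.entropy_min < 0 or self.mismatch_max < 0 or self.intron_min < 0:
            raise ValueError("thresholds must be nonnegative")

    @classmethod
    def single_end(cls) -> "FilterThresholds":
        return cls(entropy_min=0.75, mismatch_max=1.5, intron_min=50)

    @classmethod
    def paired_end(cls) -> "FilterThresholds":
        return cls(entropy_min=0.75, mismatch_max=1.0, intron_min=50)


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_first_fail: dict   # rule -> count, partitions the removed set
    failed_any: dict           # rule -> count, a junction may fail several
    retention_annotated: float | None = None
    retention_novel: float | None = None

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def _passes(st: JunctionStats, thr: FilterThresholds) -> tuple[bool, bool, bool]:
    return (
        st.entropy >= thr.entropy_min,
        st.avg_mismatch <= thr.mismatch_max,
        st.intron_length >= thr.intron_min,
    )


def apply_filters(
    stats: Mapping[JunctionKey, JunctionStats],
    thresholds: FilterThresholds = FilterThresholds(),
    classes: Mapping[JunctionKey, str] | None = None,
) -> tuple[set, FilterReport]:
    """Retain junctions passing all three predicates.

    A junction is retained iff entropy >= entropy_min AND avg_mismatch <=
    mismatch_max AND intron_length >= intron_min.  The report attributes each
    removed junction to its first failing rule (a partition) and separately
    tallies every failed rule.  When ``classes`` is given (values from the
    annotation module), per-class retention fractions are reported:
    annotated vs all novel sub-classes pooled.
    """
    retained: set[JunctionKey] = set()
    first_fail = dict.fromkeys(RULES, 0)
    any_fail = dict.fromkeys(RULES, 0)
    kept_by_class = {"annotated": 0, "novel": 0}
    total_by_class = {"annotated": 0, "novel": 0}
    for key, st in stats.items():
        ok = _passes(st, thresholds)
        keep = all(ok)
        if keep:
            retained.add(key)
        else:
            for rule, passed in zip(RULES, ok):
                if not passed:
                    any_fail[rule] += 1
            first_fail[RULES[ok.index(False)]] += 1
        if classes is not None:
            group = "annotated" if classes.get(key) == "annotated" else "novel"
            total_by_class[group] += 1
            kept_by_class[group] += keep
    report = FilterReport(
        n_input=len(stats),
        n_retained=len(retained),
        removed_first_fail=first_fail,
        failed_any=any_fail,
    )
    if classes is not None:
        for group, attr in (("annotated", "retention_annotated"), ("novel", "retention_novel")):
            if total_by_class[group]:
                setattr(report, attr, kept_by_class[group] / total_by_class[group])
    return retained, report


@dataclass
class CalibrationProfiles:
    """Annotated-vs-novel views used to choose thresholds by inspection."""

    annotated_points: list    # (entropy, avg_mismatch) per annotated junction
    novel_points: list
    annotated_length_hist: tuple  # (counts, bin_edges)
    novel_length_hist: tuple


def calibration_profiles(
    stats: Mapping[JunctionKey, JunctionStats],
    classes: Mapping[JunctionKey, str],
    length_bins=None,
) -> CalibrationProfiles:
    """Split junctions into annotated and novel point sets plus
    intron-length histograms, ready for scatter/histogram plotting."""
    ann_pts, nov_pts, ann_len, nov_len = [], [], [], []
    for key, st in stats.items():
        if classes.get(key) == "annotated":
            ann_pts.append((st.entropy, st.avg_mismatch))
            ann_len.append(st.intron_length)
        else:
            nov_pts.append((st.entropy, st.avg_mismatch))
            nov_len.append(st.intron_length)
    if length_bins is None:
        upper = max(ann_len + nov_len, default=1000)
        length_bins = np.linspace(0, max(upper, 1), 51)
    ann_hist = np.histogram(ann_len, bins=length_bins)
    nov_hist = np.histogram(nov_len, bins=length_bins)
    return CalibrationProfiles(ann_pts, nov_pts, ann_hist, nov_hist)


def _nearest_rank(sorted_values: Sequence[float], q: float, ceil: bool = False) -> float:
    """Nearest-rank quantile: element at index floor(q * (n - 1)).

    The mismatch criterion keeps values *below* its threshold, so its
    quantile index rounds up instead; with floor-rounding a sample like
    {0, 1} at retention 0.75 would yield threshold 0 and retain only half.
    """
    pos = q * (len(sorted_values) - 1)
    idx = math.ceil(pos) if ceil else math.floor(pos)
    return sorted_values[idx]


def suggest_thresholds(
    annotated_stats: Iterable[JunctionStats],
    retention: float,
    intron_min: int = 50,
) -> FilterThresholds:
    """Mechanized threshold calibration from the annotated set.

    Picks ``entropy_min`` as the lower (1 - retention)-quantile of annotated
    entropies and ``mismatch_max`` as the retention-quantile of annotated
    mean mismatches (nearest-rank on the sorted sample), so that each single
    criterion retains at least ``retention`` of the annotated junctions.
    ``retention=1.0`` reduces to min entropy / max mismatch.
    """
    stats = list(annotated_stats)
    if len(stats) < 2:
        raise ValueError("need at least 2 annotated junctions to calibrate")
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    entropies = sorted(s.entropy for s in stats)
    mismatches = sorted(s.avg_mismatch for s in stats)
    return FilterThresholds(
        entropy_min=_nearest_rank(entropies, 1.0 - retention),
        mismatch_max=_nearest_rank(mismatches, retention, ceil=True),
        intron_min=intron_min,
    )
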