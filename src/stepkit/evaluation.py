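"""Tolerance-window scoring and clinical plausibility analyses.

Detected step times are matched one-to-one to reference times under a
+/-0.3 s tolerance window (the default accounts for the human reaction delay
of manual annotation).  Matching is greedy leftmost pairing over the two
sorted sequences, which attains the maximum matching cardinality for a
uniform window on a line; precision, recall, and F1 follow the usual
definitions with the 0/0 -> 0 convention so degenerate detector outputs are
penalized instead of crashing batch runs.

The module also implements two screens used when no ground truth exists,
e.g. on archival clinical Timed Up and Go (TUG) recordings: a plausibility
screen (is the step count inside a physiologically credible range, 4-20
steps for a TUG by default) and bilateral consistency (absolute step-count
difference between paired left/right sensors).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "MatchResult",
    "PlausibilitySummary",
    "match_steps",
    "prf",
    "plausibility_screen",
    "bilateral_consistency",
    "summary_table",
    "format_summary_text",
]


@dataclass
class MatchResult:
    """Outcome of matching one detection list against one reference list."""

    tp: int
    fp: int
    fn: int
    pairs: list
    precision: float
    recall: float
    f1: float
    tolerance_s: float


@dataclass
class PlausibilitySummary:
    """Nearest-rank percentile summary of step counts with a plausible-range rate."""

    n: int
    median: float
    p10: float
    p90: float
    p99: float
    pct_plausible: float
    range: tuple


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, and F1 from match counts (0/0 convention -> 0)."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("match counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _check_sorted(x: np.ndarray, name: str) -> None:
    if x.size > 1 and np.any(np.diff(x) < 0):
        raise ValidationError(f"{name} times must be sorted")


def match_steps(
    detected: Sequence[float],
    reference: Sequence[float],
    tolerance_s: float = 0.3,
) -> MatchResult:
    """Match detections to references within ``tolerance_s`` (one-to-one).

    Greedy leftmost pairing over the sorted sequences: advance through both
    lists, pairing the current detection and reference whenever they lie
    within the window, otherwise advancing whichever is earlier.  For a
    uniform window this greedy scheme is optimal (maximum cardinality), a
    property the test suite verifies against exhaustive search.
    """
    if not tolerance_s > 0:
        raise ValidationError("tolerance_s must be positive")
    d = np.asarray(detected, dtype=float)
    r = np.asarray(reference, dtype=float)
    _check_sorted(d, "detected")
    _check_sorted(r, "reference")

    pairs: list[tuple[float, float]] = []
    i = j = 0
    while i < d.size and j < r.size:
        if abs(d[i] - r[j]) <= tolerance_s:
            pairs.append((float(d[i]), float(r[j])))
            i += 1
            j += 1
        elif d[i] < r[j]:
            i += 1
        else:
            j += 1
    tp = len(pairs)
    fp = int(d.size) - tp
    fn = int(r.size) - tp
    precision, recall, f1 = prf(tp, fp, fn)
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        pairs=pairs,
        precision=precision,
        recall=recall,
        f1=f1,
        tolerance_s=tolerance_s,
    )


def _nearest_rank(counts: np.ndarray, q: float) -> float:
    return float(np.percentile(counts, q, method="inverted_cdf"))


def plausibility_screen(
    counts: Iterable[int], lo: int = 4, hi: int = 20
) -> PlausibilitySummary:
    """Summarize step counts and the share inside the plausible range.

    The default range 4-20 steps fits a Timed Up and Go trial: the lower
    bound flags near-zero detector failures, the upper accommodates short
    strides over the 6 m walked.  Bounds are inclusive.  Percentiles use the
    nearest-rank method, so summaries of integer counts stay integers.
    """
    c = np.asarray(list(counts))
    if c.size == 0:
        raise ValidationError("plausibility screen needs at least one count")
    if np.any(c < 0):
        raise ValidationError("step counts must be nonnegative")
    if lo > hi:
        raise ValidationError("plausible range must satisfy lo <= hi")
    in_range = np.count_nonzero((c >= lo) & (c <= hi))
    return PlausibilitySummary(
        n=int(c.size),
        median=_nearest_rank(c, 50),
        p10=_nearest_rank(c, 10),
        p90=_nearest_rank(c, 90),
        p99=_nearest_rank(c, 99),
        pct_plausible=100.0 * in_range / c.size,
        range=(lo, hi),
    )


def bilateral_consistency(
    left_counts: Sequence[int], right_counts: Sequence[int]
) -> tuple[float, float]:
    """Mean and sample SD of |left - right| step counts over paired sensors.

    A single pair has no sample SD; it is reported as 0 with a warning.
    """
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValidationError("left and right count lists must have equal length")
    if left.size == 0:
        raise ValidationError("bilateral consistency needs at least one pair")
    diffs = np.abs(left - right)
    if diffs.size == 1:
        _warnings.warn(
            "single sensor pair: sample SD is undefined, reporting 0", stacklevel=2
        )
        return float(diffs[0]), 0.0
    return float(diffs.mean()), float(diffs.std(ddof=1))


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------


def summary_table(
    counts_by_algorithm: dict, lo: int = 4, hi: int = 20
) -> pd.DataFrame:
    """Per-algorithm plausibility summary (Median/P10/P90/P99/% plausible)."""
    rows = []
    for name, counts in counts_by_algorithm.items():
        s = plausibility_screen(counts, lo=lo, hi=hi)
        rows.append(
            {
                "algorithm": name,
                "n": s.n,
                "median": s.median,
                "p10": s.p10,
                "p90": s.p90,
                "p99": s.p99,
                "pct_plausible": round(s.pct_plausible, 1),
            }
        )
    return pd.DataFrame(rows)


def format_summary_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`summary_table` output."""
    return table.to_string(index=False)
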