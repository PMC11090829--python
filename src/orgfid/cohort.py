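"""Secondary cohort statistics.

Marker-redundancy correlations (does CD10/SMA/p63 area track K14 area, or
K18/ERa track K8?), positive-cell fractions (ERa, Ki67, cleaved
caspase-3), fold-changes, and treated-vs-control organoid-area responses.
Group comparisons use the two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, UndefinedStatisticError

#: Combined-sample-size cutoff below which the exact Mann-Whitney null
#: distribution is enumerated; larger samples use the tie-corrected normal
#: approximation.
EXACT_MW_MAX_N = 16


@dataclass
class MarkerPairResult:
    marker_x: str
    marker_y: str
    measure: str  # "area" | "count"
    r: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    statistic: float
    p_value: float
    fold_change: float
    n_a: int
    n_b: int


def marker_correlation(
    pairs: Sequence[tuple[float, float]],
    marker_x: str,
    marker_y: str,
    measure: str = "area",
) -> MarkerPairResult:
    """Pearson correlation between paired per-section marker measurements.

    "Linear correlation" here is the product-moment coefficient; a strong
    positive r indicates the two markers carry redundant information.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ConfigurationError("need >= 3 finite (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("non-finite measurement in input")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"correlation undefined: zero variance in {marker_x!r} or {marker_y!r}"
        )
    res = stats.pearsonr(x, y)
    return MarkerPairResult(
        marker_x=marker_x,
        marker_y=marker_y,
        measure=measure,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=arr.shape[0],
    )


def positive_cell_fraction(positive: int, total: int) -> float:
    """Fraction of counted cells positive for a nuclear marker."""
    if total < 1:
        raise UndefinedStatisticError("fraction undefined for total = 0")
    if not 0 <= positive <= total:
        raise ConfigurationError(f"positive={positive} outside [0, total={total}]")
    return positive / total


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    use_median: bool = False,
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of two measurement groups.

    The exact null distribution is enumerated when the combined sample is
    small (<= 16) and tie-free; otherwise the tie-corrected normal
    approximation is used.  ``fold_change`` is mean(b)/mean(a) (medians via
    ``use_median``).  Fully tied data yield p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ConfigurationError("both groups must be non-empty")
    center = np.median if use_median else np.mean
    ca, cb = float(center(a)), float(center(b))
    fold = cb / ca if ca != 0 else float("inf")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        warnings.warn("all observations tied; p-value is 1", stacklevel=2)
        return GroupComparison(
            label_a=label_a,
            label_b=label_b,
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            fold_change=fold,
            n_a=a.size,
            n_b=b.size,
        )
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        fold_change=fold,
        n_a=a.size,
        n_b=b.size,
    )


def area_response(
    treated: Sequence[float],
    control: Sequence[float],
    label_treated: str = "treated",
    label_control: str = "control",
) -> GroupComparison:
    """Drug response of organoid cross-sectional area, control-normalized.

    Both groups are divided by the control mean, so the control normalizes
    to 1 and ``fold_change`` reads directly as the surviving area fraction
    under treatment.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 1 or control.size < 1:
        raise ConfigurationError("both groups must be non-empty")
    ctrl_mean = float(np.mean(control))
    if ctrl_mean <= 0:
        raise ConfigurationError("control mean must be > 0 for normalization")
    return group_compare(
        control / ctrl_mean,
        treated / ctrl_mean,
        label_a=label_control,
        label_b=label_treated,
    )
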