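"""Agreement statistics: trapezoid AUC, Bland-Altman, paired t, percent difference.

These implement the direct (area under the input curve) and indirect (Ki)
comparisons between an invasively measured reference and a model-computed
quantity.  Differences are oriented as computed minus experimental
throughout, so a positive mean difference means the model overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .expsum import ExpPolySum

__all__ = [
    "PairedMeasurements",
    "BlandAltmanReport",
    "auc_trapezoid",
    "bland_altman",
    "paired_t",
    "pointwise_percent_difference",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Experimental (x) vs computed (y) values in the same units."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.size < 1:
            raise ValueError("x and y must be equal-length 1-D arrays with >= 1 pair")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("paired measurements must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BlandAltmanReport:
    mean_diff: float
    sd_diff: float
    loa_low: float   # mean_diff - 1.96 * sd_diff
    loa_high: float  # mean_diff + 1.96 * sd_diff
    pct_within: float
    mean_pct_diff: float

    def as_dict(self) -> dict:
        return asdict(self)


def auc_trapezoid(times, values, t_range: tuple[float, float] | None = None) -> float:
    """Composite trapezoid area of a sampled curve over a time range.

    Accepts either sampled ``(times, values)`` arrays or an analytic curve
    (``ExpPolySum`` or any object exposing ``.curve()``) as ``times`` with
    ``values=None``, in which case the exact closed-form integral is used
    and ``t_range`` is required.  Sampled points outside ``t_range`` are
    dropped (no edge interpolation); at least two points must remain.
    """
    if values is None:
        curve = times if isinstance(times, ExpPolySum) else times.curve()
        if t_range is None:
            raise ValueError("t_range is required for analytic curves")
        return float(curve.definite_integral(t_range[0], t_range[1]))
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    if t_range is not None:
        mask = (t >= t_range[0]) & (t <= t_range[1])
        t, v = t[mask], v[mask]
    if t.size < 2:
        raise ValueError("need >= 2 points inside the range for a trapezoid AUC")
    return float(np.trapezoid(v, t))


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanReport:
    """Limits-of-agreement analysis of computed-vs-experimental pairs.

    Differences d = y - x; sample (n-1) SD; limits mean +/- 1.96 SD;
    ``pct_within`` is the percentage of pairs inside the limits and
    ``mean_pct_diff`` the mean of 100 * d / pairwise-mean.
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs >= 2 pairs")
    d = pairs.y - pairs.x
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    within = (d >= loa_low) & (d <= loa_high)
    pairwise_mean = (pairs.x + pairs.y) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pairwise_mean != 0, 100.0 * d / pairwise_mean, 0.0)
    return BlandAltmanReport(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        pct_within=float(100.0 * np.mean(within)),
        mean_pct_diff=float(np.mean(pct)),
    )


def paired_t(pairs: PairedMeasurements) -> tuple[float, float, int]:
    """Two-sided paired Student's t-test -> (t, p, df) with df = n - 1.

    Zero-variance differences are degenerate: t = 0, p = 1 when the mean
    difference is also zero, otherwise t = +/-inf with p = 0.
    """
    if len(pairs) < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    d = pairs.y - pairs.x
    df = len(d) - 1
    if np.std(d, ddof=1) == 0.0:
        if np.mean(d) == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(np.mean(d)) * np.inf), 0.0, df
    t, p = stats.ttest_rel(pairs.y, pairs.x)
    return float(t), float(p), df


def pointwise_percent_difference(
    reference, computed, floor: float = 0.0
) -> tuple[float, int]:
    """Mean percent deviation of a computed curve from an experimental reference.

    Returns ``(mean of 100*(a - b)/a, n_excluded)`` over paired values with
    reference a and computed b; points with reference <= ``floor`` are
    excluded and counted.  Positive output means the computed curve runs
    below the reference.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(computed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must be sampled on the same points")
    mask = a > floor
    n_excluded = int((~mask).sum())
    if not mask.any():
        raise ValueError("all points excluded by the reference floor")
    return float(np.mean(100.0 * (a[mask] - b[mask]) / a[mask])), n_excluded
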