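"""Log-log scaling curves and regression-range selection.

Fractal dimension estimation reduces to ordinary least squares on a
``(log scale, log measure)`` curve.  Real images are fractal only over a
finite range of scales, so the points entering the regression must be
chosen; here a contiguous window is selected by thresholding the Pearson
correlation of the log-log points, which keeps the number of fitted points
objective and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalingCurve",
    "RegressionRange",
    "FDEstimate",
    "select_linear_range",
    "fit_dimension",
]


@dataclass(frozen=True)
class ScalingCurve:
    """Ordered (scale, measure) pairs backing a log-log regression.

    Parameters
    ----------
    scales : ndarray
        Strictly increasing positive scales: box side lengths for box
        counting, dilation radii for the Minkowski ("sausage") method.
    measures : ndarray
        Positive measures matched to ``scales``: occupied-box counts
        N(eps), or dilated foreground areas A(r).
    method : str
        ``"box"`` or ``"minkowski"``; decides how a fitted slope is
        converted into a dimension.
    """

    scales: np.ndarray
    measures: np.ndarray
    method: str

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        measures = np.asarray(self.measures, dtype=float)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "measures", measures)
        if scales.ndim != 1 or measures.ndim != 1:
            raise ValueError("scales and measures must be 1-D")
        if scales.size != measures.size:
            raise ValueError("scales and measures must have equal length")
        if scales.size < 3:
            raise ValueError("a scaling curve needs at least 3 points")
        if not np.all(np.isfinite(scales)) or not np.all(np.isfinite(measures)):
            raise ValueError("scales and measures must be finite")
        if np.any(scales <= 0) or np.any(measures <= 0):
            raise ValueError("scales and measures must be positive")
        if np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    def __len__(self) -> int:
        return int(self.scales.size)

    @property
    def log_scales(self) -> np.ndarray:
        return np.log(self.scales)

    @property
    def log_measures(self) -> np.ndarray:
        return np.log(self.measures)


@dataclass(frozen=True)
class RegressionRange:
    """Inclusive index window ``[first, last]`` into a :class:`ScalingCurve`."""

    first: int
    last: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.first < 0 or self.last < self.first:
            raise ValueError("invalid regression range")
        if self.last - self.first < 2:
            raise ValueError("regression range must span at least 3 points")

    def __len__(self) -> int:
        return self.last - self.first + 1

    def slice(self) -> slice:
        return slice(self.first, self.last + 1)


@dataclass(frozen=True)
class FDEstimate:
    """A fractal dimension with its fit metadata."""

    value: float
    method: str
    fit_r: float
    range: RegressionRange
    slope: float
    intercept: float
    slope_stderr: float = field(default=float("nan"))


def _window_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of a log-log window.

    A window whose ordinates are constant (e.g. N(eps) = 1 for a single
    point set) is exactly linear with slope zero, so its linearity score
    is taken as 1 rather than undefined.
    """
    if np.ptp(y) == 0.0:
        return 1.0
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate abscissa: zero variance in log scale")
    return float(np.corrcoef(x, y)[0, 1])


def select_linear_range(curve: ScalingCurve, r_threshold: float = 0.995) -> RegressionRange:
    """Pick the scaling range entering the dimension regression.

    Returns the longest contiguous window of the curve whose log-log
    Pearson correlation satisfies ``|R| >= r_threshold``; ties are broken
    toward the window starting at the smaller scale.  If no window of at
    least 3 points qualifies, the 3-point window with the highest ``|R|``
    is returned with ``flagged=True``.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must lie in (0, 1)")
    x, y = curve.log_scales, curve.log_measures
    n = len(curve)

    best: RegressionRange | None = None
    for length in range(n, 2, -1):
        for first in range(0, n - length + 1):
            last = first + length - 1
            r = _window_corr(x[first : last + 1], y[first : last + 1])
            if abs(r) >= r_threshold:
                best = RegressionRange(first, last)
                break
        if best is not None:
            break

    if best is not None:
        return best

    # degenerate: no window reaches the threshold
    best_r, best_first = -np.inf, 0
    for first in range(0, n - 2):
        r = abs(_window_corr(x[first : first + 3], y[first : first + 3]))
        if r > best_r:
            best_r, best_first = r, first
    return RegressionRange(best_first, best_first + 2, flagged=True)


def fit_dimension(curve: ScalingCurve, range_: RegressionRange | None = None) -> FDEstimate:
    """OLS fit of log measure on log scale, converted to a dimension.

    For box counting the dimension is minus the slope of
    log N(eps) vs log eps.  For the dilation (Minkowski) method the
    dilated area scales as A(r) ~ r^(2-D), so D = 2 - slope.
    """
    if range_ is None:
        range_ = RegressionRange(0, len(curve) - 1)
    if range_.last >= len(curve):
        raise ValueError("regression range exceeds curve length")

    x = curve.log_scales[range_.slice()]
    y = curve.log_measures[range_.slice()]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate abscissa: zero variance in log scale")

    slope, intercept = np.polyfit(x, y, 1)
    r = _window_corr(x, y)
    resid = y - (slope * x + intercept)
    dof = x.size - 2
    if dof > 0 and np.ptp(y) > 0:
        stderr = float(np.sqrt(np.sum(resid**2) / dof / np.sum((x - x.mean()) ** 2)))
    else:
        stderr = 0.0

    if curve.method == "box":
        value = -slope
    elif curve.method == "minkowski":
        value = 2.0 - slope
    else:
        raise ValueError(f"unknown curve method {curve.method!r}")

    return FDEstimate(
        value=float(value),
        method=curve.method,
        fit_r=float(r),
        range=range_,
        slope=float(slope),
        intercept=float(intercept),
        slope_stderr=stderr,
    )
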