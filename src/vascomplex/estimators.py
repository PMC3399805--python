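"""Box-counting and Minkowski (dilation) fractal dimension estimators.

Two classical estimators of the fractal dimension of a planar set:

* **Box counting** covers the image with a top-left-anchored grid of
  square boxes of dyadic side ``eps = 2^n`` and counts occupied boxes
  N(eps); the dimension is minus the slope of log N vs log eps.
* **Minkowski–Bouligand** ("sausage") dilates the foreground with square
  structuring elements of side ``2n+1`` (n = 0..n_max) and measures the
  dilated area A(r), r = (2n+1)/2; the area of an r-neighbourhood of a
  D-dimensional set scales as r^(2-D), so D = 2 - slope.

Both models select the regression window by the correlation-threshold
rule (|R| >= 0.995 by default) and return a results object carrying the
estimate, the fitted window and diagnostics, in the spirit of
statsmodels' ``Model.fit() -> Results``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_ops import validate_binary
from .scaling import FDEstimate, RegressionRange, ScalingCurve, fit_dimension, select_linear_range

__all__ = [
    "box_counts",
    "minkowski_areas",
    "BoxCountModel",
    "MinkowskiModel",
    "FractalDimensionResults",
]


def dyadic_scales(shape: tuple[int, int]) -> np.ndarray:
    """Box sides 1, 2, 4, ... up to the larger image extent."""
    limit = max(shape)
    n_max = int(np.floor(np.log2(limit)))
    return 2 ** np.arange(n_max + 1)


def _occupancy_count(image: np.ndarray, eps: int, anchor: tuple[int, int]) -> int:
    """Number of eps-boxes (grid anchored at ``anchor``) holding foreground."""
    ay, ax = anchor
    padded = np.pad(image, ((ay, 0), (ax, 0)))
    h, w = padded.shape
    ph, pw = (-h) % eps, (-w) % eps
    padded = np.pad(padded, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // eps, eps, padded.shape[1] // eps, eps)
    return int(blocks.any(axis=(1, 3)).sum())


def box_counts(image: np.ndarray, anchor: tuple[int, int] = (0, 0)) -> ScalingCurve:
    """Occupied-box counts N(eps) over the dyadic box-size series.

    The grid is anchored at the top-left pixel (offset by ``anchor``);
    partial boxes at the right/bottom edges count as boxes.  N(eps) is
    strictly positive and non-increasing in eps; N(1) equals the
    foreground pixel count.
    """
    img = validate_binary(image)
    if img.sum() == 0:
        raise ValueError("no foreground: cannot box-count an empty image")
    scales = dyadic_scales(img.shape)
    counts = [_occupancy_count(img, int(eps), anchor) for eps in scales]
    return ScalingCurve(scales=np.asarray(scales, float), measures=np.asarray(counts, float), method="box")


def minkowski_areas(image: np.ndarray, n_max: int = 20) -> ScalingCurve:
    """Dilated foreground areas A(r) for square elements of side 2n+1.

    For n = 0..n_max the image is morphologically dilated with a
    (2n+1)x(2n+1) square (clipped at the canvas) and the foreground area
    recorded against the radius r_n = (2n+1)/2.  A single Chebyshev
    distance transform yields all dilation areas at once: a pixel lies in
    the n-dilation iff its chessboard distance to the foreground is <= n.
    """
    img = validate_binary(image)
    if img.sum() == 0:
        raise ValueError("no foreground: cannot dilate an empty image")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    dist = ndimage.distance_transform_cdt(img == 0, metric="chessboard")
    n = np.arange(n_max + 1)
    areas = np.array([(dist <= k).sum() for k in n], dtype=float)
    radii = (2 * n + 1) / 2.0
    return ScalingCurve(scales=radii, measures=areas, method="minkowski")


@dataclass(frozen=True)
class FractalDimensionResults:
    """Fitted fractal dimension plus the curve and window behind it."""

    estimate: FDEstimate
    curve: ScalingCurve
    r_threshold: float

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def fit_r(self) -> float:
        return self.estimate.fit_r

    @property
    def range(self) -> RegressionRange:
        return self.estimate.range

    def curve_frame(self):
        """The scaling curve as a DataFrame (scale, measure, logs, in_range)."""
        import pandas as pd

        in_range = np.zeros(len(self.curve), dtype=bool)
        in_range[self.range.slice()] = True
        return pd.DataFrame(
            {
                "scale": self.curve.scales,
                "measure": self.curve.measures,
                "log_scale": self.curve.log_scales,
                "log_measure": self.curve.log_measures,
                "in_range": in_range,
            }
        )

    def summary(self) -> str:
        e = self.estimate
        name = {"box": "Box-counting dimension D_b", "minkowski": "Minkowski dimension D_m"}[e.method]
        lines = [
            f"{name}: {e.value:.4f}",
            f"  slope {e.slope:.4f} (stderr {e.slope_stderr:.4f}), intercept {e.intercept:.4f}",
            f"  fit |R| = {abs(e.fit_r):.5f} over points "
            f"[{e.range.first}..{e.range.last}] of {len(self.curve)} "
            f"(scales {self.curve.scales[e.range.first]:g}..{self.curve.scales[e.range.last]:g})",
            f"  range selection threshold R = {self.r_threshold}",
        ]
        if e.range.flagged:
            lines.append("  WARNING: no window reached the threshold; best 3-point window used")
        return "\n".join(lines)

    def plot_loglog(self, ax=None):
        """Log-log diagnostic plot: all points, fitted window and line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.curve.log_scales, self.curve.log_measures
        ax.plot(x, y, "o", color="0.6", label="all scales")
        sl = self.range.slice()
        ax.plot(x[sl], y[sl], "ko", label="fitted range")
        e = self.estimate
        xs = np.array([x[sl].min(), x[sl].max()])
        ax.plot(xs, e.slope * xs + e.intercept, "r-", label=f"fit, D = {e.value:.3f}")
        ax.set_xlabel("log scale")
        ax.set_ylabel("log measure")
        ax.legend()
        return ax


class _ScalingModel:
    """Shared fit machinery for the two dimension estimators."""

    def __init__(self, image: np.ndarray):
        self.image = validate_binary(image)

    def _curve(self) -> ScalingCurve:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, r_threshold: float = 0.995, range_: RegressionRange | None = None) -> FractalDimensionResults:
        """Select the scaling range (unless given) and fit the dimension."""
        curve = self._curve()
        if range_ is None:
            range_ = select_linear_range(curve, r_threshold)
        estimate = fit_dimension(curve, range_)
        return FractalDimensionResults(estimate=estimate, curve=curve, r_threshold=r_threshold)


class BoxCountModel(_ScalingModel):
    """Box-counting dimension model for a binary image.

    Parameters
    ----------
    image : array-like of {0,1}
    anchor : (int, int)
        Grid origin offset (rows, cols).  The occupied-box count of a
        non-power-of-two image depends on where the grid is anchored;
        the default pins it to the top-left pixel.
    """

    def __init__(self, image: np.ndarray, anchor: tuple[int, int] = (0, 0)):
        super().__init__(image)
        self.anchor = anchor

    def _curve(self) -> ScalingCurve:
        return box_counts(self.image, anchor=self.anchor)


class MinkowskiModel(_ScalingModel):
    """Minkowski (dilation) dimension model for a binary image."""

    def __init__(self, image: np.ndarray, n_max: int = 20):
        super().__init__(image)
        self.n_max = n_max

    def _curve(self) -> ScalingCurve:
        return minkowski_areas(self.image, n_max=self.n_max)
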