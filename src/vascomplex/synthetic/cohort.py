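"""Synthetic AVM cohort generator.

Emulates the statistical structure of a paired angiographic study: each
subject contributes two 182x436 hemisphere skeletons (random binary
branching trees), an intensity-time curve of contrast passage, and —
for patients — four nidus diameters.  Patients carry an extra dense
tangle of short strokes (the "nidus") on the affected side, so that
side's branch count, and hence its fractal dimension, is strictly
larger; the peak upslope of the bolus curve is an affine function of
total branch count, and the mean nidus diameter grows monotonically
with the tangle size.  This is a stand-in for real hemodynamics, not a
vascular growth model: it encodes exactly the monotone
complexity-flow-nidus relationships the analysis is meant to recover,
with tunable noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from ..image_ops import skeletonize

__all__ = ["CohortParams", "SyntheticSubject", "generate_cohort", "gamma_variate"]

HEMISPHERE_SHAPE = (436, 182)  # rows x cols; two halves of a 436x364 raster


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults define the study conditions.

    Tree parameters shape the per-hemisphere binary branching tree;
    ``nidus_*`` control the extra tangle on the AVM side; ``slope_*``
    and ``diam_*`` are the affine links from branch count to the bolus
    peak upslope (a.u./s) and to the mean nidus diameter (cm).
    """

    # branching tree
    tree_depth: int = 7
    trunk_length: float = 85.0
    length_decay: float = 0.74
    length_jitter: float = 0.12
    branch_angle_deg: float = 27.0
    angle_jitter_deg: float = 9.0
    # nidus tangle (patients, AVM side); the disk radius grows like
    # sqrt(d) so stroke density stays constant and thinning never
    # collapses the tangle
    nidus_branches_low: int = 10
    nidus_branches_high: int = 160
    nidus_radius: float = 26.0  # disk radius in px at d = 40 tangle strokes
    nidus_stroke_length: tuple[float, float] = (6.0, 16.0)
    nidus_center_jitter: float = 1.0  # 0 pins the tangle to a fixed site
    nidus_feeder_fraction: float = 0.35  # share of d drawn as feeding vessels
    # intensity-time curve (gamma-variate bolus)
    curve_t_max: float = 60.0
    curve_dt: float = 0.5
    bolus_t0: float = 8.0
    bolus_alpha: float = 3.0
    bolus_beta: float = 1.8
    slope_intercept: float = 0.5
    slope_per_branch: float = 0.02
    slope_noise_sd: float = 0.05
    # nidus diameters
    diam_intercept: float = 0.8
    diam_per_branch: float = 0.02
    diam_noise_sd: float = 0.0
    diam_view_spread: tuple[float, float] = (0.1, 0.3)

    def __post_init__(self) -> None:
        if self.tree_depth < 1 or self.trunk_length <= 0:
            raise ValueError("degenerate tree parameters: zero branches")
        if self.nidus_branches_low < 1 or self.nidus_branches_high < self.nidus_branches_low:
            raise ValueError("nidus branch range must be >= 1 and ordered")
        if int(self.curve_t_max / self.curve_dt) + 1 < 10:
            raise ValueError("intensity-time curve must have >= 10 samples")


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic participant: images, curve, diameters, ground truth."""

    subject_id: str
    group: str  # "patient" or "control"
    left_image: np.ndarray
    right_image: np.ndarray
    avm_side: str | None  # "left"/"right" for patients, None for controls
    branch_count_left: int
    branch_count_right: int
    times: np.ndarray
    intensities: np.ndarray
    nidus_diameters: tuple[float, float, float, float] | None  # cm, 2 views x min/max
    rng_seed: int

    @property
    def total_branches(self) -> int:
        return self.branch_count_left + self.branch_count_right

    def hemisphere(self, side: str) -> np.ndarray:
        if side == "left":
            return self.left_image
        if side == "right":
            return self.right_image
        raise ValueError(f"unknown side {side!r}")

    def whole_image(self) -> np.ndarray:
        return np.hstack([self.left_image, self.right_image])


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float, amplitude: float = 1.0) -> np.ndarray:
    """Gamma-variate bolus curve A * tau^alpha * exp(-tau/beta), tau = t - t0."""
    t = np.asarray(t, dtype=float)
    tau = np.clip(t - t0, 0.0, None)
    return amplitude * tau**alpha * np.exp(-tau / beta)


def _gamma_variate_max_slope(t0: float, alpha: float, beta: float) -> float:
    """Analytic maximum of d/dt of the unit-amplitude gamma-variate.

    The derivative tau^(alpha-1) e^(-tau/beta) (alpha - tau/beta) is
    maximal at tau = beta * (2*alpha - 1 - sqrt(2*alpha - 1)) / 2 ... the
    closed form is awkward; the stationary point of the second derivative
    is found from its quadratic in tau.
    """
    # I''(tau) = 0  =>  tau^2/beta^2 - 2*alpha*tau/beta + alpha*(alpha-1) = 0
    a = alpha
    disc = np.sqrt(a**2 - a * (a - 1.0))
    tau_star = beta * (a - disc)
    if tau_star <= 0:
        tau_star = beta * (a + disc)
    tau = tau_star
    return float(tau ** (a - 1.0) * np.exp(-tau / beta) * (a - tau / beta))


def _draw_segment(img: np.ndarray, y0: float, x0: float, y1: float, x1: float) -> None:
    h, w = img.shape
    rr, cc = _draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = 1


def _grow_tree(img: np.ndarray, params: CohortParams, rng: np.random.Generator) -> int:
    """Rasterize a recursive bifurcating tree; returns the segment count."""
    h, w = img.shape
    count = 0
    # stack of (y, x, angle_rad, length, depth); trunk points "up" (-y)
    stack = [(h - 1.0, w / 2.0 + rng.uniform(-8, 8), -np.pi / 2, params.trunk_length, params.tree_depth)]
    while stack:
        y, x, ang, length, depth = stack.pop()
        y1 = y + length * np.sin(ang)
        x1 = x + length * np.cos(ang)
        _draw_segment(img, y, x, y1, x1)
        count += 1
        if depth > 0:
            spread = np.deg2rad(params.branch_angle_deg)
            for sgn in (-1.0, 1.0):
                jitter = np.deg2rad(rng.normal(0.0, params.angle_jitter_deg))
                child_len = length * params.length_decay * (1.0 + rng.normal(0.0, params.length_jitter))
                child_len = max(child_len, 2.0)
                stack.append((y1, x1, ang + sgn * spread + jitter, child_len, depth - 1))
    return count


def _grow_avm(img: np.ndarray, d: int, params: CohortParams, rng: np.random.Generator) -> int:
    """Draw the d extra vessels of the malformation.

    A fraction of the extra vessels are feeding arteries: longer
    segments converging radially on the nidus from across the
    hemisphere.  The rest are short strokes scattered in a disk — the
    dense tangle of the nidus itself.  The disk radius grows like
    sqrt(tangle size) so the stroke density stays constant and thinning
    never erases the added complexity.
    """
    h, w = img.shape
    jit = params.nidus_center_jitter
    cy = h * (0.45 + jit * rng.uniform(-0.15, 0.15))
    cx = w * (0.50 + jit * rng.uniform(-0.15, 0.15))
    n_feed = int(round(params.nidus_feeder_fraction * d))
    n_tangle = d - n_feed
    lo, hi = params.nidus_stroke_length
    disk_radius = params.nidus_radius * np.sqrt(max(n_tangle, 1) / 40.0)
    for _ in range(n_tangle):
        rad = disk_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        y0, x0 = cy + rad * np.sin(phi), cx + rad * np.cos(phi)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        length = rng.uniform(lo, hi)
        _draw_segment(img, y0, x0, y0 + length * np.sin(ang), x0 + length * np.cos(ang))
    for _ in range(n_feed):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        start_r = rng.uniform(60.0, 170.0)
        y0, x0 = cy + start_r * np.sin(phi), cx + start_r * np.cos(phi)
        ang = np.arctan2(cy - y0, cx - x0) + rng.normal(0.0, 0.25)
        length = rng.uniform(35.0, 80.0)
        _draw_segment(img, y0, x0, y0 + length * np.sin(ang), x0 + length * np.cos(ang))
    return d


def _make_hemisphere(params: CohortParams, rng: np.random.Generator, nidus_strokes: int = 0) -> tuple[np.ndarray, int]:
    img = np.zeros(HEMISPHERE_SHAPE, dtype=np.uint8)
    count = _grow_tree(img, params, rng)
    if nidus_strokes > 0:
        count += _grow_avm(img, nidus_strokes, params, rng)
    return skeletonize(img), count


def generate_cohort(
    n_patients: int = 10,
    n_controls: int = 10,
    params: CohortParams | None = None,
    rng_seed: int = 0,
) -> list[SyntheticSubject]:
    """Generate a reproducible cohort of patients and controls.

    Patients receive a nidus tangle of d extra strokes (d uniform on the
    configured range) on a randomly assigned AVM side, making that side
    strictly more complex; controls are symmetric.  The bolus curve's
    peak upslope is ``slope_intercept + slope_per_branch * total
    branches`` plus Gaussian noise, and the four nidus diameters average
    to ``diam_intercept + diam_per_branch * d`` (plus optional noise).
    """
    if n_patients < 1 and n_controls < 1:
        raise ValueError("cohort must contain at least one subject")
    params = params or CohortParams()
    times = np.arange(0.0, params.curve_t_max + params.curve_dt / 2, params.curve_dt)
    unit_max_slope = _gamma_variate_max_slope(params.bolus_t0, params.bolus_alpha, params.bolus_beta)

    seeds = np.random.SeedSequence(rng_seed).spawn(n_patients + n_controls)
    subjects: list[SyntheticSubject] = []
    for i, seed_seq in enumerate(seeds):
        rng = np.random.default_rng(seed_seq)
        is_patient = i < n_patients
        sid = f"P{i + 1:02d}" if is_patient else f"C{i - n_patients + 1:02d}"

        if is_patient:
            d = int(rng.integers(params.nidus_branches_low, params.nidus_branches_high + 1))
            avm_side = "left" if rng.uniform() < 0.5 else "right"
            left, n_left = _make_hemisphere(params, rng, nidus_strokes=d if avm_side == "left" else 0)
            right, n_right = _make_hemisphere(params, rng, nidus_strokes=d if avm_side == "right" else 0)
            diam_mean = params.diam_intercept + params.diam_per_branch * d
            diam_mean += rng.normal(0.0, params.diam_noise_sd) if params.diam_noise_sd > 0 else 0.0
            diam_mean = max(diam_mean, 0.1)
            u_cor = rng.uniform(*params.diam_view_spread)
            u_sag = rng.uniform(*params.diam_view_spread)
            diameters = (
                diam_mean * (1 - u_cor),
                diam_mean * (1 + u_cor),
                diam_mean * (1 - u_sag),
                diam_mean * (1 + u_sag),
            )
        else:
            d = 0
            avm_side = None
            left, n_left = _make_hemisphere(params, rng)
            right, n_right = _make_hemisphere(params, rng)
            diameters = None

        total = n_left + n_right
        target_slope = params.slope_intercept + params.slope_per_branch * total
        if params.slope_noise_sd > 0:
            target_slope += rng.normal(0.0, params.slope_noise_sd)
        target_slope = max(target_slope, 1e-6)
        intensities = gamma_variate(
            times, params.bolus_t0, params.bolus_alpha, params.bolus_beta,
            amplitude=target_slope / unit_max_slope,
        )

        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group="patient" if is_patient else "control",
                left_image=left,
                right_image=right,
                avm_side=avm_side,
                branch_count_left=n_left,
                branch_count_right=n_right,
                times=times,
                intensities=intensities,
                nidus_diameters=diameters,
                rng_seed=rng_seed,
            )
        )
    return subjects
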