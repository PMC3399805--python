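"""Cohort-level analysis: FD tables, hemisphere contrasts, correlations.

Reproduces the study design around the estimators: every subject's two
hemisphere skeletons (and the whole image) are scored with five
dimension estimates (D_b, D_m, D_0, D_1, D_2); hemispheres are compared
within patients (AVM vs contralateral) and within controls (left vs
right); the affected-side FD is correlated with the maximum slope of the
contrast bolus and with the mean nidus diameter; and a Fisher-z power
calculation turns each correlation into a sample-size estimate.  A DLA
replicate block quantifies the matrix-size sensitivity of box counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import BoxCountModel, MinkowskiModel, box_counts, minkowski_areas
from .image_ops import split_hemispheres
from .multifractal import MultifractalModel
from .synthetic.cohort import CohortParams, SyntheticSubject, generate_cohort
from .synthetic.dla import generate_dla_geometry

__all__ = [
    "max_slope",
    "nidus_mean_diameter",
    "correlate",
    "CorrelationResult",
    "sample_size_from_r",
    "fd_estimates",
    "cohort_fd_table",
    "compare_hemispheres",
    "dla_block",
    "dla_block_summary",
    "StudyConfig",
    "CohortReport",
    "run_study",
]

METHODS = ("D_b", "D_m", "D_0", "D_1", "D_2")


# ---------------------------------------------------------------------------
# elementary operations


def max_slope(times: np.ndarray, intensities: np.ndarray) -> float:
    """Maximum of the differentiated intensity-time curve.

    Central differences in the interior, one-sided at the ends; sampling
    must be uniform.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.ndim != 1 or t.size != y.size:
        raise ValueError("times and intensities must be 1-D and matched")
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError("sampling must be uniform and increasing")
    return float(np.gradient(y, t).max())


def nidus_mean_diameter(d_cor_min: float, d_cor_max: float, d_sag_min: float, d_sag_max: float) -> float:
    """Mean nidus diameter: average of min/max diameters from both views (cm)."""
    d = np.array([d_cor_min, d_cor_max, d_sag_min, d_sag_max], dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameters must be positive and finite")
    return float(d.mean())


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its OLS line and two-sided p-value."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r, two-sided p (t transform), and the OLS fit line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def sample_size_from_r(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Subjects needed to detect a correlation r (Fisher-z method).

    n = ceil( ((z_{1-alpha/2} + z_power) / atanh(|r|))^2 + 3 ).
    """
    r = float(r)
    if not 0.0 < abs(r) < 1.0:
        raise ValueError("r must satisfy 0 < |r| < 1")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    c = np.arctanh(abs(r))
    return int(np.ceil(((z_alpha + z_power) / c) ** 2 + 3.0))


# ---------------------------------------------------------------------------
# per-image and per-cohort dimension tables


def fd_estimates(
    image: np.ndarray,
    r_threshold: float = 0.995,
    n_max: int = 20,
    q_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """All five dimension estimates of one binary image."""
    d_b = BoxCountModel(image).fit(r_threshold=r_threshold).value
    d_m = MinkowskiModel(image, n_max=n_max).fit(r_threshold=r_threshold).value
    spectrum = MultifractalModel(image, q_grid=q_grid).fit()
    return {
        "D_b": d_b,
        "D_m": d_m,
        "D_0": spectrum.d0,
        "D_1": spectrum.d1,
        "D_2": spectrum.d2,
    }


def _shared_window(curves: list, r_threshold: float):
    """Correlation-threshold window of the cohort-mean log-log curve.

    A group analysis must score every image over the same scales —
    per-image window selection injects between-subject noise that has
    nothing to do with the vasculature.  The window is therefore chosen
    once, on the scale-wise mean of the log measures, and reused.
    """
    from .scaling import ScalingCurve, select_linear_range

    scales = curves[0].scales
    if any(len(c) != len(scales) or not np.allclose(c.scales, scales) for c in curves):
        return None  # heterogeneous scale grids: fall back to per-image
    mean_log = np.mean([c.log_measures for c in curves], axis=0)
    mean_curve = ScalingCurve(scales=scales, measures=np.exp(mean_log), method=curves[0].method)
    return select_linear_range(mean_curve, r_threshold)


def cohort_fd_table(
    subjects: list[SyntheticSubject],
    r_threshold: float = 0.995,
    n_max: int = 20,
    q_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format table: subject, group, region, role, method, value.

    All images are fitted over shared regression windows (one per
    estimator, selected on the cohort-mean scaling curve) so every
    subject contributes the same number of points to each regression.
    """
    from .multifractal import generalized_spectrum, partition_moments
    from .scaling import RegressionRange, fit_dimension

    items: list[tuple[SyntheticSubject, str, str, np.ndarray]] = []
    for s in subjects:
        for region, image in (
            ("left", s.left_image),
            ("right", s.right_image),
            ("whole", s.whole_image()),
        ):
            if s.group == "patient" and region != "whole":
                role = "avm" if region == s.avm_side else "no_avm"
            else:
                role = region
            items.append((s, region, role, image))

    box_curves = [box_counts(img) for *_, img in items]
    mink_curves = [minkowski_areas(img, n_max=n_max) for *_, img in items]
    box_window = _shared_window(box_curves, r_threshold)
    mink_window = _shared_window(mink_curves, r_threshold)

    # shared multifractal window: mass threshold applied to cohort-mean
    # occupied-box mass, so the same sizes are used for every image
    pms = [partition_moments(img, q_grid) for *_, img in items]
    mfa_window = None
    n_sizes = {pm.sizes.size for pm in pms}
    if len(n_sizes) == 1:
        mean_mass = np.mean([pm.total_mass / pm.moments[0] for pm in pms], axis=0)
        qualifying = np.flatnonzero(mean_mass >= 4.0)
        if qualifying.size >= 3:
            mfa_window = RegressionRange(int(qualifying[0]), int(qualifying[-1]))

    from .multifractal import _spectrum_from_moments
    from .scaling import select_linear_range

    rows: list[dict] = []
    for (s, region, role, image), bc, mk, pm in zip(items, box_curves, mink_curves, pms):
        bw = box_window if box_window is not None else select_linear_range(bc, r_threshold)
        mw = mink_window if mink_window is not None else select_linear_range(mk, r_threshold)
        d_b = fit_dimension(bc, bw).value
        d_m = fit_dimension(mk, mw).value
        if mfa_window is not None:
            d_q, _ = _spectrum_from_moments(pm, mfa_window)
            idx = {v: int(np.flatnonzero(np.isclose(pm.q_grid, v))[0]) for v in (0.0, 1.0, 2.0)}
            d0, d1, d2 = (float(d_q[idx[v]]) for v in (0.0, 1.0, 2.0))
        else:
            spec = generalized_spectrum(image, q_grid)
            d0, d1, d2 = spec.d0, spec.d1, spec.d2
        for method, value in (
            ("D_b", d_b),
            ("D_m", d_m),
            ("D_0", d0),
            ("D_1", d1),
            ("D_2", d2),
        ):
            rows.append(
                {
                    "subject": s.subject_id,
                    "group": s.group,
                    "region": region,
                    "role": role,
                    "method": method,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def compare_hemispheres(fd_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means +/- SEM and paired hemisphere contrasts.

    Returns ``(summary, paired)``: the summary lists mean and SEM per
    method for each group/role cell; the paired frame holds the
    within-subject mean difference and paired t statistic for patients
    (AVM minus contralateral) and controls (left minus right).
    """
    required = {"subject", "group", "role", "method", "value"}
    if not required <= set(fd_table.columns):
        raise ValueError(f"fd table must have columns {sorted(required)}")

    cells = [
        ("patient", "avm", "P_AVM"),
        ("patient", "no_avm", "P_no_AVM"),
        ("patient", "whole", "P_total"),
        ("control", "left", "HC_left"),
        ("control", "right", "HC_right"),
        ("control", "whole", "HC_total"),
    ]
    summary_rows = []
    for group, role, label in cells:
        sub = fd_table[(fd_table["group"] == group) & (fd_table["role"] == role)]
        if sub.empty:
            continue
        for method, vals in sub.groupby("method")["value"]:
            summary_rows.append(
                {
                    "cell": label,
                    "method": method,
                    "mean": vals.mean(),
                    "sem": stats.sem(vals) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    summary = pd.DataFrame(summary_rows)

    paired_rows = []
    for group, role_a, role_b, label in [
        ("patient", "avm", "no_avm", "P: AVM - no AVM"),
        ("control", "left", "right", "HC: left - right"),
    ]:
        sub = fd_table[fd_table["group"] == group]
        if sub.empty:
            continue
        for method in sub["method"].unique():
            a = sub[(sub["role"] == role_a) & (sub["method"] == method)].set_index("subject")["value"]
            b = sub[(sub["role"] == role_b) & (sub["method"] == method)].set_index("subject")["value"]
            common = a.index.intersection(b.index)
            if len(common) < 2:
                raise ValueError(f"missing hemisphere values for paired contrast in {group}")
            diff = a[common] - b[common]
            t_stat, p = stats.ttest_rel(a[common], b[common])
            paired_rows.append(
                {
                    "contrast": label,
                    "method": method,
                    "mean_diff": diff.mean(),
                    "sem_diff": stats.sem(diff),
                    "t": float(t_stat),
                    "p": float(p),
                    "n": len(common),
                }
            )
    return summary, pd.DataFrame(paired_rows)


def cohort_correlations(
    subjects: list[SyntheticSubject], fd_table: pd.DataFrame
) -> pd.DataFrame:
    """FD-vs-physiology correlations over patients (affected hemisphere).

    For each dimension estimate, correlates the AVM-side value with the
    subject's maximum contrast-transit slope and with the mean nidus
    diameter, and attaches the Fisher-z sample-size estimate.
    """
    patients = [s for s in subjects if s.group == "patient"]
    if len(patients) < 3:
        raise ValueError("need at least 3 patients for correlations")
    slopes = {s.subject_id: max_slope(s.times, s.intensities) for s in patients}
    diameters = {
        s.subject_id: nidus_mean_diameter(*s.nidus_diameters)
        for s in patients
        if s.nidus_diameters is not None
    }

    rows = []
    avm = fd_table[(fd_table["group"] == "patient") & (fd_table["role"] == "avm")]
    for method in METHODS:
        vals = avm[avm["method"] == method].set_index("subject")["value"]
        for covariate, mapping in (("max_slope", slopes), ("nidus_diameter", diameters)):
            ids = [sid for sid in vals.index if sid in mapping]
            res = correlate(vals[ids].to_numpy(), np.array([mapping[sid] for sid in ids]))
            rows.append(
                {
                    "method": method,
                    "covariate": covariate,
                    "r": res.r,
                    "p": res.p_value,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n": res.n,
                    "sample_size": sample_size_from_r(res.r) if abs(res.r) < 1 else 4,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DLA matrix-size sensitivity block


def dla_block(
    n_replicates: int = 10,
    geometries: tuple[str, ...] = ("512x512", "364x436"),
    rng_seed: int = 0,
    r_threshold: float = 0.995,
    n_max: int = 20,
    **dla_overrides,
) -> pd.DataFrame:
    """D_b and D_m of replicate DLA clusters, whole image and halves.

    Long format: replicate, geometry, region (whole/left/right), method,
    value.  Replicate seeds derive deterministically from ``rng_seed``.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates) % (2**31)
    rows = []
    for geometry in geometries:
        for rep, seed in enumerate(seeds):
            image = generate_dla_geometry(geometry, int(seed), **dla_overrides)
            left, right = split_hemispheres(image)
            for region, img in (("whole", image), ("left", left), ("right", right)):
                d_b = BoxCountModel(img).fit(r_threshold=r_threshold).value
                d_m = MinkowskiModel(img, n_max=n_max).fit(r_threshold=r_threshold).value
                for method, value in (("D_b", d_b), ("D_m", d_m)):
                    rows.append(
                        {
                            "replicate": rep,
                            "geometry": geometry,
                            "region": region,
                            "method": method,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def dla_block_summary(block: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per geometry/region/method (the DLA table layout)."""
    grouped = block.groupby(["geometry", "region", "method"])["value"]
    out = grouped.agg(mean="mean", sem=stats.sem, n="count").reset_index()
    return out


def dla_half_discrepancy(block: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate |whole - half| differences, averaged over halves."""
    rows = []
    for (geometry, method, rep), sub in block.groupby(["geometry", "method", "replicate"]):
        whole = sub[sub["region"] == "whole"]["value"].iloc[0]
        halves = sub[sub["region"].isin(("left", "right"))]["value"]
        rows.append(
            {
                "geometry": geometry,
                "method": method,
                "replicate": rep,
                "abs_diff": float(np.mean(np.abs(whole - halves))),
                "diff": float(np.mean(whole - halves)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study orchestration


@dataclass
class StudyConfig:
    """Everything a full synthetic-study run needs; YAML-loadable."""

    n_patients: int = 10
    n_controls: int = 10
    cohort_seed: int = 0
    cohort_params: CohortParams = field(default_factory=CohortParams)
    r_threshold: float = 0.995
    minkowski_n_max: int = 20
    with_dla_block: bool = False
    dla_replicates: int = 10
    dla_seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = CohortParams(**raw.pop("cohort_params", {}))
        return cls(cohort_params=params, **raw)


@dataclass
class CohortReport:
    """All study outputs: tables, contrasts, correlations, DLA block."""

    fd_table: pd.DataFrame
    hemisphere_summary: pd.DataFrame
    paired_contrasts: pd.DataFrame
    correlations: pd.DataFrame
    dla: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Vascular complexity study report", "=" * 34, ""]
        lines.append("Group means +/- SEM")
        for _, row in self.hemisphere_summary.iterrows():
            lines.append(
                f"  {row['cell']:<10s} {row['method']:<4s} {row['mean']:.3f} +/- {row['sem']:.3f} (n={int(row['n'])})"
            )
        lines.append("")
        lines.append("Paired hemisphere contrasts")
        for _, row in self.paired_contrasts.iterrows():
            lines.append(
                f"  {row['contrast']:<18s} {row['method']:<4s} diff {row['mean_diff']:+.3f} "
                f"+/- {row['sem_diff']:.3f}, t = {row['t']:+.2f}, p = {row['p']:.4f}"
            )
        lines.append("")
        lines.append("Correlations of affected-hemisphere FD (r, p, Fisher-z sample size)")
        for _, row in self.correlations.iterrows():
            lines.append(
                f"  {row['method']:<4s} vs {row['covariate']:<14s} r = {row['r']:+.3f}, "
                f"p = {row['p']:.2e}, n = {int(row['n'])}, required n = {int(row['sample_size'])}"
            )
        if self.dla is not None:
            lines.append("")
            lines.append("DLA matrix-size block (mean +/- SEM)")
            for _, row in dla_block_summary(self.dla).iterrows():
                lines.append(
                    f"  {row['geometry']:<8s} {row['region']:<6s} {row['method']:<4s} "
                    f"{row['mean']:.3f} +/- {row['sem']:.3f}"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = {"index": False, "float_format": "%.6f"}
        self.fd_table.to_csv(outdir / "report.csv", **kw)
        self.hemisphere_summary.to_csv(outdir / "hemisphere_summary.csv", **kw)
        self.paired_contrasts.to_csv(outdir / "paired_contrasts.csv", **kw)
        self.correlations.to_csv(outdir / "correlations.csv", **kw)
        if self.dla is not None:
            self.dla.to_csv(outdir / "dla_block.csv", **kw)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def run_study(config: StudyConfig | None = None) -> CohortReport:
    """Generate (or load) the cohort and run the full analysis.

    Deterministic for a fixed config: rerunning writes byte-identical
    CSV output.
    """
    config = config or StudyConfig()
    subjects = generate_cohort(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        params=config.cohort_params,
        rng_seed=config.cohort_seed,
    )
    est_kw = {"r_threshold": config.r_threshold, "n_max": config.minkowski_n_max}
    fd_table = cohort_fd_table(subjects, **est_kw)
    summary, paired = compare_hemispheres(fd_table)
    correlations = cohort_correlations(subjects, fd_table)
    dla = None
    if config.with_dla_block:
        dla = dla_block(
            n_replicates=config.dla_replicates,
            rng_seed=config.dla_seed,
            r_threshold=config.r_threshold,
            n_max=config.minkowski_n_max,
        )
    report = CohortReport(
        fd_table=fd_table,
        hemisphere_summary=summary,
        paired_contrasts=paired,
        correlations=correlations,
        dla=dla,
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report
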