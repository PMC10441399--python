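"""FRAP normalisation, hyperbolic recovery fitting and replicate pooling.

Fluorescence recovery after photobleaching reports molecular mobility inside
droplets.  A bleached region of interest (ROI) is tracked together with a
non-bleached reference droplet and a background region; the normalised
recovery is

    FRAP(t) = (F_bleach(t) - F_background(t)) / (F_nonbleached(t) - F_background(t))

which cancels background offset and acquisition photobleaching.  Recovery is
fitted with a hyperbolic (single-binding-site style) saturation curve

    F(t) = F0 + (F_inf - F0) * t / (t_half + t)

whose half-time ``t_half`` satisfies F(t_half) = (F0 + F_inf)/2 by
construction.  Replicate experiments (each averaging several ROIs) are
pooled with Bessel weights ``n_i - 1``:

    s^2_pooled = sum (n_i - 1) s_i^2 / sum (n_i - 1),  SEM = s_pooled / sqrt(sum n_i)

The synthetic generator emulates the acquisition protocol of the droplet
experiments: 15 frames per minute, 60 s of pre-bleach frames, 12 min of
recovery, six independent experiments of 6-10 bleached ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FRAPError(ValueError):
    """Invalid FRAP input."""


class FRAPFitError(RuntimeError):
    """Hyperbolic fit failed or is unidentifiable."""


@dataclass(frozen=True)
class FRAPTrace:
    """Raw intensity traces for one bleached ROI (t = 0 at end of bleach)."""

    times_s: np.ndarray
    f_bleach: np.ndarray
    f_background: np.ndarray
    f_nonbleached: np.ndarray
    pre_bleach_mean: float = 1.0
    roi_id: str = ""
    experiment_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, float)
        fb = np.asarray(self.f_bleach, float)
        bg = np.asarray(self.f_background, float)
        fn = np.asarray(self.f_nonbleached, float)
        if not (t.shape == fb.shape == bg.shape == fn.shape):
            raise FRAPError("all trace arrays must have equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise FRAPError("times must be strictly increasing (>= 2 points)")
        for name, arr in (("times_s", t), ("f_bleach", fb),
                          ("f_background", bg), ("f_nonbleached", fn)):
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class RecoveryFit:
    t_half_s: float
    f0: float
    f_inf: float
    mobile_fraction: float
    standard_errors: np.ndarray
    residuals: np.ndarray


def normalize_frap(trace: FRAPTrace) -> np.ndarray:
    """Background-subtracted, reference-normalised recovery curve."""
    denom = trace.f_nonbleached - trace.f_background
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise FRAPError(
            f"non-positive reference-minus-background at frame {bad[0]} "
            f"(t = {trace.times_s[bad[0]]:g} s)"
        )
    return (trace.f_bleach - trace.f_background) / denom


def hyperbolic(t: np.ndarray, f0: float, f_inf: float, t_half: float) -> np.ndarray:
    """Recovery model ``F0 + (F_inf - F0) t / (t_half + t)``."""
    return f0 + (f_inf - f0) * t / (t_half + t)


def fit_hyperbolic(
    times_s: np.ndarray, values: np.ndarray, fix_f0_zero: bool = False
) -> RecoveryFit:
    """Least-squares hyperbolic fit of a normalised recovery curve.

    Requires at least 5 points at t > 0 and a non-degenerate (non-constant)
    series.  With ``fix_f0_zero`` the 2-parameter form (no post-bleach
    floor) is fitted instead.
    """
    t = np.asarray(times_s, float)
    y = np.asarray(values, float)
    if t.shape != y.shape:
        raise FRAPError("times and values must have equal length")
    if np.sum(t > 0) < 5:
        raise FRAPError("need at least 5 recovery points at t > 0")
    if np.ptp(y) < 1e-12:
        raise FRAPFitError("constant series: t_half is unidentifiable")
    f0_guess = float(y[t <= np.quantile(t, 0.05)].mean()) if np.any(t <= 0) else float(y[0])
    finf_guess = float(y[-3:].mean())
    half_level = (f0_guess + finf_guess) / 2.0
    above = np.nonzero(y >= half_level)[0]
    th_guess = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(np.median(t))
    try:
        if fix_f0_zero:
            popt, pcov = curve_fit(
                lambda tt, f_inf, t_half: hyperbolic(tt, 0.0, f_inf, t_half),
                t, y, p0=[finf_guess, th_guess],
                bounds=([0.0, 1e-6], [2.0, 1e5]), maxfev=10000,
            )
            f0, (f_inf, t_half) = 0.0, popt
            se = np.concatenate([[0.0], np.sqrt(np.diag(pcov))])
        else:
            popt, pcov = curve_fit(
                hyperbolic, t, y, p0=[f0_guess, finf_guess, th_guess],
                bounds=([-0.5, 0.0, 1e-6], [1.5, 2.0, 1e5]), maxfev=10000,
            )
            f0, f_inf, t_half = popt
            se = np.sqrt(np.diag(pcov))
    except RuntimeError as exc:
        raise FRAPFitError(
            f"hyperbolic fit did not converge (initial guess F0={f0_guess:.3g}, "
            f"F_inf={finf_guess:.3g}, t_half={th_guess:.3g} s)"
        ) from exc
    resid = y - hyperbolic(t, f0, f_inf, t_half)
    mobile = (f_inf - f0) / (1.0 - f0) if f0 < 1.0 else np.nan
    return RecoveryFit(
        t_half_s=float(t_half), f0=float(f0), f_inf=float(f_inf),
        mobile_fraction=float(mobile), standard_errors=se, residuals=resid,
    )


# ---------------------------------------------------------------------------
# Replicate pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledCurve:
    times_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    pooled_variance: np.ndarray
    n_total: int


def pool_experiments(
    experiment_means: Sequence[np.ndarray],
    experiment_variances: Sequence[np.ndarray],
    n_rois: Sequence[int],
    times_s: np.ndarray,
) -> PooledCurve:
    """Pool per-experiment mean curves with Bessel ``n_i - 1`` weights.

    ``experiment_means[i]``/``experiment_variances[i]`` are the per-time
    mean and (ROI-wise, ddof=1) variance of experiment i, already on the
    common time grid; ``n_rois[i]`` its number of bleached ROIs.  Pooled
    variance is ``sum (n_i-1) s_i^2 / sum (n_i-1)`` and the SEM of the
    pooled mean is ``s_pooled / sqrt(sum n_i)``.  Experiments with a single
    ROI contribute to the mean but carry zero Bessel weight.
    """
    if len(experiment_means) == 0:
        raise FRAPError("nothing to pool")
    means = np.vstack(experiment_means)
    variances = np.vstack(experiment_variances)
    n = np.asarray(n_rois, dtype=float)
    if means.shape[0] != n.size or variances.shape != means.shape:
        raise FRAPError("inconsistent replicate structure")
    import warnings

    if n.size == 1:
        warnings.warn("single experiment: pooled curve is a passthrough",
                      stacklevel=2)
        return PooledCurve(
            times_s=np.asarray(times_s, float), mean=means[0],
            sem=np.sqrt(variances[0] / n[0]), pooled_variance=variances[0],
            n_total=int(n[0]),
        )
    w_bessel = n - 1.0
    if w_bessel.sum() <= 0:
        raise FRAPError("all experiments have a single ROI; variance undefined")
    pooled_var = (w_bessel[:, None] * variances).sum(axis=0) / w_bessel.sum()
    mean = (n[:, None] * means).sum(axis=0) / n.sum()
    sem = np.sqrt(pooled_var) / np.sqrt(n.sum())
    return PooledCurve(
        times_s=np.asarray(times_s, float), mean=mean, sem=sem,
        pooled_variance=pooled_var, n_total=int(n.sum()),
    )


def regrid(times_s: np.ndarray, values: np.ndarray, grid_s: np.ndarray) -> np.ndarray:
    """Linear interpolation onto a common time grid."""
    return np.interp(grid_s, times_s, values)


# ---------------------------------------------------------------------------
# Synthetic dataset generator (acquisition-protocol emulator)
# ---------------------------------------------------------------------------

#: Ground-truth recovery parameters used by default for synthetic datasets.
#: The half-time is the fitted droplet value; the post-bleach floor and
#: plateau are realistic choices for partial bleaching of a liquid droplet.
DEFAULT_RECOVERY = {"f0": 0.2, "f_inf": 0.85, "t_half_s": 64.0}

#: Default ROIs per experiment: six experiments of 6-10 droplets, 47 in all.
DEFAULT_ROIS_PER_EXPERIMENT = (8, 8, 8, 8, 8, 7)


def generate_frap_dataset(
    params: dict | None = None,
    rois_per_experiment: Sequence[int] = DEFAULT_ROIS_PER_EXPERIMENT,
    frame_interval_s: float = 4.0,
    pre_bleach_s: float = 60.0,
    recovery_s: float = 720.0,
    noise_sd: float = 0.02,
    roi_jitter: float = 0.05,
    acquisition_bleach_rate: float = 2e-4,
    background: float = 100.0,
    pre_bleach_intensity: float = 1000.0,
    seed: int | None = None,
) -> list[FRAPTrace]:
    """Simulate raw FRAP traces for several independent experiments.

    Each ROI follows the hyperbolic model with small per-ROI parameter
    jitter; raw channels carry a common background, mild mono-exponential
    acquisition bleaching on both bleached and reference droplets (which
    the normalisation cancels), and Gaussian detector noise of
    ``noise_sd`` (units of the normalised scale) on the bleached channel.
    ``roi_jitter`` sets the relative ROI-to-ROI spread of the recovery
    parameters (0 makes every ROI follow the model curve exactly).
    """
    p = dict(DEFAULT_RECOVERY)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    n_recovery = int(round(recovery_s / frame_interval_s))
    times = frame_interval_s * np.arange(1, n_recovery + 1)
    amplitude = pre_bleach_intensity - background
    traces = []
    for e, n_roi in enumerate(rois_per_experiment):
        for r in range(n_roi):
            # small biological ROI-to-ROI variability
            f0 = p["f0"] * (1 + roi_jitter * rng.standard_normal())
            finf = p["f_inf"] * (1 + 0.4 * roi_jitter * rng.standard_normal())
            th = p["t_half_s"] * (1 + roi_jitter * rng.standard_normal())
            model = hyperbolic(times, f0, finf, th)
            acq = np.exp(-acquisition_bleach_rate * times)
            noise = noise_sd * rng.standard_normal(times.size)
            f_bleach = background + amplitude * (model * acq + noise)
            f_ref = background + amplitude * acq
            f_bg = np.full_like(times, background)
            traces.append(
                FRAPTrace(
                    times_s=times, f_bleach=f_bleach, f_background=f_bg,
                    f_nonbleached=f_ref, pre_bleach_mean=pre_bleach_intensity,
                    roi_id=f"exp{e + 1}_roi{r + 1}", experiment_id=f"exp{e + 1}",
                )
            )
    return traces


def pooled_fit(traces: Sequence[FRAPTrace]) -> tuple[RecoveryFit, PooledCurve]:
    """Normalise, aggregate per experiment, pool, and fit the pooled mean."""
    if len(traces) == 0:
        raise FRAPError("no traces")
    by_exp: dict[str, list[FRAPTrace]] = {}
    for tr in traces:
        by_exp.setdefault(tr.experiment_id, []).append(tr)
    grid = traces[0].times_s
    means, variances, ns = [], [], []
    for exp_id, group in by_exp.items():
        curves = np.vstack(
            [regrid(tr.times_s, normalize_frap(tr), grid) for tr in group]
        )
        means.append(curves.mean(axis=0))
        variances.append(
            curves.var(axis=0, ddof=1) if len(group) > 1 else np.zeros(grid.size)
        )
        ns.append(len(group))
    pooled = pool_experiments(means, variances, ns, grid)
    fit = fit_hyperbolic(pooled.times_s, pooled.mean)
    return fit, pooled


def traces_to_frame(traces: Sequence[FRAPTrace]) -> pd.DataFrame:
    """Long-format CSV schema: time_s, roi_id, experiment_id, channel, intensity."""
    rows = []
    for tr in traces:
        for channel, arr in (
            ("bleach", tr.f_bleach),
            ("background", tr.f_background),
            ("nonbleached", tr.f_nonbleached),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": tr.times_s,
                        "roi_id": tr.roi_id,
                        "experiment_id": tr.experiment_id,
                        "channel": channel,
                        "intensity": arr,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[FRAPTrace]:
    traces = []
    for (exp_id, roi_id), g in df.groupby(["experiment_id", "roi_id"]):
        wide = g.pivot_table(index="time_s", columns="channel", values="intensity")
        for col in ("bleach", "background", "nonbleached"):
            if col not in wide.columns:
                raise FRAPError(f"trace {roi_id!r} is missing channel {col!r}")
        wide = wide.sort_index()
        traces.append(
            FRAPTrace(
                times_s=wide.index.to_numpy(),
                f_bleach=wide["bleach"].to_numpy(),
                f_background=wide["background"].to_numpy(),
                f_nonbleached=wide["nonbleached"].to_numpy(),
                roi_id=str(roi_id), experiment_id=str(exp_id),
            )
        )
    return traces
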