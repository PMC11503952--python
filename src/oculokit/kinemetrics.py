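"""Saccade kinematics: peak-velocity residuals and time-normalized profiles.

Peak velocity rises lawfully with amplitude (the main sequence), so raw
peak velocity confounds amplitude differences with velocity differences.
The residual of an ordinary least-squares regression of peak velocity on
amplitude removes that dependence and is the velocity measure used for
group contrasts.  The regression can be fitted pooled across a comparison
set (default — residuals then comparable across conditions, since a common
velocity shift moves only the intercept) or within each participant (used
by the trial-screening filter).

Time-normalized profiles map each saccade's duration onto [0, 1] and
average velocity (and distance travelled) within 10 equal-width time bins,
giving group velocity/amplitude trajectories over the saccade time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResidualModel",
    "fit_velocity_residuals",
    "residuals_by_participant",
    "time_normalized_profile",
    "profile_table",
]


@dataclass(frozen=True)
class ResidualModel:
    intercept: float
    slope: float
    scope: str
    n: int

    def predict(self, amplitude: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(amplitude, dtype=float)


def fit_velocity_residuals(
    trials: pd.DataFrame, scope: str = "pooled"
) -> tuple[ResidualModel, np.ndarray]:
    """OLS of peak velocity on amplitude; returns the model and residuals.

    ``trials`` needs ``amplitude_deg`` and ``peak_velocity_deg_s`` columns.
    Residuals (observed minus fitted) are aligned with the input rows.
    """
    x = trials["amplitude_deg"].to_numpy(dtype=float)
    y = trials["peak_velocity_deg_s"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 trials to fit the residual regression")
    if np.ptp(x) == 0:
        raise ValueError("constant amplitude: residual regression is rank deficient")
    slope, intercept = np.polyfit(x, y, 1)
    model = ResidualModel(float(intercept), float(slope), scope, len(x))
    return model, y - model.predict(x)


def residuals_by_participant(trials: pd.DataFrame) -> pd.Series:
    """Per-participant residual regressions; residuals aligned to input index."""
    out = pd.Series(np.nan, index=trials.index, name="velocity_residual")
    for _, grp in trials.groupby(["subject_id", "condition"], sort=False):
        if len(grp) >= 3 and np.ptp(grp["amplitude_deg"].to_numpy()) > 0:
            _, res = fit_velocity_residuals(grp, scope="participant")
            out.loc[grp.index] = res
    return out


def time_normalized_profile(
    t_norm: np.ndarray,
    velocity: np.ndarray,
    duration_ms: float | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Bin one saccade's velocity samples into equal-width normalized-time bins.

    Bins are half-open [(k-1)/n, k/n) with the last bin closed.  If fewer
    samples than ``n_bins`` are supplied the trace is linearly resampled to
    ``10 * n_bins`` points first.  When ``duration_ms`` is given, the
    cumulative distance travelled (trapezoidal integral of velocity over
    real time) is binned as well.
    """
    t = np.asarray(t_norm, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if t.size == 0:
        raise ValueError("empty velocity trace")
    if t.size < n_bins:
        fine = np.linspace(t.min(), t.max(), 10 * n_bins)
        v = np.interp(fine, t, v)
        t = fine
    bin_idx = np.minimum((t * n_bins).astype(int), n_bins - 1)
    rows = []
    cum = None
    if duration_ms is not None:
        dt_s = np.diff(t) * duration_ms / 1000.0
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt_s)])
    for k in range(n_bins):
        sel = bin_idx == k
        rows.append(
            {
                "bin_index": k + 1,
                "mean_velocity": float(v[sel].mean()) if sel.any() else np.nan,
                "mean_amplitude_travelled": (
                    float(cum[sel].mean()) if cum is not None and sel.any() else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def profile_table(profiles: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Average per-saccade binned profiles over a long-format sample table.

    ``profiles`` columns: subject_id, condition, task, trial_index, t_norm,
    velocity_deg_s and optionally sacc_duration_ms.  Returns one row per
    (subject, condition, bin) with mean velocity and distance travelled.
    """
    rows = []
    has_dur = "sacc_duration_ms" in profiles.columns
    keys = ["subject_id", "condition", "trial_index"]
    for (sid, cond, trial), grp in profiles.groupby(keys, sort=True):
        prof = time_normalized_profile(
            grp["t_norm"].to_numpy(),
            grp["velocity_deg_s"].to_numpy(),
            float(grp["sacc_duration_ms"].iloc[0]) if has_dur else None,
            n_bins,
        )
        prof.insert(0, "subject_id", sid)
        prof.insert(1, "condition", cond)
        rows.append(prof)
    per_saccade = pd.concat(rows, ignore_index=True)
    return (
        per_saccade.groupby(["subject_id", "condition", "bin_index"], as_index=False)[
            ["mean_velocity", "mean_amplitude_travelled"]
        ]
        .mean()
    )
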