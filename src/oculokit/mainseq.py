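"""Square-root main-sequence model and normative deviation scoring.

The main sequence is modelled as ``y = V * sqrt(x)`` with ``y`` the peak
velocity (deg/s), ``x`` the absolute amplitude (deg) and ``V`` the single
coefficient.  Least squares through the origin in sqrt-amplitude gives the
closed form ``V = sum(y * sqrt(x)) / sum(x)``.  The sampling distribution
of ``V`` is obtained by case-resampling the saccade set (1000 bootstrap
replicates by default); the reported coefficient is the bootstrap median
and the 95% interval the 2.5/97.5 percentiles.

Deviation from a normative curve: for each saccade of a test group,
``delta = y - V_ref * sqrt(x)`` evaluates the reference (control) curve at
the observed amplitude and subtracts it from the observed peak velocity.
A one-sample t-test and a default JZS Bayes factor ask whether the group's
deltas differ from zero, treating trials as the unit of analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .bayesstats import DEFAULT_PRIOR_SCALE, jzs_bf_t

__all__ = ["MainSequenceFit", "DeltaVelocity", "fit_sqrt", "bootstrap_v", "delta_peak_velocity"]


@dataclass(frozen=True)
class MainSequenceFit:
    V: float  # bootstrap median
    V_point: float  # closed-form estimate on the full sample
    ci95: tuple[float, float]
    n_saccades: int
    n_boot: int
    bootstrap_V: np.ndarray

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "V": self.V,
            "V_point": self.V_point,
            "ci95": list(self.ci95),
            "n_saccades": self.n_saccades,
            "n_boot": self.n_boot,
            "seed": seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def reference_from_json(path: str | Path) -> float:
        return float(json.loads(Path(path).read_text())["V"])


@dataclass(frozen=True)
class DeltaVelocity:
    deltas: np.ndarray
    mean: float
    se: float
    t: float
    df: float
    p_two_sided: float
    bf10: float
    reference_V: float


def fit_sqrt(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares V for y = V*sqrt(x): V = sum(y*sqrt(x)) / sum(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one saccade")
    if np.any(x <= 0):
        raise ValueError("amplitudes must be positive")
    return float(np.sum(y * np.sqrt(x)) / np.sum(x))


def bootstrap_v(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    subject_ids: np.ndarray | None = None,
) -> MainSequenceFit:
    """Case-resampling bootstrap of the main-sequence coefficient.

    Saccades are resampled with replacement as whole (x, y) cases; with
    ``subject_ids`` the resampling is stratified within participants so
    each replicate preserves the per-subject trial counts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 saccades to bootstrap")
    if np.any(x <= 0):
        raise ValueError("amplitudes must be positive")
    rng = np.random.default_rng(rng)
    if subject_ids is None:
        idx = rng.integers(0, n, size=(n_boot, n))
    else:
        subject_ids = np.asarray(subject_ids)
        cols = []
        for sid in np.unique(subject_ids):
            pos = np.flatnonzero(subject_ids == sid)
            cols.append(pos[rng.integers(0, pos.size, size=(n_boot, pos.size))])
        idx = np.concatenate(cols, axis=1)
    sx = x[idx]
    boot = (y[idx] * np.sqrt(sx)).sum(axis=1) / sx.sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MainSequenceFit(
        V=float(np.median(boot)),
        V_point=fit_sqrt(x, y),
        ci95=(float(lo), float(hi)),
        n_saccades=int(n),
        n_boot=int(n_boot),
        bootstrap_V=boot,
    )


def delta_peak_velocity(
    x: np.ndarray,
    y: np.ndarray,
    reference_V: float,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> DeltaVelocity:
    """Per-saccade deviation from a frozen normative curve, with tests.

    ``reference_V`` must come from an independent (control) fit; scoring a
    group against its own fit gives mean delta 0 by the normal equations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(reference_V):
        raise ValueError("reference_V must be a finite number")
    deltas = y - reference_V * np.sqrt(x)
    n = deltas.size
    t_res = stats.ttest_1samp(deltas, 0.0)
    t = float(t_res.statistic)
    # degenerate cases (n = 1 or zero-variance deltas) have no defined test
    bf = jzs_bf_t(t, n, prior_scale=prior_scale).bf10 if np.isfinite(t) and n >= 2 else float("nan")
    return DeltaVelocity(
        deltas=deltas,
        mean=float(deltas.mean()),
        se=float(deltas.std(ddof=1) / np.sqrt(n)),
        t=t,
        df=float(n - 1),
        p_two_sided=float(t_res.pvalue),
        bf10=bf,
        reference_V=float(reference_V),
    )
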