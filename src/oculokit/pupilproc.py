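"""Resting pupil-diameter preprocessing.

The chain turns a raw, blink-contaminated pupil trace into a single
z-scored mean diameter per recording session:

1. window QC — partition the trace into consecutive fixed-length windows
   (default 15 s) and drop windows with more than 15% of samples missing,
   judged on the RAW validity mask (before blink padding);
2. blink padding — extend every invalid run by 100 ms on each side, since
   the partially occluded pupil is misestimated around a blink;
3. linear interpolation across invalid gaps (constant extension at the
   trace boundaries);
4. Hann-window smoothing (unit-sum kernel, reflected edges);
5. z-scoring over the samples of the kept windows, removal of samples more
   than 3 SD from the mean, and averaging of the survivors.

The output is dimensionless (z units), so affine recording-scale
differences between sessions drop out by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthio import PupilTrace

__all__ = [
    "PupilSummary",
    "PupilParams",
    "window_qc",
    "pad_blinks",
    "interpolate_gaps",
    "hanning_smooth",
    "zscore_clip_mean",
    "process_trace",
    "summarize_pupil_table",
]


@dataclass(frozen=True)
class PupilParams:
    window_s: float = 15.0
    max_missing: float = 0.15
    pad_ms: float = 100.0
    hann_ms: float = 200.0
    clip_sd: float = 3.0


@dataclass(frozen=True)
class PupilSummary:
    mean_z: float
    n_windows_total: int
    n_windows_kept: int
    fraction_samples_clipped: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_windows_kept <= self.n_windows_total:
            raise ValueError("kept windows out of range")


class QCFailure(ValueError):
    """Raised when no window of a trace survives quality control."""


def window_qc(trace: PupilTrace, window_s: float = 15.0, max_missing: float = 0.15) -> np.ndarray:
    """Indices of windows whose missing fraction is <= ``max_missing``.

    Windows are consecutive blocks of ``window_s`` seconds; a trailing
    partial window is discarded.  A window is dropped only when its missing
    fraction strictly exceeds the threshold.
    """
    n = len(trace.diameter)
    if n == 0:
        raise ValueError("empty trace")
    w = int(round(window_s * trace.sampling_rate))
    n_windows = n // w
    if n_windows == 0:
        return np.array([], dtype=int)
    missing = ~trace.valid[: n_windows * w].reshape(n_windows, w)
    frac = missing.mean(axis=1)
    return np.flatnonzero(frac <= max_missing)


def pad_blinks(trace: PupilTrace, pad_ms: float = 100.0) -> PupilTrace:
    """Extend each invalid run by ``pad_ms`` on both sides.

    Runs are detected on the incoming mask, so applying the operation twice
    widens the margins twice; the pipeline calls it exactly once.
    """
    pad = int(round(pad_ms * trace.sampling_rate / 1000.0))
    valid = trace.valid.copy()
    n = len(valid)
    bad = np.flatnonzero(~trace.valid)
    if bad.size and pad > 0:
        # maximal runs of the original mask
        breaks = np.flatnonzero(np.diff(bad) > 1)
        starts = bad[np.r_[0, breaks + 1]]
        stops = bad[np.r_[breaks, bad.size - 1]]
        for s, e in zip(starts, stops):
            valid[max(s - pad, 0) : min(e + pad + 1, n)] = False
    return PupilTrace(trace.time, trace.diameter.copy(), valid, trace.sampling_rate)


def interpolate_gaps(trace: PupilTrace) -> PupilTrace:
    """Linearly interpolate invalid samples; constant-extend at the ends."""
    good = np.flatnonzero(trace.valid)
    if good.size < 2:
        raise ValueError("need at least two valid samples to interpolate")
    idx = np.arange(len(trace.diameter))
    diam = np.interp(idx, good, trace.diameter[good])  # np.interp clamps ends
    return PupilTrace(trace.time, diam, np.ones(len(diam), dtype=bool), trace.sampling_rate)


def hanning_smooth(trace: PupilTrace, window_ms: float = 200.0) -> PupilTrace:
    """Convolve with a unit-sum Hann kernel; edges handled by reflection."""
    w = int(round(window_ms * trace.sampling_rate / 1000.0))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    n = len(trace.diameter)
    if w > n:
        raise ValueError(f"smoothing window ({w} samples) longer than trace ({n})")
    kernel = np.hanning(w + 2)[1:-1]  # strip the zero endpoints
    kernel = kernel / kernel.sum()
    half = w // 2
    padded = np.pad(trace.diameter, half, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return PupilTrace(trace.time, smoothed, trace.valid.copy(), trace.sampling_rate)


def kept_samples(
    trace: PupilTrace, kept_windows: np.ndarray, window_s: float = 15.0
) -> np.ndarray:
    """Values of the samples belonging to the kept windows."""
    w = int(round(window_s * trace.sampling_rate))
    kept_windows = np.asarray(kept_windows, dtype=int)
    sel = np.zeros(len(trace.diameter), dtype=bool)
    for k in kept_windows:
        sel[k * w : (k + 1) * w] = True
    return trace.diameter[sel]


def zscore_clip_mean(
    trace: PupilTrace,
    kept_windows: np.ndarray,
    window_s: float = 15.0,
    clip_sd: float = 3.0,
    center: float | None = None,
    scale: float | None = None,
) -> PupilSummary:
    """Z-score the kept-window samples, drop |z| > ``clip_sd``, average.

    ``center``/``scale`` override the z-scoring statistics; by default they
    come from the trace's own kept samples.  A subject-level scope (pooling
    the statistics over a subject's sessions) keeps between-condition
    diameter differences visible in the session means.
    """
    n = len(trace.diameter)
    w = int(round(window_s * trace.sampling_rate))
    n_windows = n // w
    kept_windows = np.asarray(kept_windows, dtype=int)
    if kept_windows.size == 0:
        raise QCFailure("no window survived quality control")
    x = kept_samples(trace, kept_windows, window_s)
    if center is None:
        center = float(x.mean())
    if scale is None:
        scale = float(x.std())
    if scale == 0:
        raise ValueError("zero variance; z-score undefined")
    z = (x - center) / scale
    keep = np.abs(z) <= clip_sd
    return PupilSummary(
        mean_z=float(z[keep].mean()),
        n_windows_total=int(n_windows),
        n_windows_kept=int(kept_windows.size),
        fraction_samples_clipped=float(1.0 - keep.mean()),
    )


def _prepare(trace: PupilTrace, params: PupilParams) -> tuple[PupilTrace, np.ndarray]:
    """QC on the raw mask, then pad -> interpolate -> smooth."""
    kept = window_qc(trace, params.window_s, params.max_missing)
    if kept.size == 0:
        raise QCFailure("no window survived quality control")
    padded = pad_blinks(trace, params.pad_ms)
    filled = interpolate_gaps(padded)
    smoothed = hanning_smooth(filled, params.hann_ms)
    return smoothed, kept


def process_trace(
    trace: PupilTrace,
    params: PupilParams = PupilParams(),
    center: float | None = None,
    scale: float | None = None,
) -> PupilSummary:
    """Full preprocessing chain for one session's resting trace."""
    smoothed, kept = _prepare(trace, params)
    return zscore_clip_mean(smoothed, kept, params.window_s, params.clip_sd, center, scale)


def summarize_pupil_table(
    pupil: pd.DataFrame, params: PupilParams = PupilParams(), sampling_rate: float = 500.0
) -> pd.DataFrame:
    """Preprocess every session of a long pupil table.

    Expects columns subject_id, condition, time_ms, pupil_au, valid (0/1).
    Z-scoring statistics are pooled over each subject's sessions so a drug
    effect on diameter survives standardization; sessions failing QC
    outright are reported with NaN mean_z and zero kept windows rather than
    dropped silently.
    """
    prepared: dict[str, list[tuple[str, PupilTrace | None, np.ndarray | None, int]]] = {}
    for (sid, cond), grp in pupil.groupby(["subject_id", "condition"], sort=True):
        trace = PupilTrace(
            time=grp["time_ms"].to_numpy(dtype=float),
            diameter=grp["pupil_au"].to_numpy(dtype=float),
            valid=grp["valid"].to_numpy().astype(bool),
            sampling_rate=sampling_rate,
        )
        n_total = len(trace.diameter) // int(round(params.window_s * sampling_rate))
        try:
            smoothed, kept = _prepare(trace, params)
            prepared.setdefault(sid, []).append((cond, smoothed, kept, n_total))
        except QCFailure:
            prepared.setdefault(sid, []).append((cond, None, None, n_total))

    rows = []
    for sid, sessions in prepared.items():
        pooled = [
            kept_samples(tr, kept, params.window_s)
            for _, tr, kept, _ in sessions
            if tr is not None
        ]
        if pooled:
            allx = np.concatenate(pooled)
            center, scale = float(allx.mean()), float(allx.std())
        for cond, tr, kept, n_total in sessions:
            if tr is None:
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": cond,
                        "mean_z": np.nan,
                        "n_windows_kept": 0,
                        "n_windows_total": n_total,
                    }
                )
                continue
            s = zscore_clip_mean(tr, kept, params.window_s, params.clip_sd, center, scale)
            rows.append(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "mean_z": s.mean_z,
                    "n_windows_kept": s.n_windows_kept,
                    "n_windows_total": s.n_windows_total,
                }
            )
    return pd.DataFrame(rows).sort_values(["subject_id", "condition"]).reset_index(drop=True)
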