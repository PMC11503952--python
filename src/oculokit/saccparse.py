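"""Primary-saccade selection, validity gating and trial filtering.

For every trial of a prosaccade/antisaccade block this module

* selects the primary saccade — the first event after target onset with
  amplitude strictly between 1.5 deg and 10 deg (excluding microsaccades
  and off-screen excursions) and latency strictly between 90 ms and
  2500 ms (excluding anticipations and inattention);
* classifies its direction from the sign of the horizontal displacement
  (prosaccade correct = toward the target, antisaccade correct = away);
* removes trials more extreme than +/-2.5 SD from the participant's own
  mean — jointly over latency, peak velocity, amplitude and the
  peak-velocity residual for prosaccades, over latency only for
  antisaccades; the filter is a single pass, SDs are not recomputed after
  removals;
* summarizes each participant-condition-task cell, the antisaccade error
  rate being incorrect / (total - removed).

All bounds are strict inequalities; ties are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinemetrics

__all__ = ["ParseParams", "select_primary", "participant_outlier_filter", "summarize_task", "process_events"]

PROSACCADE_FILTER_MEASURES = ("latency_ms", "peak_velocity_deg_s", "amplitude_deg", "velocity_residual")
ANTISACCADE_FILTER_MEASURES = ("latency_ms",)


@dataclass(frozen=True)
class ParseParams:
    amp_min: float = 1.5
    amp_max: float = 10.0
    lat_min: float = 90.0
    lat_max: float = 2500.0
    sd_k: float = 2.5
    # prosaccade trials whose first valid saccade goes away from the target:
    # "discard" drops the trial; "search" takes the first valid toward-target event
    prosaccade_wrong_way: str = "discard"


def select_primary(events: pd.DataFrame, params: ParseParams = ParseParams()) -> pd.DataFrame:
    """Pick the primary saccade per trial and classify its direction.

    ``events`` holds one row per detected saccade with the standard event
    columns; latency is ``sacc_onset_ms - target_onset_ms`` when a
    ``latency_ms`` column is not already present.  Returns one row per
    trial: the selected event with ``valid`` and ``removal_reason`` columns
    and, for valid trials, a ``correct`` flag.
    """
    ev = events.copy()
    if "latency_ms" not in ev.columns:
        ev["latency_ms"] = ev["sacc_onset_ms"] - ev["target_onset_ms"]
    keys = ["subject_id", "condition", "task", "trial_index"]
    rows = []
    for key, grp in ev.groupby(keys, sort=True):
        grp = grp.sort_values("sacc_onset_ms")
        amp = grp["amplitude_deg"].to_numpy()
        lat = grp["latency_ms"].to_numpy()
        ok = (
            (amp > params.amp_min)
            & (amp < params.amp_max)
            & (lat > params.lat_min)
            & (lat < params.lat_max)
        )
        task = grp["task"].iloc[0]
        row, reason = _pick(grp, ok, task, params)
        if row is None:
            base = grp.iloc[0].to_dict()
            base.update(valid=False, removal_reason=reason, correct=np.nan)
            rows.append(base)
        else:
            rec = row.to_dict()
            correct, amb = _classify(rec, task)
            if amb:
                rec.update(valid=False, removal_reason="ambiguous_direction", correct=np.nan)
            else:
                rec.update(valid=True, removal_reason="", correct=correct)
            rows.append(rec)
    return pd.DataFrame(rows).reset_index(drop=True)


def _pick(grp: pd.DataFrame, ok: np.ndarray, task: str, params: ParseParams):
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None, "no_valid_saccade"
    first = grp.iloc[idx[0]]
    if task == "prosaccade":
        sign = np.sign(first["end_x_deg"] - first["start_x_deg"])
        target = 1.0 if first["target_side"] == "right" else -1.0
        if sign != target and sign != 0:  # zero displacement handled as ambiguous later
            if params.prosaccade_wrong_way == "discard":
                return None, "wrong_direction"
            for j in idx:  # first valid saccade directed toward the target
                cand = grp.iloc[j]
                if np.sign(cand["end_x_deg"] - cand["start_x_deg"]) == target:
                    return cand, ""
            return None, "wrong_direction"
    return first, ""


def _classify(rec: dict, task: str) -> tuple[bool, bool]:
    """(correct, ambiguous) from horizontal displacement sign vs target side."""
    disp = rec["end_x_deg"] - rec["start_x_deg"]
    if disp == 0:
        return False, True
    toward = np.sign(disp) == (1.0 if rec["target_side"] == "right" else -1.0)
    correct = toward if task == "prosaccade" else not toward
    return bool(correct), False


def participant_outlier_filter(
    primaries: pd.DataFrame, params: ParseParams = ParseParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove trials deviating > k SD from the participant's mean.

    Prosaccades are screened jointly on latency, peak velocity, amplitude
    and the within-participant peak-velocity residual; antisaccades on
    latency only.  Cells with fewer than 3 valid trials are flagged and
    left unfiltered.  Returns (filtered primaries, removal log); removed
    and gate-invalid trials appear in the log exactly once.
    """
    df = primaries.copy()
    log_rows = [
        r[["subject_id", "condition", "task", "trial_index", "removal_reason"]].to_dict()
        for _, r in df[~df["valid"]].iterrows()
    ]
    valid = df[df["valid"]].copy()
    valid["velocity_residual"] = np.nan
    keep_mask = pd.Series(True, index=valid.index)
    cell_keys = ["subject_id", "condition", "task"]
    for key, grp in valid.groupby(cell_keys, sort=True):
        task = grp["task"].iloc[0]
        if len(grp) < 3:
            continue  # too few trials to estimate spread; flagged, not filtered
        if task == "prosaccade":
            if np.ptp(grp["amplitude_deg"].to_numpy(dtype=float)) > 0:
                res = kinemetrics.fit_velocity_residuals(grp, scope="participant")[1]
                valid.loc[grp.index, "velocity_residual"] = res
                grp = valid.loc[grp.index]
            measures = PROSACCADE_FILTER_MEASURES
        else:
            measures = ANTISACCADE_FILTER_MEASURES
        out = pd.Series(False, index=grp.index)
        for m in measures:
            x = grp[m].astype(float)
            sd = x.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                continue
            out |= (x - x.mean()).abs() > params.sd_k * sd
        keep_mask.loc[out[out].index] = False
        for i in out[out].index:
            log_rows.append(
                {
                    "subject_id": grp.loc[i, "subject_id"],
                    "condition": grp.loc[i, "condition"],
                    "task": task,
                    "trial_index": grp.loc[i, "trial_index"],
                    "removal_reason": "participant_outlier",
                }
            )
    kept = valid[keep_mask].drop(columns=["velocity_residual"])
    removal_log = pd.DataFrame(
        log_rows, columns=["subject_id", "condition", "task", "trial_index", "removal_reason"]
    )
    return kept.reset_index(drop=True), removal_log.reset_index(drop=True)


def summarize_task(
    primaries: pd.DataFrame, removal_log: pd.DataFrame, n_trials_total: int = 24
) -> pd.DataFrame:
    """Per participant-condition-task counts and antisaccade error rate.

    error_rate = n incorrect / (n_trials_total - n removed); NaN when no
    trial completed.
    """
    keys = ["subject_id", "condition", "task"]
    removed = removal_log.groupby(keys).size() if len(removal_log) else pd.Series(dtype=int)
    rows = []
    for key, grp in primaries.groupby(keys, sort=True):
        n_removed = int(removed.get(key, 0))
        n_completed = n_trials_total - n_removed
        n_errors = int((~grp["correct"].astype(bool)).sum())
        rows.append(
            {
                "subject_id": key[0],
                "condition": key[1],
                "task": key[2],
                "n_trials_total": n_trials_total,
                "n_removed": n_removed,
                "n_completed": n_completed,
                "n_errors": n_errors,
                "error_rate": n_errors / n_completed if n_completed > 0 else np.nan,
                "mean_latency_ms": float(grp["latency_ms"].mean()),
                "mean_amplitude_deg": float(grp["amplitude_deg"].mean()),
                "mean_peak_velocity_deg_s": float(grp["peak_velocity_deg_s"].mean()),
            }
        )
    return pd.DataFrame(rows)


def process_events(
    events: pd.DataFrame, params: ParseParams = ParseParams(), n_trials_total: int = 24
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """select_primary -> outlier filter -> summary, in the fixed order.

    Returns (primary saccades, removal log, per-cell summary).
    """
    prim = select_primary(events, params)
    kept, removal_log = participant_outlier_filter(prim, params)
    summary = summarize_task(kept, removal_log, n_trials_total)
    return kept, removal_log, summary
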