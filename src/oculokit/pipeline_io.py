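"""Pipeline orchestration, table I/O, configuration and run manifests.

All tabular artefacts are plain UTF-8, header-first TSV (pupil traces CSV);
fitted models are JSON.  ``run_all`` drives the full chain on a simulated
cohort or on externally supplied event/pupil tables:

    simulate -> pupil preprocessing -> saccade parsing -> kinematics
    -> main sequence (control reference first, then each patient condition)
    -> summary statistics and report

and writes a manifest (config hash, seed, per-stage row counts) that makes
a run reproducible and auditable: every trial removed at any stage appears
exactly once in removal_log.tsv.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinemetrics, mainseq, pupilproc, saccparse, synthio

__all__ = ["RunConfig", "RunManifest", "StageError", "read_table", "write_table", "run_all"]

__version__ = "0.1.0"

REQUIRED_EVENT_COLUMNS = synthio.EVENT_COLUMNS
REQUIRED_PUPIL_COLUMNS = ["subject_id", "condition", "time_ms", "pupil_au", "valid"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "oculokit_out"
    events_path: str | None = None  # None -> simulate
    pupil_path: str | None = None
    seed: int = 0
    simulate: bool = True
    pupil_duration_s: float = 180.0
    write_pupil_csv: bool = False
    n_boot: int = 1000
    generator: synthio.GeneratorConfig = field(default_factory=synthio.GeneratorConfig)
    parse: saccparse.ParseParams = field(default_factory=saccparse.ParseParams)
    pupil: pupilproc.PupilParams = field(default_factory=pupilproc.PupilParams)
    comparisons: Sequence[tuple[str, str]] = (("placebo", "control"), ("atomoxetine", "control"))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            g = dict(d["generator"])
            if "drug_effect" in g and isinstance(g["drug_effect"], dict):
                g["drug_effect"] = synthio.DrugEffect(**g["drug_effect"])
            for k in ("eccentricities", "fixation_duration_range", "blink_duration_range_ms"):
                if k in g and isinstance(g[k], list):
                    g[k] = tuple(g[k])
            d["generator"] = synthio.GeneratorConfig(**g)
        if "parse" in d and isinstance(d["parse"], dict):
            d["parse"] = saccparse.ParseParams(**d["parse"])
        if "pupil" in d and isinstance(d["pupil"], dict):
            d["pupil"] = pupilproc.PupilParams(**d["pupil"])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    row_counts: dict[str, int]
    input_checksums: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    for c in cols:
        if df[c].dtype == object:
            bad = df[c].astype(str).str.contains(",", regex=False)
            if bad.any():
                raise ValueError(
                    f"{path}: column '{c}' contains comma-localized numbers "
                    f"(e.g. {df[c][bad].iloc[0]!r}); use '.' as the decimal separator"
                )
            df[c] = pd.to_numeric(df[c])


def read_table(path: str | Path, required: Sequence[str], numeric: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV/CSV table, enforcing the schema column by column."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    _check_numeric(df, numeric, str(path))
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    numeric = [
        "target_onset_ms", "target_eccentricity_deg", "sacc_onset_ms",
        "sacc_duration_ms", "amplitude_deg", "peak_velocity_deg_s",
        "start_x_deg", "end_x_deg",
    ]
    return read_table(path, REQUIRED_EVENT_COLUMNS, numeric)


def read_pupil(path: str | Path) -> pd.DataFrame:
    return read_table(path, REQUIRED_PUPIL_COLUMNS, ["time_ms", "pupil_au"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write the output bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    checksums: dict[str, str] = {}
    report: list[str] = [f"oculokit {__version__} run (seed {config.seed})", ""]

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate:
            gen = replace(config.generator, seed=config.seed)
            cohort = synthio.gen_cohort(gen, pupil_duration=config.pupil_duration_s)
            events = synthio.cohort_events(cohort)
            profiles = synthio.cohort_profiles(cohort)
            synthio.write_cohort(cohort, out, write_pupil=config.write_pupil_csv)
            pupil_frames = [
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "condition": s.condition,
                        "time_ms": s.pupil.time,
                        "pupil_au": s.pupil.diameter,
                        "valid": s.pupil.valid.astype(int),
                    }
                )
                for s in cohort.sessions
            ]
            pupil = pd.concat(pupil_frames, ignore_index=True)
            sampling_rate = gen.sampling_rate
        else:
            if config.events_path is None:
                raise FileNotFoundError("events_path is required when simulate is off")
            events = read_events(config.events_path)
            checksums["events"] = _sha256(Path(config.events_path))
            profiles = None
            if config.pupil_path is None:
                raise FileNotFoundError("pupil_path is required when simulate is off")
            pupil = read_pupil(config.pupil_path)
            checksums["pupil"] = _sha256(Path(config.pupil_path))
            sampling_rate = 500.0
    except Exception as e:  # noqa: BLE001 - stage context is the contract
        raise StageError("inputs", str(e)) from e
    counts["events_in"] = len(events)

    # ---- stage: pupil --------------------------------------------------
    try:
        pupil_summary = pupilproc.summarize_pupil_table(pupil, config.pupil, sampling_rate)
        write_table(pupil_summary, out / "pupil_summary.tsv")
    except Exception as e:
        raise StageError("pupil", str(e)) from e
    counts["pupil_sessions"] = len(pupil_summary)

    # ---- stage: parse --------------------------------------------------
    try:
        primaries, removal_log, task_summary = saccparse.process_events(
            events, config.parse, n_trials_total=int(events.groupby(
                ["subject_id", "condition", "task"]
            )["trial_index"].nunique().iloc[0])
        )
        write_table(primaries, out / "primary_saccades.tsv")
        write_table(removal_log, out / "removal_log.tsv")
        write_table(task_summary, out / "task_summary.tsv")
    except Exception as e:
        raise StageError("parse", str(e)) from e
    counts["primary_saccades"] = len(primaries)
    counts["removed_trials"] = len(removal_log)

    # ---- stage: kinemetrics -------------------------------------------
    try:
        pro = primaries[primaries["task"] == "prosaccade"].copy()
        model, res = kinemetrics.fit_velocity_residuals(pro, scope="pooled")
        pro["velocity_residual"] = res
        write_table(
            pro[["subject_id", "condition", "task", "trial_index", "amplitude_deg",
                 "peak_velocity_deg_s", "velocity_residual"]],
            out / "residuals.tsv",
        )
        if profiles is not None:
            prof_tbl = kinemetrics.profile_table(profiles)
            write_table(prof_tbl, out / "profiles.tsv")
            counts["profile_rows"] = len(prof_tbl)
    except Exception as e:
        raise StageError("kinemetrics", str(e)) from e
    counts["prosaccades"] = len(pro)

    # ---- stage: mainseq ------------------------------------------------
    try:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA15]))
        fits: dict[str, mainseq.MainSequenceFit] = {}
        deltas_rows = []
        ctrl = pro[pro["condition"] == "control"]
        if len(ctrl) >= 2:
            fits["control"] = mainseq.bootstrap_v(
                ctrl["amplitude_deg"].to_numpy(),
                ctrl["peak_velocity_deg_s"].to_numpy(),
                n_boot=config.n_boot,
                rng=rng,
            )
        for cond in ("placebo", "atomoxetine"):
            sub = pro[pro["condition"] == cond]
            if len(sub) < 2:
                continue
            fits[cond] = mainseq.bootstrap_v(
                sub["amplitude_deg"].to_numpy(),
                sub["peak_velocity_deg_s"].to_numpy(),
                n_boot=config.n_boot,
                rng=rng,
            )
            if "control" in fits:
                dv = mainseq.delta_peak_velocity(
                    sub["amplitude_deg"].to_numpy(),
                    sub["peak_velocity_deg_s"].to_numpy(),
                    fits["control"].V,
                )
                deltas_rows.append(
                    {
                        "condition": cond,
                        "n": len(sub),
                        "mean_delta": dv.mean,
                        "se_delta": dv.se,
                        "t": dv.t,
                        "df": dv.df,
                        "p_two_sided": dv.p_two_sided,
                        "bf10": dv.bf10,
                        "reference_V": dv.reference_V,
                    }
                )
        for name, fit in fits.items():
            fit.to_json(out / f"mainseq_{name}.json", seed=config.seed)
        deltas = pd.DataFrame(deltas_rows)
        write_table(deltas, out / "deltas.tsv")
    except Exception as e:
        raise StageError("mainseq", str(e)) from e
    counts["mainseq_fits"] = len(fits)
    counts["delta_tests"] = len(deltas)

    # ---- stage: report -------------------------------------------------
    report.append("Main-sequence fits (V, deg/s per sqrt(deg)):")
    for name, fit in fits.items():
        report.append(
            f"  {name:12s} V = {fit.V:7.2f}  ci95 = [{fit.ci95[0]:.2f}, {fit.ci95[1]:.2f}]"
            f"  n = {fit.n_saccades}"
        )
    report.append("")
    report.append("Delta peak-velocity tests against the control curve:")
    for r in deltas_rows:
        report.append(
            f"  {r['condition']:12s} mean = {r['mean_delta']:6.2f} deg/s  "
            f"t({r['df']:.0f}) = {r['t']:.2f}  p = {r['p_two_sided']:.3g}  BF10 = {r['bf10']:.3g}"
        )
    report.append("")
    anti = task_summary[task_summary["task"] == "antisaccade"]
    for cond, grp in anti.groupby("condition"):
        report.append(
            f"Antisaccade error rate, {cond}: "
            f"{grp['error_rate'].mean():.3f} (mean over {len(grp)} sessions)"
        )
    ok = pupil_summary.dropna(subset=["mean_z"])
    for cond, grp in ok.groupby("condition"):
        report.append(
            f"Resting pupil mean_z, {cond}: {grp['mean_z'].mean():+.3f} over {len(grp)} sessions"
        )
    (out / "report.txt").write_text("\n".join(report) + "\n")

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        row_counts=counts,
        input_checksums=checksums,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
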