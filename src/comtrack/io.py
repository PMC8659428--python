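"""Study serialisation: manifests, per-trial CSV time series, configuration.

On-disk layout of a study directory::

    manifest.csv        participant_id, task_id, com_file, tracker_file,
                        event_time_mocap_s, event_time_tracker_s,
                        com_missing, tracker_missing
    body_model.json     mass fractions, segment COM offsets, marker geometry
    study_config.json   the full StudyConfig (for provenance)
    trials/*.csv        marker tables (time_s, <seg>_m<k>_{x,y,z}) and
                        tracker tables (time_s, x, y, z; engine frame)

All positions are metres; CSVs are comma-separated, dot-decimal, UTF-8,
with a header row. Floats are written in round-trip precision so a
write/read cycle is lossless.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body import AnthropometricModel, SegmentParams
from .errors import ComtrackError, SchemaError
from .kinematics import MarkerClusterSet
from .preprocess import AlignmentEvent
from .synthetic import (
    MissingnessPlan,
    SensorErrorModel,
    StudyConfig,
    StudyDataset,
    TaskRecording,
    TaskSpec,
)
from .timeseries import TimeSeries3D

MANIFEST_COLUMNS = [
    "participant_id",
    "task_id",
    "com_file",
    "tracker_file",
    "event_time_mocap_s",
    "event_time_tracker_s",
    "com_missing",
    "tracker_missing",
]

_AXES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------
def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write a study as a manifest + per-trial CSV tree; returns manifest path."""
    out = Path(out_dir)
    trials = out / "trials"
    trials.mkdir(parents=True, exist_ok=True)
    _write_body_model(dataset, out / "body_model.json")
    (out / "study_config.json").write_text(config_to_json(dataset.config))
    rows = []
    for rec in dataset.records:
        stem = f"P{rec.participant_id:02d}_T{rec.task_id:02d}"
        com_file = ""
        tracker_file = ""
        if not rec.com_missing:
            com_file = f"trials/{stem}_markers.csv"
            _write_marker_csv(rec.clusters, out / com_file)
        if not rec.tracker_missing:
            tracker_file = f"trials/{stem}_tracker.csv"
            _write_tracker_csv(rec.tracker_engine, out / tracker_file)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "task_id": rec.task_id,
                "com_file": com_file,
                "tracker_file": tracker_file,
                "event_time_mocap_s": rec.event.event_time_mocap,
                "event_time_tracker_s": rec.event.event_time_tracker,
                "com_missing": int(rec.com_missing),
                "tracker_missing": int(rec.tracker_missing),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _write_marker_csv(clusters: dict[str, MarkerClusterSet], path: Path) -> None:
    first = next(iter(clusters.values()))
    data = {"time_s": first.timestamps}
    for sid, cl in clusters.items():
        for m in range(cl.local_coords.shape[0]):
            for ai, ax in enumerate(_AXES):
                data[f"{sid}_m{m + 1}_{ax}"] = cl.observed[:, m, ai]
    pd.DataFrame(data).to_csv(path, index=False)


def _write_tracker_csv(ts: TimeSeries3D, path: Path) -> None:
    pd.DataFrame(
        {
            "time_s": ts.timestamps,
            "x": ts.positions[:, 0],
            "y": ts.positions[:, 1],
            "z": ts.positions[:, 2],
        }
    ).to_csv(path, index=False)


def _write_body_model(dataset: StudyDataset, path: Path) -> None:
    model = dataset.model
    local = {}
    for rec in dataset.records:
        if rec.clusters is not None:
            local = {sid: cl.local_coords.tolist() for sid, cl in rec.clusters.items()}
            break
    payload = {
        "segments": {
            sid: {
                "mass_fraction": p.mass_fraction,
                "com_offset": list(p.com_offset),
                "marker_local": local.get(sid),
            }
            for sid, p in model.segments.items()
        }
    }
    path.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------
class LazyTrial:
    """A manifest row whose streams load on demand."""

    def __init__(self, base_dir: Path, row: dict, body: dict, sample_rate: float):
        self.base_dir = base_dir
        self.participant_id = int(row["participant_id"])
        self.task_id = int(row["task_id"])
        self.com_file = row["com_file"]
        self.tracker_file = row["tracker_file"]
        self.event = AlignmentEvent(
            float(row["event_time_mocap_s"]), float(row["event_time_tracker_s"])
        )
        self.com_missing = bool(int(row["com_missing"]))
        self.tracker_missing = bool(int(row["tracker_missing"]))
        self._body = body
        self.sample_rate = sample_rate

    def load(self) -> TaskRecording:
        clusters = None
        tracker = None
        if not self.com_missing:
            clusters = _read_marker_csv(self.base_dir / self.com_file, self._body)
        if not self.tracker_missing:
            df = pd.read_csv(self.base_dir / self.tracker_file, float_precision="round_trip")
            tracker = TimeSeries3D(
                df["time_s"].to_numpy(), df[["x", "y", "z"]].to_numpy()
            )
        return TaskRecording(
            participant_id=self.participant_id,
            task_id=self.task_id,
            sample_rate=self.sample_rate,
            clusters=clusters,
            tracker_engine=tracker,
            event=self.event,
        )


def _read_marker_csv(path: Path, body: dict) -> dict[str, MarkerClusterSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    clusters = {}
    for sid, seg in body["segments"].items():
        local = np.asarray(seg["marker_local"], dtype=float)
        m = local.shape[0]
        cols = [f"{sid}_m{k + 1}_{ax}" for k in range(m) for ax in _AXES]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing marker columns {missing[:3]}")
        observed = df[cols].to_numpy().reshape(t.size, m, 3)
        clusters[sid] = MarkerClusterSet(sid, local, observed, t)
    return clusters


def read_trial_manifest(path: str | Path) -> StudyDataset:
    """Read a study directory through its manifest into lazy trial handles.

    Malformed rows are reported with their (1-based, header-exclusive) row
    numbers; referenced stream files must exist unless the corresponding
    missing flag is set.
    """
    manifest = Path(path)
    base = manifest.parent
    try:
        df = pd.read_csv(manifest, keep_default_na=False)
    except OSError as exc:
        raise ComtrackError(f"cannot read manifest: {exc}") from exc
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"manifest missing required columns: {sorted(missing_cols)}")
    body_path = base / "body_model.json"
    if not body_path.exists():
        raise ComtrackError(f"study directory lacks body_model.json: {base}")
    body = json.loads(body_path.read_text())
    config = None
    cfg_path = base / "study_config.json"
    if cfg_path.exists():
        config = config_from_json(cfg_path.read_text())
    sample_rate = config.sample_rate if config is not None else 100.0
    model = AnthropometricModel(
        {
            sid: SegmentParams(seg["mass_fraction"], tuple(seg["com_offset"]))
            for sid, seg in body["segments"].items()
        }
    )
    records = []
    errors = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            tid = int(row["task_id"])
            if not 1 <= tid <= 12:
                raise SchemaError(f"unknown task_id {tid}")
            trial = LazyTrial(base, row, body, sample_rate)
            if not trial.com_missing and not (base / trial.com_file).exists():
                raise ComtrackError(f"referenced file missing: {trial.com_file}")
            if not trial.tracker_missing and not (base / trial.tracker_file).exists():
                raise ComtrackError(f"referenced file missing: {trial.tracker_file}")
            records.append(trial)
        except (ValueError, ComtrackError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise SchemaError("malformed manifest rows: " + "; ".join(errors[:5]))
    return StudyDataset(config=config, model=model, records=records)


# ---------------------------------------------------------------------------
# config serialisation
# ---------------------------------------------------------------------------
def config_to_json(config: StudyConfig) -> str:
    d = dataclasses.asdict(config)
    d["missingness"] = {
        "com_missing_trials": sorted(config.missingness.com_missing_trials),
        "tracker_missing_trials": sorted(config.missingness.tracker_missing_trials),
    }
    return json.dumps(d, indent=1)


def config_from_json(text: str) -> StudyConfig:
    d = json.loads(text)
    return _config_from_dict(d)


def _config_from_dict(d: dict) -> StudyConfig:
    specs = tuple(TaskSpec(**{**s, "amplitude": tuple(s["amplitude"]),
                              "sway_band": tuple(s["sway_band"])})
                  for s in d["task_specs"])
    err = d["sensor_error"]
    error = SensorErrorModel(
        constant_offset=tuple(err["constant_offset"]),
        noise_sd=tuple(err["noise_sd"]),
        sway_gain=tuple(err["sway_gain"]),
        dropout_after_s=err.get("dropout_after_s"),
    )
    miss = d["missingness"]
    plan = MissingnessPlan(
        com_missing_trials=frozenset(tuple(x) for x in miss["com_missing_trials"]),
        tracker_missing_trials=frozenset(tuple(x) for x in miss["tracker_missing_trials"]),
    )
    return StudyConfig(
        n_participants=int(d["n_participants"]),
        task_specs=specs,
        sensor_error=error,
        missingness=plan,
        sample_rate=float(d.get("sample_rate", 100.0)),
        seed=int(d.get("seed", 0)),
    )


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return _config_from_dict(yaml.safe_load(text))
    return config_from_json(text)
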