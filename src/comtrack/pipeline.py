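"""End-to-end orchestration: simulate -> process -> report.

``run_pipeline`` ties the stages together on a study (in-memory or read
from a manifest) and writes the result tables:

* ``trial_agreement.csv`` — per-trial per-axis RMS error (cm) + status;
* ``task_summary.csv``    — per-task n, mean, SD per axis (cm);
* ``displacement.csv``    — long-format ranges for the standing tasks (cm);
* ``stats_results.csv``   — per-direction F, p, BF10, evidence label;
* ``run_log.json``        — version, config hash, seed, resolved parameters
                            and trial accounting, so any table can be
                            regenerated.

Identical study + parameters produce byte-identical CSVs (plots excluded).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import analyze_study, summarize_by_task
from .errors import ComtrackError
from .io import config_to_json, read_trial_manifest, write_study
from .preprocess import DEFAULT_SG_ORDER, DEFAULT_SG_WINDOW, ENGINE_TO_LAB, FrameMapping
from .stats import DEFAULT_PRIOR_SCALE, analyze_directions
from .synthetic import StudyConfig, StudyDataset, generate_study

_HEADER_NOTE = (
    "# units: cm; lab axes: X forward (anteroposterior), "
    "Y left (mediolateral), Z up\n"
)


@dataclass
class PipelineResult:
    summary: object
    stats: list
    out_dir: Path
    agreement_rows: list
    displacement_rows: list


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_NOTE)
        df.to_csv(fh, index=False)


def simulate(config: StudyConfig, out_dir: str | Path) -> Path:
    """Generate a study and write it to disk; returns the manifest path."""
    dataset = generate_study(config)
    return write_study(dataset, out_dir)


def run_pipeline(
    study: StudyDataset | str | Path,
    out_dir: str | Path,
    mapping: FrameMapping = ENGINE_TO_LAB,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    dc_removal: bool = True,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> PipelineResult:
    """Process a study end to end and write the result tables."""
    if isinstance(study, (str, Path)):
        study = read_trial_manifest(study)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows, disp = analyze_study(
        study, mapping=mapping, sg_window=sg_window, sg_order=sg_order, dc_removal=dc_removal
    )
    summary = summarize_by_task(rows)
    try:
        stats = analyze_directions(disp, prior_scale=prior_scale)
    except ComtrackError:
        stats = []

    trial_df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "task_id": [r.task_id for r in rows],
            "status": [r.status for r in rows],
            "rms_x_cm": [r.rms[0] if r.rms else None for r in rows],
            "rms_y_cm": [r.rms[1] if r.rms else None for r in rows],
            "rms_z_cm": [r.rms[2] if r.rms else None for r in rows],
        }
    )
    _write_csv(trial_df, out / "trial_agreement.csv")

    task_df = pd.DataFrame(
        {
            "task_id": [s.task_id for s in summary.task_summaries],
            "task": [s.task_name for s in summary.task_summaries],
            "n": [s.n for s in summary.task_summaries],
            **{
                f"{stat}_{ax}_cm": [
                    getattr(s, stat)[i] if getattr(s, stat) is not None else None
                    for s in summary.task_summaries
                ]
                for stat in ("mean", "sd")
                for i, ax in enumerate(("x", "y", "z"))
            },
        }
    )
    _write_csv(task_df, out / "task_summary.csv")

    disp_df = pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in disp],
            "task_id": [d.task_id for d in disp],
            "method": [d.method for d in disp],
            "range_x_cm": [d.range_x for d in disp],
            "range_y_cm": [d.range_y for d in disp],
        }
    )
    _write_csv(disp_df, out / "displacement.csv")

    stats_df = pd.DataFrame(
        {
            "direction": [s.direction for s in stats],
            "n_subjects": [s.n_subjects_used for s in stats],
            "F": [s.classical_f for s in stats],
            "p": [s.classical_p for s in stats],
            "bf10": [s.bf10 for s in stats],
            "evidence": [s.evidence_label for s in stats],
        }
    )
    _write_csv(stats_df, out / "stats_results.csv")

    config = getattr(study, "config", None)
    log = {
        "comtrack_version": __version__,
        "seed": config.seed if config is not None else None,
        "config_sha256": (
            hashlib.sha256(config_to_json(config).encode()).hexdigest()
            if config is not None
            else None
        ),
        "parameters": {
            "sg_window": sg_window,
            "sg_order": sg_order,
            "dc_removal": dc_removal,
            "prior_scale": prior_scale,
            "frame_mapping": dataclasses.asdict(mapping),
        },
        "accounting": dataclasses.asdict(summary.accounting),
        "grand_mean_rms_cm": summary.grand_mean_cm,
        "grand_sd_rms_cm": summary.grand_sd_cm,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return PipelineResult(summary, stats, out, rows, disp)


def plot_trial_overlay(rec, out_path: str | Path, **analyze_kwargs) -> Path:
    """Overlay the processed COM and tracker trajectories of one trial (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .agreement import analyze_trial  # local import avoids cycles
    from .kinematics import compute_whole_body_com, estimate_segment_pose, pelvis_proxy_com
    from .preprocess import align_time, remove_dc, smooth_savgol, translate_frame
    from .body import default_anthropometric_model

    rec = rec.load()
    if rec.com_missing or rec.tracker_missing:
        raise ComtrackError("cannot plot a trial with a missing stream")
    model = analyze_kwargs.get("model") or default_anthropometric_model()
    poses = {sid: estimate_segment_pose(cl) for sid, cl in rec.clusters.items()}
    com = compute_whole_body_com(poses, model)
    proxy = pelvis_proxy_com(
        translate_frame(rec.tracker_engine, analyze_kwargs.get("mapping", ENGINE_TO_LAB))
    )
    a, b = align_time(com, proxy, rec.event, sample_rate=rec.sample_rate)
    a = remove_dc(smooth_savgol(a))
    b = remove_dc(smooth_savgol(b))
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    for i, label in enumerate(["X (AP)", "Y (ML)", "Z (vertical)"]):
        axes[i].plot(a.timestamps, 100 * a.positions[:, i], label="COM (optical)")
        axes[i].plot(b.timestamps, 100 * b.positions[:, i], "--", label="pelvis tracker")
        axes[i].set_ylabel(f"{label} [cm]")
    axes[0].legend(loc="upper right")
    axes[0].set_title(f"P{rec.participant_id:02d} task {rec.task_id}")
    axes[-1].set_xlabel("time [s]")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
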