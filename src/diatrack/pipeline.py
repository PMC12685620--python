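"""Session orchestration: simulate, track, model, predict, evaluate.

A session runs the full chain on a synthetic phantom: generate the
respiratory signal and coupled anatomy, render dual-view frames, track the
diaphragm apex with epipolar-constrained template matching, build the
offset-vector and correlation models on the training window, predict over
the evaluation window from the surrogate signal alone, and summarize the
errors per scenario.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, imaging, motion, phantom
from .geometry import (
    backproject_ray,
    project_point,
    triangulate,
    view_pair,
)
from .imaging import ProjectionImage, TrackResult
from .motion import RespiratorySignal
from .phantom import (
    ARC_CCW,
    ARC_CW,
    AnatomyConfig,
    Arc,
    RenderConfig,
    RespiratoryConfig,
    SessionTruth,
)

__all__ = ["SessionConfig", "SessionResult", "run_session", "pseudo_tumor_centroid",
           "render_session_frames", "load_config"]

CSV_FLOAT_FORMAT = "%.9f"


@dataclass
class SessionConfig:
    """Everything needed to reproduce one session end to end."""

    duration_s: float = 70.0
    frame_interval_s: float = 0.2
    training_s: float = 20.0
    evaluation_s: float = 50.0
    arc: Arc | str = "cw"
    scenarios: tuple[str, ...] = ("S_no", "S_con", "S_var")
    seed: int = 0
    respiratory: RespiratoryConfig = field(default_factory=RespiratoryConfig)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    track_from_frames: bool = True  # False = feed true apex (noise-free tracking)
    seed_from_truth: bool = True  # first-frame apex seeds from phantom truth
    out_dir: str | None = None

    def __post_init__(self):
        if abs(self.training_s + self.evaluation_s - self.duration_s) > 1e-9:
            raise ValueError("training_s + evaluation_s must equal duration_s")
        if isinstance(self.arc, str):
            self.arc = {"cw": ARC_CW, "ccw": ARC_CCW}[self.arc.lower()]
        unknown = set(self.scenarios) - set(motion.SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}")
        # derive the phantom seed from the session seed unless set explicitly
        if self.respiratory.seed == 0 and self.seed != 0:
            self.respiratory = dataclasses.replace(self.respiratory, seed=self.seed)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1


@dataclass
class SessionResult:
    config: SessionConfig
    signal: RespiratorySignal
    truth: SessionTruth
    pseudo_tumor: np.ndarray  # (n, 3) triangulated marker centroid
    apex_used: np.ndarray  # (n, 3) apex trajectory fed to the models
    track: TrackResult | None
    extrema: motion.BreathingExtrema
    offset_models: dict[str, motion.OffsetVectorModel]
    correlation_models: dict[str, motion.CorrelationModel]
    predictions: dict[str, np.ndarray]  # (n, 3) over the full session
    summaries: dict[str, evaluation.ErrorSummary]


def pseudo_tumor_centroid(
    markers_true: np.ndarray,
    angles1_deg: np.ndarray,
    imager_offset_deg: float = 90.0,
) -> np.ndarray:
    """Triangulated marker centroid per frame.

    Each marker is projected into both views at that frame's gantry
    position, back-projected and triangulated; the per-frame centroid of
    the reconstructed markers is the pseudo-tumor trajectory.
    """
    markers_true = np.asarray(markers_true, dtype=float)
    n, m, _ = markers_true.shape
    out = np.zeros((n, 3))
    for k in range(n):
        g1, g2 = view_pair(angles1_deg[k], imager_offset_deg)
        pts = np.zeros((m, 3))
        for j in range(m):
            q1 = project_point(g1, markers_true[k, j])
            q2 = project_point(g2, markers_true[k, j])
            pt, _ = triangulate(backproject_ray(g1, q1), backproject_ray(g2, q2))
            pts[j] = pt.to_array()
        out[k] = pts.mean(axis=0)
    return out


def render_session_frames(
    truth: SessionTruth,
    render_cfg: RenderConfig,
    seed: int,
) -> dict[int, list[ProjectionImage]]:
    """Raw-polarity frames for both imagers at every session frame."""
    rng = np.random.default_rng(seed)
    frames: dict[int, list[ProjectionImage]] = {1: [], 2: []}
    for k in range(len(truth)):
        for imager, ang in ((1, truth.angle1_deg[k]), (2, truth.angle2_deg[k])):
            g1, g2 = view_pair(truth.angle1_deg[k])
            geom = g1 if imager == 1 else g2
            img = phantom.render_frame(
                truth.apex[k], truth.markers[k], geom, render_cfg, rng=rng
            )
            img.time_s = float(truth.times_s[k])
            frames[imager].append(img)
    return frames


def _tracked_apex(cfg: SessionConfig, truth: SessionTruth):
    """Render, preprocess and track the session; returns the apex
    trajectory and the full track result."""
    frames = render_session_frames(truth, cfg.render, seed=cfg.seed + 1)
    banks = phantom.template_bank(cfg.anatomy, arc=truth.arc, rc=cfg.render)
    initial = None
    if cfg.seed_from_truth:
        initial = {}
        for imager in (1, 2):
            geom = frames[imager][0].view
            initial[imager] = project_point(geom, truth.apex[0])
    track = imaging.track_session(
        frames, banks, initial_apexes=initial, times_s=truth.times_s
    )
    return track.apex_3d, track


def run_session(cfg: SessionConfig) -> SessionResult:
    """Execute the full pipeline for every scenario in the config."""
    sig = phantom.simulate_respiration(
        cfg.respiratory, duration_s=cfg.duration_s, dt_s=cfg.frame_interval_s
    )
    truth = phantom.simulate_anatomy(sig, cfg.anatomy, arc=cfg.arc)
    pseudo = pseudo_tumor_centroid(truth.markers, truth.angle1_deg)

    track = None
    if cfg.track_from_frames:
        apex_used, track = _tracked_apex(cfg, truth)
    else:
        apex_used = truth.apex.copy()

    train_window = (0.0, cfg.training_s)
    eval_window = (cfg.training_s, cfg.duration_s)
    extrema = motion.detect_extrema(sig, window=train_window)

    offset_models: dict[str, motion.OffsetVectorModel] = {}
    corr_models: dict[str, motion.CorrelationModel] = {}
    predictions: dict[str, np.ndarray] = {}
    summaries: dict[str, evaluation.ErrorSummary] = {}

    for scen in cfg.scenarios:
        m = motion.build_offset_model(scen, apex_used, pseudo, sig, extrema)
        offset_models[scen] = m
        if scen == "S_no":
            tumor_est = pseudo
        else:
            tumor_est = motion.estimate_tumor(
                m, apex_used, apex_used[extrema.i_ex], sig.p
            )
        model = motion.fit_4dm(sig, tumor_est, window=train_window)
        corr_models[scen] = model
        pred = motion.predict_4dm(model, sig.p, sig.p_dot)
        predictions[scen] = pred
        series = evaluation.error_series(pred, pseudo, sig.times_s, window=eval_window)
        eval_mask = (sig.times_s > eval_window[0]) & (sig.times_s <= eval_window[1])
        summaries[scen] = evaluation.summarize(
            series, tumor_truth_si=pseudo[eval_mask, 2]
        )

    result = SessionResult(
        config=cfg,
        signal=sig,
        truth=truth,
        pseudo_tumor=pseudo,
        apex_used=apex_used,
        track=track,
        extrema=extrema,
        offset_models=offset_models,
        correlation_models=corr_models,
        predictions=predictions,
        summaries=summaries,
    )
    if cfg.out_dir is not None:
        write_artifacts(result, Path(cfg.out_dir))
    return result


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def write_artifacts(result: SessionResult, out_dir: Path) -> None:
    """Write all tabular artifacts (CSV) and model files (JSON)."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.truth.to_csv(out_dir / "truth.csv")
    sig = result.signal
    pd.DataFrame(
        {"time_s": sig.times_s, "p_mm": sig.p, "p_dot_mm_s": sig.p_dot}
    ).to_csv(out_dir / "signal.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    pd.DataFrame(
        {
            "time_s": result.truth.times_s,
            "pseudo_x_mm": result.pseudo_tumor[:, 0],
            "pseudo_y_mm": result.pseudo_tumor[:, 1],
            "pseudo_z_mm": result.pseudo_tumor[:, 2],
            "apex_used_x_mm": result.apex_used[:, 0],
            "apex_used_y_mm": result.apex_used[:, 1],
            "apex_used_z_mm": result.apex_used[:, 2],
        }
    ).to_csv(out_dir / "trajectories.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    if result.track is not None:
        result.track.to_dataframe().to_csv(
            out_dir / "detections.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
    t = result.truth.times_s
    eval_mask = (t > result.config.training_s) & (t <= result.config.duration_s)
    for scen, pred in result.predictions.items():
        pd.DataFrame(
            {
                "time_s": t[eval_mask],
                "pred_x_mm": pred[eval_mask, 0],
                "pred_y_mm": pred[eval_mask, 1],
                "pred_z_mm": pred[eval_mask, 2],
            }
        ).to_csv(
            out_dir / f"prediction_{scen}.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        result.correlation_models[scen].save_json(out_dir / f"model_4dm_{scen}.json")
        with open(out_dir / f"model_offset_{scen}.json", "w") as fh:
            json.dump(result.offset_models[scen].to_dict(), fh, indent=2)
    summary = {scen: s.to_dict() for scen, s in result.summaries.items()}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    rows = []
    for scen, s in result.summaries.items():
        for ax in ("LR", "AP", "SI", "3D"):
            rows.append(
                {
                    "scenario": scen,
                    "direction": ax,
                    "mean_mm": s.mean[ax],
                    "sd_mm": s.sd[ax],
                    "e90_mm": s.e90[ax],
                    "e95_mm": s.e95[ax],
                }
            )
    pd.DataFrame(rows).to_csv(
        out_dir / "summary.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )


def load_config(path) -> SessionConfig:
    """Load a SessionConfig from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return config_from_dict(data or {})


def config_from_dict(data: dict) -> SessionConfig:
    data = dict(data)
    if "respiratory" in data:
        resp = dict(data["respiratory"])
        events = tuple(
            phantom.IrregularityEvent(**e) for e in resp.pop("irregularity_events", [])
        )
        data["respiratory"] = RespiratoryConfig(**resp, irregularity_events=events)
    if "anatomy" in data:
        anat = dict(data["anatomy"])
        for key in ("apex_rest", "tumor_rest", "coupling_mm"):
            if key in anat:
                anat[key] = tuple(anat[key])
        if "marker_offsets_mm" in anat:
            anat["marker_offsets_mm"] = tuple(tuple(v) for v in anat["marker_offsets_mm"])
        data["anatomy"] = AnatomyConfig(**anat)
    if "render" in data:
        data["render"] = RenderConfig(**data["render"])
    if "arc" in data and isinstance(data["arc"], dict):
        data["arc"] = Arc(**data["arc"])
    if "scenarios" in data:
        data["scenarios"] = tuple(data["scenarios"])
    return SessionConfig(**data)
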