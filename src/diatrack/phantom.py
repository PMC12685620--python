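"""Synthetic session generator.

Produces everything a tracking session needs when no measured data are
available: a drifting, pulsating respiratory surrogate signal; coupled
diaphragm-apex / tumor / fiducial-marker trajectories with controllable
phase-dependent asynchrony and hysteresis; rendered dual-view projection
frames; and an angle-indexed diaphragm template bank.

All randomness is seeded, so a session is a pure function of its
configuration.  Trajectory arrays are in room order ``(LR, AP, SI)`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import motion
from .exceptions import ApexOutsideImageError, BadConfigError
from .geometry import PixelCoord, ViewGeometry, project_point
from .imaging import (
    TEMPLATE_APEX_OFFSET,
    TEMPLATE_SHAPE,
    DiaphragmTemplate,
    ProjectionImage,
)
from .motion import RespiratorySignal

__all__ = [
    "IrregularityEvent",
    "RespiratoryConfig",
    "AnatomyConfig",
    "RenderConfig",
    "Arc",
    "SessionTruth",
    "ARC_CW",
    "ARC_CCW",
    "simulate_respiration",
    "simulate_anatomy",
    "render_frame",
    "render_templates",
    "template_bank",
]

FRAME_INTERVAL_S = 0.2
SESSION_DURATION_S = 70.0


@dataclass(frozen=True)
class Arc:
    """Gantry arc traversed at constant angular velocity over a session."""

    start_deg: float
    end_deg: float
    clockwise: bool = True

    @property
    def span_deg(self) -> float:
        """Unsigned angular span of the arc (degrees)."""
        if self.clockwise:
            return (self.end_deg - self.start_deg) % 360.0
        return (self.start_deg - self.end_deg) % 360.0

    def angle_at(self, t_s, duration_s: float = SESSION_DURATION_S):
        """Gantry angle(s) at time *t_s*, wrapped to [0, 360)."""
        t = np.asarray(t_s, dtype=float)
        sign = 1.0 if self.clockwise else -1.0
        ang = (self.start_deg + sign * self.span_deg * t / duration_s) % 360.0
        return float(ang) if np.ndim(t_s) == 0 else ang

    def grid_angles(self, step_deg: float = 0.3) -> np.ndarray:
        """Template grid angles from arc start to end inclusive, wrapped."""
        if step_deg <= 0:
            raise BadConfigError("angle step must be positive")
        n = int(round(self.span_deg / step_deg)) + 1
        sign = 1.0 if self.clockwise else -1.0
        return (self.start_deg + sign * step_deg * np.arange(n)) % 360.0


#: the two session arcs: 330->75 clockwise, 30->285 counterclockwise
ARC_CW = Arc(330.0, 75.0, clockwise=True)
ARC_CCW = Arc(30.0, 285.0, clockwise=False)


@dataclass(frozen=True)
class IrregularityEvent:
    """Piecewise modification of the breathing-depth waveform.

    ``pause`` freezes the waveform (time-warp; breathing resumes where it
    stopped); ``amplitude_shift`` scales depth by *scale* inside the window;
    ``deep_breath`` is an amplitude_shift with scale > 1 over roughly one
    cycle.
    """

    kind: str
    start_s: float
    duration_s: float
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("pause", "deep_breath", "amplitude_shift"):
            raise BadConfigError(f"unknown irregularity kind {self.kind!r}")
        if self.duration_s < 0:
            raise BadConfigError("event duration must be nonnegative")


@dataclass(frozen=True)
class RespiratoryConfig:
    period_s: float = 4.0
    amplitude_mm: float = 8.0
    lujan_exponent: int = 2
    drift_rate_mm_per_s: float = 0.0
    pulsation_amplitude_mm: float = 0.0
    pulsation_freq_hz: float = 1.2
    noise_sd_mm: float = 0.0
    irregularity_events: tuple[IrregularityEvent, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.period_s <= 0:
            raise BadConfigError("period_s must be positive")
        if self.amplitude_mm < 0:
            raise BadConfigError("amplitude_mm must be nonnegative")
        if self.lujan_exponent < 1 or self.lujan_exponent % 1:
            raise BadConfigError("lujan_exponent must be a positive integer")


@dataclass(frozen=True)
class AnatomyConfig:
    """Coupled apex/tumor/marker kinematics.

    ``coupling_mm`` is the tumor displacement per unit breathing depth in
    room order (LR, AP, SI); ``mode`` selects between a hysteresis
    generator and one whose tumor is an exact quadratic function of the
    surrogate signal and its velocity (``model_consistent``).
    """

    apex_rest: tuple[float, float, float] = (10.0, 5.0, 30.0)
    apex_si_excursion_mm: float = -15.0
    tumor_rest: tuple[float, float, float] = (-15.0, -10.0, -25.0)
    coupling_mm: tuple[float, float, float] = (1.0, 3.0, -12.0)
    hysteresis_lag_s: float = 0.0
    asynchrony_si_amplitude_mm: float = 0.0
    n_markers: int = 3
    marker_offsets_mm: tuple[tuple[float, float, float], ...] = (
        (6.0, 0.0, 4.0),
        (-5.0, 4.0, -3.0),
        (0.0, -5.0, -4.0),
    )
    mode: str = "hysteresis"
    model_coeffs: tuple | None = None  # optional explicit (3, 5) rows (LR, AP, SI)

    def __post_init__(self):
        if self.n_markers < 1:
            raise BadConfigError("need at least one marker")
        if len(self.marker_offsets_mm) < self.n_markers:
            raise BadConfigError("marker_offsets_mm shorter than n_markers")
        if self.mode not in ("hysteresis", "model_consistent"):
            raise BadConfigError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RenderConfig:
    """Analytic dome renderer parameters (pixel units on the detector)."""

    base_intensity: float = 400.0
    dome_contrast: float = 600.0
    edge_softness_px: float = 5.0
    curvature_px: float = 0.004
    curvature_angle_mod: float = 0.15
    skew_px: float = 2.0e-7
    marker_sigma_px: float = 2.5
    marker_depth: float = 300.0
    noise_sd: float = 0.0


@dataclass
class SessionTruth:
    """Per-frame ground truth for one simulated session."""

    times_s: np.ndarray
    angle1_deg: np.ndarray
    angle2_deg: np.ndarray
    p_mm: np.ndarray
    apex: np.ndarray  # (n, 3) room mm
    tumor: np.ndarray  # (n, 3)
    markers: np.ndarray  # (n, m, 3)
    arc: Arc = field(default_factory=lambda: ARC_CW)

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def n_markers(self) -> int:
        return int(self.markers.shape[1])

    def pseudo_tumor(self) -> np.ndarray:
        """Centroid of the true marker positions per frame, (n, 3)."""
        return self.markers.mean(axis=1)

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "time_s": self.times_s,
            "angle1_deg": self.angle1_deg,
            "angle2_deg": self.angle2_deg,
            "p_mm": self.p_mm,
        }
        for name, arr in (("apex", self.apex), ("tumor", self.tumor)):
            for j, ax in enumerate("xyz"):
                cols[f"{name}_{ax}_mm"] = arr[:, j]
        for i in range(self.n_markers):
            for j, ax in enumerate("xyz"):
                cols[f"marker{i + 1}_{ax}_mm"] = self.markers[:, i, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# respiratory signal
# ---------------------------------------------------------------------------


def _breathing_depth(t: np.ndarray, cfg: RespiratoryConfig) -> np.ndarray:
    """Normalized depth in [0, 1]: 0 = end-expiration (long dwell), 1 =
    end-inspiration.  Irregularity events warp or scale the waveform."""
    tau = t.astype(float).copy()
    for ev in cfg.irregularity_events:
        if ev.kind == "pause":
            # time-warp: clock stops during the pause, resumes afterwards
            t0, t1 = ev.start_s, ev.start_s + ev.duration_s
            tau = np.where(tau <= t0, tau, np.where(tau >= t1, tau - ev.duration_s, t0))
    # sin^(2n) dwells near zero: long end-expiratory rest, brief inspiration
    n = cfg.lujan_exponent
    b = np.sin(np.pi * tau / cfg.period_s) ** (2 * n)
    for ev in cfg.irregularity_events:
        if ev.kind in ("amplitude_shift", "deep_breath"):
            inside = (t >= ev.start_s) & (t < ev.start_s + ev.duration_s)
            b = np.where(inside, b * ev.scale, b)
    return b


def simulate_respiration(
    cfg: RespiratoryConfig,
    duration_s: float = SESSION_DURATION_S,
    dt_s: float = FRAME_INTERVAL_S,
) -> RespiratorySignal:
    """Surrogate signal ``p(t)`` = drift + amplitude * depth + pulsation + noise.

    Troughs are end-expiration, peaks end-inspiration.  The normalized
    depth waveform is attached as ``signal.depth`` for downstream anatomy
    generation.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise BadConfigError("duration and dt must be positive")
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    b = _breathing_depth(t, cfg)
    p = cfg.drift_rate_mm_per_s * t + cfg.amplitude_mm * b
    if cfg.pulsation_amplitude_mm:
        p = p + cfg.pulsation_amplitude_mm * np.sin(
            2.0 * np.pi * cfg.pulsation_freq_hz * t
        )
    if cfg.noise_sd_mm:
        rng = np.random.default_rng(cfg.seed)
        p = p + rng.normal(0.0, cfg.noise_sd_mm, size=n)
    return RespiratorySignal(times_s=t, p=p, depth=b)


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------


def _default_model_coeffs(cfg: AnatomyConfig, resp_amplitude: float) -> np.ndarray:
    """Quadratic-model coefficients reproducing ``coupling * depth`` to
    first order, with small curvature and velocity terms per direction."""
    a = max(resp_amplitude, 1e-9)
    coeffs = np.zeros((3, 5))
    for j in range(3):
        c = cfg.coupling_mm[j]
        coeffs[j] = [0.02 * c / a**2, 0.9 * c / a, cfg.tumor_rest[j], 0.001 * c, 0.02 * c]
    return coeffs


def simulate_anatomy(
    resp: RespiratorySignal,
    cfg: AnatomyConfig,
    arc: Arc = ARC_CW,
    imager_offset_deg: float = 90.0,
    resp_amplitude_mm: float | None = None,
) -> SessionTruth:
    """Apex/tumor/marker trajectories coupled to the respiratory signal.

    * apex: rest position plus ``apex_si_excursion_mm * depth(t)`` in SI;
    * tumor (``hysteresis`` mode): rest + ``coupling * depth``, with the
      LR/AP response lagged by ``hysteresis_lag_s`` (elliptical loop) and an
      SI asynchrony term linear in depth (and hence in the clean signal)
      whose total swing is ``asynchrony_si_amplitude_mm``;
    * tumor (``model_consistent`` mode): an exact quadratic function of
      ``(p, p_dot)`` per direction, using the same velocity estimator as
      the correlation-model fit — a correct fit is then exact;
    * markers: tumor plus fixed offsets.
    """
    if len(resp) == 0:
        raise BadConfigError("empty respiratory signal")
    t = resp.times_s
    depth = resp.depth
    if depth is None:
        ptp = np.ptp(resp.p)
        if ptp <= 0:
            raise BadConfigError("cannot infer breathing depth from a flat signal")
        depth = (resp.p - resp.p.min()) / ptp
    apex = np.tile(np.asarray(cfg.apex_rest, dtype=float), (len(resp), 1))
    apex[:, 2] += cfg.apex_si_excursion_mm * depth

    if cfg.mode == "model_consistent":
        if cfg.model_coeffs is not None:
            coeffs = np.asarray(cfg.model_coeffs, dtype=float).reshape(3, 5)
        else:
            amp = resp_amplitude_mm if resp_amplitude_mm is not None else float(np.ptp(resp.p))
            coeffs = _default_model_coeffs(cfg, amp)
        tumor = motion.predict_4dm(motion.CorrelationModel(coeffs=coeffs), resp.p, resp.p_dot)
    else:
        # hysteresis: the LR/AP response lags the breathing depth (elliptical
        # loop); SI stays concurrent so the SI offset remains linear in the
        # clean signal and the phase-interpolated offset model is exact there
        lagged = np.interp(t - cfg.hysteresis_lag_s, t, depth)
        coupling = np.asarray(cfg.coupling_mm, dtype=float)
        tumor = np.tile(np.asarray(cfg.tumor_rest, dtype=float), (len(resp), 1))
        tumor[:, :2] += np.multiply.outer(lagged, coupling[:2])
        tumor[:, 2] += coupling[2] * depth
        tumor[:, 2] += cfg.asynchrony_si_amplitude_mm * depth

    offsets = np.asarray(cfg.marker_offsets_mm[: cfg.n_markers], dtype=float)
    markers = tumor[:, None, :] + offsets[None, :, :]

    duration = float(t[-1] - t[0]) if len(resp) > 1 else SESSION_DURATION_S
    a1 = arc.angle_at(t, duration_s=duration)
    a2 = (np.atleast_1d(a1) + imager_offset_deg) % 360.0
    return SessionTruth(
        times_s=t,
        angle1_deg=np.atleast_1d(a1),
        angle2_deg=a2,
        p_mm=resp.p.copy(),
        apex=apex,
        tumor=tumor,
        markers=markers,
        arc=arc,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _dome_boundary(du: np.ndarray, apex_v: float, gantry_angle: float, rc: RenderConfig):
    """Boundary curve v_b(u) of the diaphragm dome; minimum exactly at du=0."""
    th = np.deg2rad(gantry_angle)
    k = rc.curvature_px * (1.0 + rc.curvature_angle_mod * np.cos(2.0 * th))
    q = rc.skew_px * np.sin(th)
    return apex_v + k * du**2 + q * du**3


def _render_dome(
    shape: tuple[int, int],
    apex_uv: tuple[float, float],
    gantry_angle: float,
    rc: RenderConfig,
    bright_below: bool,
) -> np.ndarray:
    rows, cols = shape
    u = np.arange(cols, dtype=float)
    v = np.arange(rows, dtype=float)
    v_b = _dome_boundary(u - apex_uv[0], apex_uv[1], gantry_angle, rc)
    z = (v[:, None] - v_b[None, :]) / rc.edge_softness_px
    ramp = 0.5 * (1.0 + np.tanh(z))  # 1 below the boundary
    if bright_below:
        return rc.base_intensity + rc.dome_contrast * ramp
    # raw polarity: exponential profile, so that log compression followed by
    # polarity inversion reproduces the template ramp up to an affine map
    lo = np.log1p(rc.base_intensity)
    hi = np.log1p(rc.base_intensity + rc.dome_contrast)
    return np.expm1(hi - (hi - lo) * ramp)


def render_frame(
    apex_true,
    markers_true,
    geom: ViewGeometry,
    rc: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
    polarity: str = "raw",
) -> ProjectionImage:
    """Render one detector frame of the analytic diaphragm dome phantom.

    ``polarity="raw"`` mimics an acquired fluoroscopy frame (air above the
    dome bright, dense tissue below dark, dark marker spots) and is what the
    preprocessing chain expects; ``polarity="display"`` renders the
    post-inversion appearance used for templates (bright below).  Markers
    are Gaussian absorption spots centered at their exact projections.

    Raises ``ApexOutsideImageError`` if the projected apex leaves the frame.
    """
    apex_px = project_point(geom, np.asarray(apex_true, dtype=float))
    if not (0 <= apex_px.u < geom.image_width and 0 <= apex_px.v < geom.image_height):
        raise ApexOutsideImageError(
            f"apex projects to ({apex_px.u:.1f}, {apex_px.v:.1f}) outside "
            f"{geom.image_width}x{geom.image_height}"
        )
    shape = (geom.image_height, geom.image_width)
    img = _render_dome(
        shape,
        (apex_px.u, apex_px.v),
        geom.gantry_angle,
        rc,
        bright_below=(polarity == "display"),
    )
    marker_px: list[PixelCoord] = []
    markers_true = np.asarray(markers_true, dtype=float).reshape(-1, 3)
    halo = int(np.ceil(6.0 * rc.marker_sigma_px))
    for m in markers_true:
        q = project_point(geom, m)
        marker_px.append(q)
        u0 = max(int(q.u) - halo, 0)
        u1 = min(int(q.u) + halo + 1, geom.image_width)
        v0 = max(int(q.v) - halo, 0)
        v1 = min(int(q.v) + halo + 1, geom.image_height)
        if u0 >= u1 or v0 >= v1:
            continue
        uu = np.arange(u0, u1, dtype=float)
        vv = np.arange(v0, v1, dtype=float)
        r2 = (uu[None, :] - q.u) ** 2 + (vv[:, None] - q.v) ** 2
        img[v0:v1, u0:u1] -= rc.marker_depth * np.exp(
            -r2 / (2.0 * rc.marker_sigma_px**2)
        )
    if rc.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, rc.noise_sd, size=shape)
    np.clip(img, 0.0, None, out=img)
    return ProjectionImage(
        intensity=img,
        time_s=0.0,
        view=geom,
        known_marker_pixels=tuple(marker_px),
    )


def render_templates(
    cfg: AnatomyConfig,
    arc: Arc = ARC_CW,
    angle_step_deg: float = 0.3,
    rc: RenderConfig = RenderConfig(),
    imager_offset_deg: float = 0.0,
    sad: float | None = None,
    sid: float | None = None,
) -> list[DiaphragmTemplate]:
    """Angle-indexed diaphragm templates over the arc's 0.3-degree grid.

    Each template is rendered at the end-expiratory reference depth
    (apex at rest) in post-inversion polarity, 199x299 px with the apex at
    the exact template center.
    """
    angles = arc.grid_angles(angle_step_deg)
    out: list[DiaphragmTemplate] = []
    apex_center = (float(TEMPLATE_APEX_OFFSET.u), float(TEMPLATE_APEX_OFFSET.v))
    for ang in angles:
        eff = (float(ang) + imager_offset_deg) % 360.0
        img = _render_dome(TEMPLATE_SHAPE, apex_center, eff, rc, bright_below=True)
        out.append(
            DiaphragmTemplate(intensity=img, gantry_angle=eff, apex_offset=TEMPLATE_APEX_OFFSET)
        )
    return out


def template_bank(
    cfg: AnatomyConfig,
    arc: Arc = ARC_CW,
    angle_step_deg: float = 0.3,
    rc: RenderConfig = RenderConfig(),
    imager_offset_deg: float = 90.0,
) -> dict[int, list[DiaphragmTemplate]]:
    """Template lists for both imagers (imager 2 offset by +90 degrees)."""
    return {
        1: render_templates(cfg, arc, angle_step_deg, rc, imager_offset_deg=0.0),
        2: render_templates(cfg, arc, angle_step_deg, rc, imager_offset_deg=imager_offset_deg),
    }
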