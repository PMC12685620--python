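"""Respiratory-surrogate motion models.

Three scenarios link the tracked diaphragm apex to the tumor:

* ``S_no`` — the tumor trajectory is taken as given (no surrogate offset);
* ``S_con`` — a constant apex-to-tumor offset frozen at end-expiration;
* ``S_var`` — an offset that varies affinely with the external respiratory
  signal ``p`` between its end-expiratory and end-inspiratory values.

A per-direction quadratic correlation model ``F(p) = a p^2 + b p + c +
d pdot^2 + e pdot`` then maps the signal (position and velocity) to tumor
position for prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import (
    DegenerateBreathingRangeError,
    NoCycleError,
    TooFewSamplesError,
    TooShortError,
)

__all__ = [
    "RespiratorySignal",
    "BreathingExtrema",
    "OffsetVectorModel",
    "CorrelationModel",
    "estimate_velocity",
    "detect_extrema",
    "build_offset_model",
    "offset_at_phase",
    "estimate_tumor",
    "fit_4dm",
    "predict_4dm",
    "SCENARIOS",
]

SCENARIOS = ("S_no", "S_con", "S_var")
DIRECTIONS = ("LR", "AP", "SI")

#: default moving-average pre-smoothing window (samples) for the velocity
DEFAULT_SMOOTH_WINDOW = 3
#: default extremum prominence, as a fraction of the window peak-to-peak
DEFAULT_PROMINENCE_FRAC = 0.2


def estimate_velocity(p, dt: float, smooth_window: int | None = DEFAULT_SMOOTH_WINDOW):
    """Finite-difference velocity of a uniformly sampled signal.

    Central differences in the interior, one-sided at the ends.  An optional
    moving average (odd window, default 3) is applied first; the padding is
    odd-reflective so linear trends pass through unchanged.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise TooShortError("need at least 3 samples to estimate velocity")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if smooth_window is not None and smooth_window > 1:
        w = int(smooth_window)
        if w % 2 == 0:
            raise ValueError("smooth_window must be odd")
        half = w // 2
        padded = np.pad(p, half, mode="reflect", reflect_type="odd")
        kernel = np.full(w, 1.0 / w)
        p = np.convolve(padded, kernel, mode="valid")
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt)
    v[0] = (p[1] - p[0]) / dt
    v[-1] = (p[-1] - p[-2]) / dt
    return v


@dataclass
class RespiratorySignal:
    """External surrogate signal on a uniform time grid.

    ``p`` is the AP centroid of the abdominal IR markers (mm, positive =
    posterior); ``p_dot`` its estimated velocity.  ``depth`` optionally
    carries the phantom's normalized breathing depth (generator metadata).
    """

    times_s: np.ndarray
    p: np.ndarray
    p_dot: np.ndarray = None  # type: ignore[assignment]
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.times_s.size != self.p.size:
            raise ValueError("times and p must have equal length")
        dts = np.diff(self.times_s)
        if self.times_s.size >= 2 and (
            np.any(dts <= 0) or not np.allclose(dts, dts[0], atol=1e-9)
        ):
            raise ValueError("times must be strictly increasing and uniform")
        if self.p_dot is None:
            self.p_dot = estimate_velocity(self.p, self.dt)
        else:
            self.p_dot = np.asarray(self.p_dot, dtype=float)
        if self.p_dot.size != self.p.size:
            raise ValueError("p_dot must match p in length")

    @property
    def dt(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def window_mask(self, t_lo: float, t_hi: float) -> np.ndarray:
        return (self.times_s >= t_lo) & (self.times_s <= t_hi)

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class BreathingExtrema:
    """Final trough (end-expiration) and peak (end-inspiration) of the
    training window, with signal values and sample indices."""

    t_ex: float
    t_in: float
    p_ex: float
    p_in: float
    i_ex: int
    i_in: int

    def __post_init__(self):
        if self.p_ex == self.p_in:
            raise DegenerateBreathingRangeError("p_ex equals p_in")


def detect_extrema(
    sig: RespiratorySignal,
    window: tuple[float, float] = (0.0, 20.0),
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> BreathingExtrema:
    """Last trough and last peak of ``p`` inside *window*.

    Extrema are local minima/maxima with prominence at least
    ``prominence_frac`` of the in-window peak-to-peak range, which rejects
    cardiac-pulsation ripples.  Raises ``NoCycleError`` if no qualifying
    trough+peak pair exists.
    """
    mask = sig.window_mask(*window)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise NoCycleError("window too short")
    p = sig.p[idx]
    ptp = float(np.ptp(p))
    if ptp <= 0:
        raise NoCycleError("signal is constant in the window")
    prom = prominence_frac * ptp
    peaks, _ = find_peaks(p, prominence=prom)
    troughs, _ = find_peaks(-p, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        raise NoCycleError("no trough/peak pair with sufficient prominence")
    i_in = int(idx[peaks[-1]])
    i_ex = int(idx[troughs[-1]])
    return BreathingExtrema(
        t_ex=float(sig.times_s[i_ex]),
        t_in=float(sig.times_s[i_in]),
        p_ex=float(sig.p[i_ex]),
        p_in=float(sig.p[i_in]),
        i_ex=i_ex,
        i_in=i_in,
    )


@dataclass
class OffsetVectorModel:
    """Apex-to-tumor offset model for one of the three scenarios.

    SI offsets start from the per-frame apex; LR/AP offsets start from the
    fixed end-expiratory apex position.  ``s_ex``/``s_in`` are the offsets
    (tumor - apex) at end-expiration / end-inspiration, in room (LR, AP, SI).
    """

    scenario: str
    s_ex: np.ndarray = None  # type: ignore[assignment]
    s_in: np.ndarray | None = None
    p_ex: float | None = None
    p_in: float | None = None
    apex_ex: np.ndarray | None = None
    clamp: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.s_ex is not None:
            self.s_ex = np.asarray(self.s_ex, dtype=float)
        if self.s_in is not None:
            self.s_in = np.asarray(self.s_in, dtype=float)
        if self.apex_ex is not None:
            self.apex_ex = np.asarray(self.apex_ex, dtype=float)
        if self.scenario == "S_var" and self.p_ex == self.p_in:
            raise DegenerateBreathingRangeError("S_var requires p_ex != p_in")

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [float(x) for x in a]

        return {
            "scenario": self.scenario,
            "s_ex": arr(self.s_ex),
            "s_in": arr(self.s_in),
            "p_ex": self.p_ex,
            "p_in": self.p_in,
            "apex_ex": arr(self.apex_ex),
            "clamp": self.clamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OffsetVectorModel":
        return cls(**{k: d.get(k) for k in ("scenario", "s_ex", "s_in", "p_ex", "p_in", "apex_ex", "clamp")})


def build_offset_model(
    scenario: str,
    apex_traj: np.ndarray,
    tumor_traj: np.ndarray,
    sig: RespiratorySignal,
    extrema: BreathingExtrema,
    clamp: bool = False,
) -> OffsetVectorModel:
    """Construct the offset model from time-aligned training trajectories.

    *apex_traj* and *tumor_traj* are (n, 3) arrays in room order (LR, AP, SI) on
    the same grid as *sig*.  ``S_no`` returns an identity model.
    """
    if scenario == "S_no":
        return OffsetVectorModel(scenario="S_no")
    apex_traj = np.asarray(apex_traj, dtype=float)
    tumor_traj = np.asarray(tumor_traj, dtype=float)
    if apex_traj.shape != tumor_traj.shape or apex_traj.shape[0] != len(sig):
        raise ValueError("trajectories must be (n, 3) and aligned with the signal")
    s_ex = tumor_traj[extrema.i_ex] - apex_traj[extrema.i_ex]
    apex_ex = apex_traj[extrema.i_ex]
    if scenario == "S_con":
        return OffsetVectorModel(scenario="S_con", s_ex=s_ex, apex_ex=apex_ex)
    if scenario == "S_var":
        s_in = tumor_traj[extrema.i_in] - apex_traj[extrema.i_in]
        return OffsetVectorModel(
            scenario="S_var",
            s_ex=s_ex,
            s_in=s_in,
            p_ex=extrema.p_ex,
            p_in=extrema.p_in,
            apex_ex=apex_ex,
            clamp=clamp,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def offset_at_phase(m: OffsetVectorModel, p) -> np.ndarray:
    """Phase-dependent offset ``s(p) = s_in + (s_ex - s_in)(p - p_in)/(p_ex - p_in)``.

    Only meaningful for ``S_var``.  Extrapolation beyond the training
    extrema is allowed unless the model was built with ``clamp=True``.
    Accepts a scalar or an array of *p*; returns shape ``(3,)`` or ``(n, 3)``.
    """
    if m.scenario != "S_var":
        raise ValueError("offset_at_phase applies to S_var models only")
    if m.p_ex == m.p_in:
        raise DegenerateBreathingRangeError("p_ex equals p_in")
    p = np.asarray(p, dtype=float)
    frac = (p - m.p_in) / (m.p_ex - m.p_in)
    if m.clamp:
        frac = np.clip(frac, 0.0, 1.0)
    s = m.s_in + np.multiply.outer(frac, m.s_ex - m.s_in)
    # the end-expiratory endpoint must be exact, not exact-to-1-ulp
    if s.ndim == 1:
        return m.s_ex.copy() if frac == 1.0 else s
    s[frac == 1.0] = m.s_ex
    return s


def estimate_tumor(
    m: OffsetVectorModel,
    apex_at_t: np.ndarray,
    apex_at_ex: np.ndarray | None,
    p,
    tumor_passthrough: np.ndarray | None = None,
) -> np.ndarray:
    """Tumor position estimate from the apex and the offset model.

    SI uses the per-frame apex, LR/AP the fixed end-expiratory apex.
    ``S_no`` returns *tumor_passthrough* unchanged.  Shapes follow the
    input: (3,) for a single frame or (n, 3) for a trajectory.
    """
    if m.scenario == "S_no":
        if tumor_passthrough is None:
            raise ValueError("S_no requires the tumor trajectory itself")
        return np.asarray(tumor_passthrough, dtype=float)
    apex_at_t = np.asarray(apex_at_t, dtype=float)
    if apex_at_ex is None:
        apex_at_ex = m.apex_ex
    apex_at_ex = np.asarray(apex_at_ex, dtype=float)
    if m.scenario == "S_con":
        s = np.broadcast_to(m.s_ex, apex_at_t.shape)
    else:
        s = np.asarray(offset_at_phase(m, p), dtype=float)
        s = np.broadcast_to(s, apex_at_t.shape) if s.ndim < apex_at_t.ndim else s
    out = np.empty_like(apex_at_t)
    start = np.broadcast_to(apex_at_ex, apex_at_t.shape)
    out[..., 0] = start[..., 0] + s[..., 0]  # LR from fixed end-exp apex
    out[..., 1] = start[..., 1] + s[..., 1]  # AP from fixed end-exp apex
    out[..., 2] = apex_at_t[..., 2] + s[..., 2]  # SI from per-frame apex
    return out


@dataclass
class CorrelationModel:
    """Per-direction quadratic surrogate-to-tumor map.

    ``coeffs`` is (3, 5): rows in room order (LR, AP, SI), columns (a, b, c, d, e) for
    ``F(p) = a p^2 + b p + c + d pdot^2 + e pdot``.
    """

    coeffs: np.ndarray
    rank_deficient: bool = False
    n_samples: int = 0
    residual_rms: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (3, 5):
            raise ValueError("coeffs must have shape (3, 5)")

    def to_dict(self) -> dict:
        return {
            "directions": list(DIRECTIONS),
            "coefficients": {
                d: dict(zip("abcde", map(float, row)))
                for d, row in zip(DIRECTIONS, self.coeffs)
            },
            "rank_deficient": bool(self.rank_deficient),
            "n_samples": int(self.n_samples),
            "residual_rms_mm": [float(x) for x in self.residual_rms],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationModel":
        coeffs = np.array(
            [[d["coefficients"][dr][k] for k in "abcde"] for dr in DIRECTIONS]
        )
        return cls(
            coeffs=coeffs,
            rank_deficient=d.get("rank_deficient", False),
            n_samples=d.get("n_samples", 0),
        )


def _design(p: np.ndarray, p_dot: np.ndarray) -> np.ndarray:
    return np.column_stack([p**2, p, np.ones_like(p), p_dot**2, p_dot])


def fit_4dm(
    sig: RespiratorySignal,
    tumor_traj: np.ndarray,
    window: tuple[float, float] = (0.0, 20.0),
) -> CorrelationModel:
    """Least-squares fit of the quadratic correlation model per direction.

    The model is linear in its five parameters, so the closed-form
    minimum-norm least-squares solution is used; a rank-deficient design
    is flagged rather than rejected.
    """
    tumor_traj = np.asarray(tumor_traj, dtype=float)
    mask = sig.window_mask(*window)
    if tumor_traj.shape != (len(sig), 3):
        raise ValueError("tumor_traj must be (n, 3) aligned with the signal")
    p = sig.p[mask]
    p_dot = sig.p_dot[mask]
    y = tumor_traj[mask]
    if p.size < 5:
        raise TooFewSamplesError(f"need >= 5 samples in window, got {p.size}")
    X = _design(p, p_dot)
    coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    return CorrelationModel(
        coeffs=coeffs.T,
        rank_deficient=rank < 5,
        n_samples=int(p.size),
        residual_rms=np.sqrt(np.mean(resid**2, axis=0)),
    )


def predict_4dm(model: CorrelationModel, p, p_dot) -> np.ndarray:
    """Evaluate the fitted model: (n, 3) tumor positions in (LR, AP, SI)."""
    scalar = np.ndim(p) == 0 and np.ndim(p_dot) == 0
    p = np.atleast_1d(np.asarray(p, dtype=float))
    p_dot = np.atleast_1d(np.asarray(p_dot, dtype=float))
    X = _design(p, p_dot)
    out = X @ model.coeffs.T
    return out[0] if scalar else out
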