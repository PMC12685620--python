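"""Error statistics for predicted vs. ground-truth tumor trajectories.

Signed per-direction errors keep their sign for mean/SD; the percentile
errors E90/E95 are taken from the absolute values with linear interpolation
between closest ranks.  The reduction ratio ``R = 1 - E/A`` relates the SI
E90 to the pseudo-tumor's SI excursion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    EmptyError,
    MisalignedTimesError,
    NonpositiveAmplitudeError,
    ZeroVarianceError,
)

__all__ = [
    "ErrorSeries",
    "ErrorSummary",
    "error_series",
    "percentile_error",
    "reduction_ratio",
    "asynchrony_residual",
    "surrogate_correlation",
    "summarize",
]

AXES = ("LR", "AP", "SI")  # room order of trajectory columns
EVAL_WINDOW_DEFAULT = (20.0, 70.0)


@dataclass
class ErrorSeries:
    """Per-frame signed component errors (predicted - truth) and 3D norms."""

    times_s: np.ndarray
    signed: np.ndarray  # (n, 3) room order (LR, AP, SI), mm

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signed = np.asarray(self.signed, dtype=float)
        if self.signed.shape != (self.times_s.size, 3):
            raise ValueError("signed errors must be (n, 3)")

    @property
    def norm3d(self) -> np.ndarray:
        return np.linalg.norm(self.signed, axis=1)

    def component(self, axis: str) -> np.ndarray:
        return self.signed[:, AXES.index(axis)]

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class ErrorSummary:
    """Signed mean/SD and absolute-value percentiles per direction + 3D."""

    mean: dict[str, float]
    sd: dict[str, float]
    e90: dict[str, float]
    e95: dict[str, float]
    n: int
    reduction: float | None = None
    amplitude_si: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "e90_mm": self.e90,
            "e95_mm": self.e95,
            "reduction_ratio": self.reduction,
            "amplitude_si_mm": self.amplitude_si,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def error_series(
    pred_traj: np.ndarray,
    truth_traj: np.ndarray,
    times_s: np.ndarray,
    window: tuple[float, float] = EVAL_WINDOW_DEFAULT,
) -> ErrorSeries:
    """Signed errors over the evaluation window ``t_lo < t <= t_hi``.

    The training endpoint itself is excluded, so a default 70 s session at
    0.2 s spacing evaluates exactly 250 frames.
    """
    pred = np.asarray(pred_traj, dtype=float)
    truth = np.asarray(truth_traj, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if pred.shape != truth.shape or pred.shape[0] != t.size:
        raise MisalignedTimesError("trajectories and times must be aligned")
    mask = (t > window[0]) & (t <= window[1])
    return ErrorSeries(times_s=t[mask], signed=pred[mask] - truth[mask])


def percentile_error(abs_errors, q: float) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    a = np.asarray(abs_errors, dtype=float)
    if a.size == 0:
        raise EmptyError("no errors to summarize")
    return float(np.percentile(a, q, method="linear"))


def reduction_ratio(e: float, a: float) -> float:
    """``R = 1 - E/A``; *a* must be positive."""
    if a <= 0:
        raise NonpositiveAmplitudeError("amplitude must be positive")
    return 1.0 - e / a


def asynchrony_residual(apex_ex, apex_in, tumor_ex, tumor_in) -> float:
    """Norm of the tumor displacement left after removing apex displacement."""
    apex_ex = np.asarray(apex_ex, dtype=float)
    apex_in = np.asarray(apex_in, dtype=float)
    tumor_ex = np.asarray(tumor_ex, dtype=float)
    tumor_in = np.asarray(tumor_in, dtype=float)
    return float(np.linalg.norm((tumor_in - tumor_ex) - (apex_in - apex_ex)))


def surrogate_correlation(sig_p, tumor_component) -> float:
    """Pearson correlation between the surrogate and one tumor component."""
    x = np.asarray(sig_p, dtype=float)
    y = np.asarray(tumor_component, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series of at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("a series with zero variance has no correlation")
    return float(np.corrcoef(x, y)[0, 1])


def summarize(
    series: ErrorSeries,
    tumor_truth_si: np.ndarray | None = None,
) -> ErrorSummary:
    """Per-direction + 3D summary; adds R when the session's pseudo-tumor
    SI trace is supplied (A = its peak-to-peak displacement)."""
    if len(series) == 0:
        raise EmptyError("empty error series")
    mean, sd, e90, e95 = {}, {}, {}, {}
    for ax in AXES:
        comp = series.component(ax)
        mean[ax] = float(np.mean(comp))
        sd[ax] = float(np.std(comp, ddof=1)) if len(series) > 1 else 0.0
        e90[ax] = percentile_error(np.abs(comp), 90)
        e95[ax] = percentile_error(np.abs(comp), 95)
    norms = series.norm3d
    mean["3D"] = float(np.mean(norms))
    sd["3D"] = float(np.std(norms, ddof=1)) if len(series) > 1 else 0.0
    e90["3D"] = percentile_error(norms, 90)
    e95["3D"] = percentile_error(norms, 95)
    reduction = amplitude = None
    if tumor_truth_si is not None:
        amplitude = float(np.ptp(np.asarray(tumor_truth_si, dtype=float)))
        if amplitude > 0:
            reduction = reduction_ratio(e90["SI"], amplitude)
    return ErrorSummary(
        mean=mean, sd=sd, e90=e90, e95=e95, n=len(series),
        reduction=reduction, amplitude_si=amplitude,
    )
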