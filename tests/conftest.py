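import numpy as np
import pytest

from diatrack import phantom as ph
from diatrack import pipeline as pl


def asynchronous_session_config(seed: int = 7, track: bool = True) -> pl.SessionConfig:
    """Default asynchronous phantom: 6.1 mm SI asynchrony, 0.3 s hysteresis
    lag, mild drift/pulsation/noise on the surrogate signal."""
    return pl.SessionConfig(
        seed=seed,
        respiratory=ph.RespiratoryConfig(
            seed=seed,
            period_s=4.0,
            amplitude_mm=8.0,
            drift_rate_mm_per_s=0.02,
            pulsation_amplitude_mm=0.3,
            pulsation_freq_hz=1.2,
            noise_sd_mm=0.1,
        ),
        anatomy=ph.AnatomyConfig(
            hysteresis_lag_s=0.3,
            asynchrony_si_amplitude_mm=6.1,
        ),
        track_from_frames=track,
    )


@pytest.fixture(scope="session")
def tracked_session():
    """One full 351-frame dual-view session with rendering and matching.

    Shared across the imaging-tracking tests and acceptance criteria 7/8 —
    this is the expensive fixture (a few minutes on one CPU).
    """
    import time

    t0 = time.monotonic()
    result = pl.run_session(asynchronous_session_config(seed=7, track=True))
    result.elapsed_s = time.monotonic() - t0
    return result


@pytest.fixture(scope="session")
def truthfed_session():
    """Same phantom, but the true apex trajectory is fed to the models
    (noise-free tracking inputs)."""
    return pl.run_session(asynchronous_session_config(seed=7, track=False))


@pytest.fixture(scope="session")
def true_apex_projections(tracked_session):
    """Per-imager exact projections of the true apex, (n, 2) pixel arrays."""
    from diatrack import geometry as g

    truth = tracked_session.truth
    out = {}
    for imager in (1, 2):
        pts = np.empty((len(truth), 2))
        for k in range(len(truth)):
            g1, g2 = g.view_pair(truth.angle1_deg[k])
            geom = g1 if imager == 1 else g2
            q = g.project_point(geom, truth.apex[k])
            pts[k] = (q.u, q.v)
        out[imager] = pts
    return out
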