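import numpy as np
import pytest

from fixstab import (
    CalibrationGeometry,
    ExclusionPolicy,
    GazeTrace,
    TraceSimConfig,
    apply_exclusions,
    detect_blinks,
    pixels_to_degrees,
    simulate_trace,
)


def make_trace(x, y, valid=None, rate_hz=50.0, units="degrees", **kw):
    """Small helper: build a trace from coordinate lists with uniform timing."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrace(
        t=np.arange(n) / rate_hz, x=x, y=np.asarray(y, dtype=float),
        valid=np.asarray(valid, dtype=bool), rate_hz=rate_hz, units=units, **kw
    )


@pytest.fixture(scope="session")
def geometry():
    return CalibrationGeometry()


@pytest.fixture(scope="session")
def sim_trace(geometry):
    """One default simulated trace plus its ground truth (pixel units)."""
    cfg = TraceSimConfig(seed=7, geometry=geometry)
    trace, truth = simulate_trace(cfg)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def sim_clean(sim_trace, geometry):
    """The same trace pushed through calibration and exclusion."""
    cfg, trace, truth = sim_trace
    deg = pixels_to_degrees(trace, geometry)
    policy = ExclusionPolicy(setup_window=(truth.setup_window,))
    blinks = detect_blinks(deg, policy)
    return apply_exclusions(deg, blinks, policy)
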