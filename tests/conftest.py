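import numpy as np
import pytest

from nirsbci import (
    HemoParams,
    build_checkerboard_layout,
    extract_features,
    generate_run,
    make_run_spec,
)


@pytest.fixture(scope="session")
def layout():
    return build_checkerboard_layout()


@pytest.fixture(scope="session")
def quiet_params():
    """Deterministic signal-only generator parameters (no nuisance terms)."""
    return HemoParams(
        noise_sd_um=0.0,
        mayer_amp_um=0.0,
        resp_amp_um=0.0,
        cardiac_amp_um=0.0,
        drift_slope_um_per_s=0.0,
    )


@pytest.fixture(scope="session")
def null_params():
    """No activation, white noise only: for calibration checks."""
    return HemoParams(
        hbo_amp_um=0.0,
        mayer_amp_um=0.0,
        resp_amp_um=0.0,
        cardiac_amp_um=0.0,
        drift_slope_um_per_s=0.0,
    )


@pytest.fixture(scope="session")
def me_run(layout):
    """One default ME run at seed 1."""
    spec = make_run_spec(task_type="ME", run_index=1, seed=1)
    return generate_run(spec, layout, HemoParams(), seed=1)


@pytest.fixture(scope="session")
def me_features(me_run):
    return extract_features(me_run)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
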