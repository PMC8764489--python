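import numpy as np
import pandas as pd
import pytest

import fmriverse as fv


@pytest.fixture(scope="session")
def frame_times():
    return np.arange(120) * 2.0


@pytest.fixture(scope="session")
def event_table():
    return fv.generate_event_table("event_related", 10, 2.0, 120, seed=5)


@pytest.fixture(scope="session")
def simple_design(frame_times, event_table):
    """Small assembled design: S-style signal, DCT drift, six motion columns."""
    rng = np.random.default_rng(9)
    sig = fv.build_signal_regressors(event_table, fv.HrfSpec.preset("S"), frame_times)
    drift = fv.drift_regressors(fv.DriftSpec("dct_basis", cutoff=128.0), frame_times, 2.0)
    motion = fv.RegressorBlock(pd.DataFrame(rng.standard_normal((len(frame_times), 6)) * 0.02), "fmriprep")
    return fv.assemble_design(
        fv.RegressorBlock(sig, "S"), fv.RegressorBlock(drift, "S"), motion, frame_times
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small event-related bundle used by the workflow tests."""
    cfg = fv.SyntheticConfig(grid_shape=(8, 8, 8), n_volumes=100, n_subjects=4, seed=3)
    events = fv.generate_event_table("event_related", 8, cfg.tr, cfg.n_volumes, seed=3)
    return fv.generate_group_bold(cfg, events)
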