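"""Shared fixtures: tiny parameter sets for fast unit tests."""
import numpy as np
import pytest

from engramsim.params import ModelParams, desk


def tiny_params(**kw) -> ModelParams:
    """A minimal network (64 exc / 16 inh on an 8x8 grid) with a very
    short protocol, for unit and integration tests."""
    mp = desk()
    n = mp.network
    n.N_stim, n.N_exc, n.N_inh, n.grid_side = 64, 64, 16, 8
    n.R_hpc = 1.5
    p = mp.protocol
    p.T_burn, p.T_training, p.T_consolidation = 2.0, 6.0, 0.0
    p.T_probing = p.T_recall = 4.0
    p.probe_off_mean = p.probe_on_mean = 1.0
    p.recall_off_mean = p.recall_on_mean = 1.0
    p.sample_every = 10.0
    mp.analysis.dt_eng = 4.0
    for k, v in kw.items():
        blk, name = k.split(".")
        setattr(getattr(mp, blk), name, v)
    return mp.validate()


@pytest.fixture
def tiny() -> ModelParams:
    return tiny_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
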