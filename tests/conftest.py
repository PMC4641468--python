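import numpy as np
import pytest

from kna_ephys.datatypes import (
    NeuronModelParams,
    ProtocolSpec,
    standard_protocols,
    template_params,
)


def quiet(params: NeuronModelParams) -> NeuronModelParams:
    """Template with recording noise switched off (deterministic traces)."""
    params.noise_sd_mv = 0.0
    params.noise_sd_pa = 0.0
    return params


@pytest.fixture
def wt_params():
    return quiet(template_params("WT"))


@pytest.fixture
def dko_params():
    return quiet(template_params("dKO"))


@pytest.fixture
def protocols():
    return standard_protocols()


@pytest.fixture
def leak_step(protocols):
    return protocols["leak_step"]


@pytest.fixture
def single_ap_step():
    """20 ms, 100 pA injection from -60 mV: the single-AP stimulus."""
    return ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                        levels=(100.0,), duration_ms=20.0, pre_ms=20.0,
                        post_ms=100.0)


def make_sweep(time_ms, recorded, command, **kw):
    from kna_ephys.datatypes import Sweep
    return Sweep(np.asarray(time_ms, float), np.asarray(recorded, float),
                 np.asarray(command, float), **kw)
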