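import numpy as np
import pytest

from n2g.model import ModelConfig
from n2g.synthetic_data import ParticipantSpec, SyntheticSpec, generate_participant

# Small config: same topology as the default, scaled for CPU test speed.
SMALL_MODEL = dict(n_filters_per_channel=8, lstm_hidden=16, se_reduction=4)

# Tiny config: short windows for unit tests exercising the forward/backward
# machinery rather than the 5-s geometry.
TINY_MODEL = dict(n_filters_per_channel=4, lstm_hidden=4, se_reduction=2,
                  conv_kernel_len=7, pool_len=5, pool_stride=3,
                  window_samples=60, head_kernel_len=3,
                  head_channels_per_group=2, lstm_layers=2)


def tiny_config(variant_flags=(True, True, True), **overrides) -> ModelConfig:
    div, se, bi = variant_flags
    return ModelConfig(use_div=div, use_se=se, use_bi=bi,
                       **{**TINY_MODEL, **overrides})


@pytest.fixture(scope="session")
def short_participant(tmp_path_factory):
    """A 20-s synthetic participant (3 visits) for integration tests."""
    out = tmp_path_factory.mktemp("participant")
    spec = SyntheticSpec(seed=7, duration_s=20.0, baseline_s=5.0,
                         coupling_band="high_beta", coupling_strength=1.0)
    manifest = generate_participant(
        ParticipantSpec(template=spec, participant_id="short-07"), out)
    return manifest, out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
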