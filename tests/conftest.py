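import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_population():
    from campariq.synthetic import generate_population

    return generate_population(
        20, frame_shape=(120, 120), fraction_tuned=0.25, seed=42
    )


@pytest.fixture
def noiseless_optics():
    from campariq.synthetic import ChannelOptics, OpticsModel

    return OpticsModel(
        wavelengths={
            1000: ChannelOptics(eff_green=1.0, eff_red=1.0, bleed=0.131),
            1040: ChannelOptics(eff_green=0.2, eff_red=1.81, bleed=0.146),
        },
        dark_green=100.0,
        dark_red=80.0,
        noise_scale=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
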