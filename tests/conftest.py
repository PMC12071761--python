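import numpy as np
import pytest

from nirdisc.evaluation import stratified_kfold
from nirdisc.simulate import BandSpec, SyntheticConfig, default_config, generate


@pytest.fixture(scope="session")
def default_data():
    """The full 300 x 1577 default synthetic dataset (generated once)."""
    return generate(default_config())


@pytest.fixture(scope="session")
def default_plan(default_data):
    return stratified_kfold(default_data.labels, 5, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size generator config for fast pipeline tests."""
    return SyntheticConfig(
        n_classes=5,
        samples_per_class=12,
        grid_start=4000.0,
        grid_spacing=3.856,
        grid_points=120,
        bands=(
            BandSpec(center=4200.0, width=80.0, base_amplitude=1.0, class_decay=0.10),
            BandSpec(center=4350.0, width=60.0, base_amplitude=0.55, class_decay=0.06),
        ),
        gain_sd=0.15,
        offset_sd=0.05,
        drift_sd=0.03,
        noise_sd=0.003,
        seed=99,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)
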