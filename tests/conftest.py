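import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from serafir.preprocess import preprocess_dataset
from serafir.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PLANTED_CENTERS = (1711.0, 1661.0, 1574.0, 1510.0, 1398.0, 1273.0, 1225.0, 1107.0, 906.5)
N_SEEDS = 20


@pytest.fixture
def tiny_dataset():
    """Handcrafted 2-spectrum, 3-point dataset."""
    from serafir.io import SpectralDataset

    return SpectralDataset(
        wavenumbers=[1800.0, 1700.0, 1600.0],
        absorbance=[[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]],
        sample_id=["s1", "s2"],
        replicate_id=["rep1", "rep1"],
        class_label=["control", "case"],
    )


def small_cohort_config(seed, **overrides):
    """A fast cohort (16 subjects, duplicates, quarter-width grid)."""
    defaults = dict(
        n_control=8,
        n_case=8,
        n_replicates=2,
        wn_start=1450.0,
        wn_end=1050.0,
        base_bands=((1400.0, 12.0, 0.3), (1240.0, 18.0, 0.25), (1080.0, 25.0, 0.4)),
        effect_bands=((1398.0, 8.0, 0.05), (1273.0, 8.0, 0.05), (1107.0, 10.0, -0.05)),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def signal_cohorts():
    """Preprocessed sample-basis datasets of the default (planted-effect)
    cohort for 20 seeds; shared across the acceptance tests."""
    return [preprocess_dataset(generate_cohort(CohortConfig(seed=s)).dataset) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def null_cohorts():
    """Same cohort family with zero-amplitude effect bands."""
    out = []
    for s in range(N_SEEDS):
        cfg = CohortConfig(
            seed=s,
            effect_bands=tuple((c, w, 0.0) for c, w, _ in CohortConfig().effect_bands),
        )
        out.append(preprocess_dataset(generate_cohort(cfg).dataset))
    return out
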