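import pytest

from lakesip import DesignSpec, analyze_dataset, default_truth, generate_dataset


@pytest.fixture(scope="session")
def design():
    return DesignSpec(seed=0)


@pytest.fixture(scope="session")
def dataset():
    """Full synthetic experiment at default noise."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def result(dataset):
    """Full pipeline output for the default-noise dataset."""
    return analyze_dataset(dataset, seed=1)


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free dataset plus its pipeline output (exact-recovery oracle)."""
    design = DesignSpec(seed=0)
    truth = default_truth(design).without_noise()
    ds = generate_dataset(design, truth, seed=0)
    return ds, analyze_dataset(ds, seed=0)
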