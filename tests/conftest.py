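import pytest

from interoppi import synthetic


@pytest.fixture(scope="session")
def default_world():
    """One default-condition synthetic world shared by read-only tests."""
    return synthetic.generate_world(seed=42)


@pytest.fixture(scope="session")
def small_config():
    """A small world configuration for many-world sweeps."""
    return synthetic.WorldConfig(
        edges_per_species=(60, 20, 8, 4, 3, 2, 2),
        n_families=80,
        n_time_series=0,
        n_presence=0,
    )
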