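import pytest

from introtrace.synthetic_data import (
    TrioSimConfig,
    panel_plate_config,
    simulate_plate,
    simulate_trio,
)


@pytest.fixture(scope="session")
def default_trio():
    """One default-condition trio simulation shared across tests."""
    cfg = TrioSimConfig(seed=11)
    return cfg, simulate_trio(cfg)


@pytest.fixture(scope="session")
def clean_trio():
    """Trio with no third-origin or heterozygous sites (exact recovery case)."""
    cfg = TrioSimConfig(seed=13, unknown_fraction=0.0, het_fraction=0.0)
    return cfg, simulate_trio(cfg)


@pytest.fixture(scope="session")
def panel_plate():
    """194-variety screening plate: 18 mutant homozygotes + 2 NTC wells."""
    cfg = panel_plate_config(seed=5)
    plate, truth = simulate_plate(cfg)
    return cfg, plate, truth
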