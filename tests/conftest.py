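import pytest

from magnetoferritin import (
    BODY_TEMPERATURE,
    ThermalField,
    canonical_edh,
    canonical_membrane,
    canonical_particle,
)


@pytest.fixture(scope="session")
def particle():
    """Fully loaded core: N = 4500 at 5 Bohr magnetons, 8 nm, magnetite."""
    return canonical_particle()


@pytest.fixture(scope="session")
def field_1t():
    """1 T at physiological temperature."""
    return ThermalField(b_field=1.0, temperature=BODY_TEMPERATURE)


@pytest.fixture(scope="session")
def membrane():
    return canonical_membrane()


@pytest.fixture(scope="session")
def edh():
    return canonical_edh()
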