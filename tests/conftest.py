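import hypothesis
import pytest

from ammokin import (
    KineticParameters,
    PatientAnthropometry,
    Sex,
    TreatmentGoals,
    reference_setup_menu,
)

hypothesis.settings.register_profile(
    "ammokin", derandomize=True, max_examples=100, deadline=None)
hypothesis.settings.load_profile("ammokin")


@pytest.fixture(scope="session")
def menu():
    """The three reference dialysis setups (4008/FXPaed, CD025, CD015)."""
    return reference_setup_menu()


@pytest.fixture(scope="session")
def v_3kg():
    """Distribution volume of the 3 kg reference infant (72 % TBW), mL."""
    return 0.72 * 3.0 * 1000.0


@pytest.fixture
def reference_params(v_3kg):
    """K from the 4008/FXPaed setup at Qb 30 (ER 45 %), C0 3000 µmol/L."""
    return KineticParameters(clearance=13.5, volume=v_3kg,
                             start_concentration=3000.0)


@pytest.fixture
def reference_infant():
    return PatientAnthropometry(weight=3.0, height=50.0, age=3.0, sex=Sex.male)


@pytest.fixture
def local_goals():
    """<400 µmol/L within 4 h, then <200 µmol/L within 4 h; rebound cap 200."""
    return TreatmentGoals(goals=((400.0, 240.0), (200.0, 240.0)),
                          rebound_limit=200.0)
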