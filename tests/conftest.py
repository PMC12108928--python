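import pytest

from valvefatigue import MaterialFatigueProperties, demo_material


@pytest.fixture(scope="session")
def demo_mat() -> MaterialFatigueProperties:
    """Packaged demo material card (placeholder constants)."""
    return demo_material()


@pytest.fixture(scope="session")
def simple_mat() -> MaterialFatigueProperties:
    """Round-number material for closed-form checks."""
    return MaterialFatigueProperties(
        su=10.0,
        sigma_f=10.0,
        beta=-0.1,
        e_modulus=1000.0,
        hardening_exp=0.2,
        strength_coeff=50.0,
        paris_c=1e-8,
        paris_m=3.0,
    )
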