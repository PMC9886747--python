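import pytest

from cthaem.phantom import PhantomSpec, generate_case


def _clean_case(residual_fraction: float):
    """Full-size phantom with no noise and no deformation (analytic ground truth)."""
    spec = PhantomSpec(
        residual_fraction=residual_fraction,
        noise_sigma_hu=0.0,
        deformation_amplitude_mm=0.0,
        seed=11,
    )
    return generate_case(spec, case_id=f"clean_f{residual_fraction:g}")


@pytest.fixture(scope="session")
def clean_case_f0():
    return _clean_case(0.0)


@pytest.fixture(scope="session")
def clean_case_f05():
    return _clean_case(0.5)


@pytest.fixture(scope="session")
def clean_case_f1():
    return _clean_case(1.0)
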