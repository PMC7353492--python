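import numpy as np
import pytest
from hypothesis import settings

import frostkin as fk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def peas_params() -> fk.ArrheniusParameters:
    """Case-study kinetics: k_ref = 0.00177 d⁻¹ at −20 °C, E_a = 104.24 kJ/mol."""
    return fk.ArrheniusParameters(0.00177, 104240.0, 253.15)


@pytest.fixture(scope="session")
def noisefree_dataset(peas_params) -> fk.IsothermalDataset:
    spec = fk.SyntheticSpec(noise_sd=0.0, seed=0)
    return fk.generate_isothermal(spec)


@pytest.fixture(scope="session")
def bundle() -> fk.CaseStudyBundle:
    """Synthetic peas dataset + one-step fit + 130-day scenario."""
    return fk.generate_case_study_bundle(seed=1)


@pytest.fixture(scope="session")
def bundle_region(bundle) -> fk.JointConfidenceRegion:
    return fk.JointConfidenceRegion.from_fit(bundle.fit, bundle.dataset, alpha=0.05)


@pytest.fixture(scope="session")
def bundle_param_dist(bundle) -> fk.ParameterDistribution:
    """Normal parameter laws built from the bundle's own fit (σ = CI95/1.96)."""
    s = bundle.fit.summary()
    return fk.ParameterDistribution.from_fit_summary(
        k_ref=s["k_ref_per_day"],
        k_ref_ci95=s["ci95_k_ref_per_day"],
        E_a=s["E_a_kJ_per_mol"] * 1000.0,
        E_a_ci95=s["ci95_E_a_kJ_per_mol"] * 1000.0,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
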