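"""Synthetic isothermal degradation data with known ground truth.

Real frozen-storage kinetic datasets are rarely published as numbers,
so every fitting, confidence-region and Monte Carlo stage here is
exercised on generated data: first-order decay at several sub-zero
temperatures with additive Gaussian measurement noise on the retention
scale.  The default generator emulates a frozen-green-peas vitamin C
study — five storage temperatures between −5 and −20 °C, eight sampling
times reaching roughly two half-lives at each temperature, and a
measurement noise of 0.02 retention units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coldchain import ColdChainScenario, case_study_scenario
from .errors import InvalidInputError
from .fitting import FitResult, IsothermalDataset, fit_one_step
from .kinetics import ArrheniusParameters, rate_constant
from .units import celsius_to_kelvin

__all__ = [
    "SyntheticSpec",
    "generate_isothermal",
    "generate_case_study_bundle",
    "CaseStudyBundle",
    "peas_truth",
]


def peas_truth() -> ArrheniusParameters:
    """Ground-truth kinetics used by the default generator:
    k_ref = 0.00177 d⁻¹ at −20 °C, E_a = 104.24 kJ/mol."""
    return ArrheniusParameters.from_celsius(k_ref=0.00177, E_a=104240.0, t_ref_celsius=-20.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic isothermal study.

    ``time_points_per_temperature`` sampling times are spaced evenly up
    to ``half_lives`` half-lives at each temperature (t = 0 is excluded:
    retention is normalized there by construction).  Noise is additive
    Gaussian on retention by default; ``multiplicative=True`` switches
    to relative noise on concentration.
    """

    true_parameters: ArrheniusParameters = field(default_factory=peas_truth)
    temperatures_C: tuple[float, ...] = (-5.0, -8.0, -12.0, -16.0, -20.0)
    time_points_per_temperature: int = 8
    half_lives: float = 2.0
    noise_sd: float = 0.02
    multiplicative: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be ≥ 0")
        if len(self.temperatures_C) < 2:
            raise InvalidInputError("need at least 2 temperatures")
        if self.time_points_per_temperature < 1:
            raise InvalidInputError("need at least 1 time point per temperature")


def generate_isothermal(spec: SyntheticSpec) -> IsothermalDataset:
    """Draw one dataset: retention = exp(−k(T)·t) + ε, truncated to > 0.

    Noise draws that push retention to or below zero are redrawn, so the
    data stay valid inputs for both fitting routes.  Deterministic under
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    temps_K, times, clean = [], [], []
    for T_C in spec.temperatures_C:
        T_K = celsius_to_kelvin(T_C)
        k = rate_constant(spec.true_parameters, T_K)
        t_max = spec.half_lives * np.log(2.0) / k
        t_grid = np.linspace(0.0, t_max, spec.time_points_per_temperature + 1)[1:]
        temps_K.extend([T_K] * len(t_grid))
        times.extend(t_grid)
        clean.extend(np.exp(-k * t_grid))
    clean = np.asarray(clean)

    if spec.noise_sd == 0:
        noisy = clean.copy()
    else:
        noisy = np.empty_like(clean)
        for i, y in enumerate(clean):
            for _ in range(1000):
                if spec.multiplicative:
                    cand = y * (1.0 + rng.normal(0.0, spec.noise_sd))
                else:
                    cand = y + rng.normal(0.0, spec.noise_sd)
                if cand > 0:
                    noisy[i] = cand
                    break
            else:  # pragma: no cover - needs noise_sd >> retention
                raise InvalidInputError("noise_sd too large: cannot keep retention positive")
    return IsothermalDataset(
        temperature_K=np.asarray(temps_K), time_days=np.asarray(times), retention=noisy
    )


@dataclass(frozen=True)
class CaseStudyBundle:
    """Reproducible end-to-end fixture: data, fit and 130-day scenario."""

    dataset: IsothermalDataset
    fit: FitResult
    scenario: ColdChainScenario
    truth: ArrheniusParameters


def generate_case_study_bundle(seed: int = 0) -> CaseStudyBundle:
    """Synthetic peas dataset, its one-step fit, and the packaged
    130-day warehouse/retail/domestic scenario."""
    spec = SyntheticSpec(seed=seed)
    dataset = generate_isothermal(spec)
    fit = fit_one_step(dataset)
    return CaseStudyBundle(
        dataset=dataset, fit=fit, scenario=case_study_scenario(), truth=spec.true_parameters
    )
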