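"""Single and nested (double) Monte Carlo shelf-life engines.

The single scheme propagates kinetic-parameter uncertainty — (k_ref,
E_a) drawn independently from normal laws built from the regression
estimates — into the shelf-life distribution at a constant temperature.
The double scheme nests a second sampling loop: each iteration also
draws one temperature per cold-chain stage, accumulates the quality
function along that realized history, and reports the remaining shelf
life at an assessment temperature.  Parameter draws can be filtered
through the joint likelihood confidence region, which removes pairs the
data contradict and narrows the output distribution.

Reproducibility: each run derives two independent substreams (parameter
draws, temperature draws) from the configured seed, so paired what-if
comparisons reuse identical temperature histories across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coldchain import ColdChainScenario, TemperatureDistribution, mean_profile
from .confidence import JointConfidenceRegion, filter_pairs
from .errors import InvalidInputError, RegionMismatchError
from .units import GAS_CONSTANT, T_REF_FROZEN_K, celsius_to_kelvin, ci_halfwidth_to_sigma

__all__ = [
    "ParameterDistribution",
    "MonteCarloConfig",
    "ShelfLifeDistribution",
    "SensitivityResult",
    "sample_parameters",
    "mc_shelf_life",
    "double_mc_remaining_shelf_life",
    "sensitivity_ci_width",
    "sensitivity_stage_distribution",
    "case_study_parameter_distribution",
]


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent normal laws for k_ref (per day) and E_a (J/mol).

    Draws of k_ref are truncated to be positive (rejected and redrawn).
    A standard deviation of zero collapses that component to a point
    mass, which is the degenerate limit used for uncertainty-source
    decompositions.
    """

    mean_k_ref: float
    sd_k_ref: float
    mean_E_a: float
    sd_E_a: float

    def __post_init__(self):
        if not (self.mean_k_ref > 0):
            raise InvalidInputError("mean_k_ref must be > 0")
        if self.sd_k_ref < 0 or self.sd_E_a < 0:
            raise InvalidInputError("standard deviations must be nonnegative")

    def scaled(self, factor: float) -> "ParameterDistribution":
        """Same means, both standard deviations multiplied by ``factor``."""
        if not (factor > 0):
            raise InvalidInputError("scale factor must be > 0")
        return ParameterDistribution(
            self.mean_k_ref, self.sd_k_ref * factor, self.mean_E_a, self.sd_E_a * factor
        )

    def degenerate(self) -> "ParameterDistribution":
        return ParameterDistribution(self.mean_k_ref, 0.0, self.mean_E_a, 0.0)

    @classmethod
    def from_fit_summary(
        cls, k_ref: float, k_ref_ci95: float, E_a: float, E_a_ci95: float
    ) -> "ParameterDistribution":
        """Build from estimates and 95% CI half-widths (σ = half-width/1.96)."""
        return cls(
            mean_k_ref=k_ref,
            sd_k_ref=ci_halfwidth_to_sigma(k_ref_ci95),
            mean_E_a=E_a,
            sd_E_a=ci_halfwidth_to_sigma(E_a_ci95),
        )


def case_study_parameter_distribution() -> ParameterDistribution:
    """Frozen-peas vitamin C case study: one-step estimates
    k_ref = 0.00177 ± 0.000494 d⁻¹ and E_a = 104.24 ± 11.34 kJ/mol
    (95% CI half-widths), converted to normal standard deviations."""
    return ParameterDistribution.from_fit_summary(
        k_ref=0.00177, k_ref_ci95=0.000494, E_a=104240.0, E_a_ci95=11340.0
    )


@dataclass(frozen=True)
class MonteCarloConfig:
    """Iteration count, seed and summary level for a Monte Carlo run."""

    n_iterations: int = 10_000
    seed: Optional[int] = None
    summary_alpha: float = 0.05
    discretize_bins: Optional[int] = None

    def __post_init__(self):
        if self.n_iterations < 1:
            raise InvalidInputError("n_iterations must be ≥ 1")
        if not (0.0 < self.summary_alpha < 1.0):
            raise InvalidInputError("summary_alpha must lie in (0, 1)")

    def streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        """(parameter stream, temperature stream) derived from the seed."""
        ss = np.random.SeedSequence(self.seed)
        child_params, child_temps = ss.spawn(2)
        return np.random.default_rng(child_params), np.random.default_rng(child_temps)


@dataclass(frozen=True)
class ShelfLifeDistribution:
    """Monte Carlo sample of (remaining) shelf-life values, in days."""

    samples: np.ndarray
    summary_alpha: float = 0.05
    acceptance_rate: Optional[float] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.samples.size > 1 else 0.0

    @property
    def variance(self) -> float:
        return self.sd**2

    @property
    def interval(self) -> tuple[float, float]:
        """Empirical central interval (2.5–97.5 percentiles by default)."""
        lo = 100.0 * self.summary_alpha / 2.0
        return (
            float(np.percentile(self.samples, lo)),
            float(np.percentile(self.samples, 100.0 - lo)),
        )

    @property
    def fraction_expired(self) -> float:
        """Share of samples at or below zero (already past the limit)."""
        return float(np.mean(self.samples <= 0.0))

    @property
    def mc_standard_error(self) -> float:
        return self.sd / np.sqrt(self.samples.size)

    def summary(self) -> dict:
        lo, hi = self.interval
        return {
            "n": int(self.samples.size),
            "mean_days": self.mean,
            "sd_days": self.sd,
            "interval_low_days": lo,
            "interval_high_days": hi,
            "summary_alpha": self.summary_alpha,
            "fraction_expired": self.fraction_expired,
            "acceptance_rate": self.acceptance_rate,
        }


def _draw_component(mean: float, sd: float, n: int, rng: np.random.Generator, bins: Optional[int]):
    if sd == 0.0:
        return np.full(n, mean)
    if bins is None:
        return rng.normal(mean, sd, size=n)
    # discretized-normal option: bin centers over ±4σ weighted by the density
    centers = np.linspace(mean - 4.0 * sd, mean + 4.0 * sd, bins)
    weights = np.exp(-0.5 * ((centers - mean) / sd) ** 2)
    weights /= weights.sum()
    return rng.choice(centers, size=n, p=weights)


def sample_parameters(
    dist: ParameterDistribution,
    n: int,
    rng: np.random.Generator,
    bins: Optional[int] = None,
) -> np.ndarray:
    """n independent (k_ref, E_a) pairs; k_ref ≤ 0 draws are redrawn."""
    if n < 1:
        raise InvalidInputError("n must be ≥ 1")
    k = _draw_component(dist.mean_k_ref, dist.sd_k_ref, n, rng, bins)
    for _ in range(1000):
        bad = k <= 0
        if not bad.any():
            break
        k[bad] = _draw_component(dist.mean_k_ref, dist.sd_k_ref, int(bad.sum()), rng, bins)
    else:
        raise RegionMismatchError("could not draw positive k_ref values")
    Ea = _draw_component(dist.mean_E_a, dist.sd_E_a, n, rng, bins)
    return np.column_stack([k, Ea])


def _accepted_parameters(
    dist: ParameterDistribution,
    n: int,
    rng: np.random.Generator,
    region: Optional[JointConfidenceRegion],
    bins: Optional[int],
) -> tuple[np.ndarray, float]:
    """n pairs, region-filtered by rejection-with-redraw; acceptance rate."""
    if region is None:
        return sample_parameters(dist, n, rng, bins), 1.0
    accepted: list[np.ndarray] = []
    drawn = kept = 0
    while sum(a.shape[0] for a in accepted) < n:
        batch = sample_parameters(dist, n, rng, bins)
        inside, mask = filter_pairs(batch, region)
        drawn += batch.shape[0]
        kept += inside.shape[0]
        accepted.append(inside)
        if drawn >= 100 * n and kept / drawn < 0.01:
            raise RegionMismatchError(
                f"joint region rejects {100 * (1 - kept / drawn):.1f}% of parameter draws: "
                "the sampling distribution and the fitted region are incompatible"
            )
    pairs = np.concatenate(accepted)[:n]
    return pairs, kept / drawn


def _rates(pairs: np.ndarray, T_kelvin, T_ref: float) -> np.ndarray:
    """Arrhenius rates for an (n, 2) pair array at scalar/array temperature."""
    k_ref = pairs[:, 0]
    Ea = pairs[:, 1]
    T = np.asarray(T_kelvin, dtype=float)
    if T.ndim == 0:
        return k_ref * np.exp(-(Ea / GAS_CONSTANT) * (1.0 / T - 1.0 / T_ref))
    return k_ref[:, None] * np.exp(-(Ea[:, None] / GAS_CONSTANT) * (1.0 / T - 1.0 / T_ref))


def mc_shelf_life(
    dist: ParameterDistribution,
    T_celsius: float,
    limit: float,
    config: MonteCarloConfig,
    region: Optional[JointConfidenceRegion] = None,
    T_ref: float = T_REF_FROZEN_K,
) -> ShelfLifeDistribution:
    """Shelf-life distribution at a constant temperature.

    Each iteration draws one (k_ref, E_a) pair (optionally filtered by
    the joint confidence region, redrawing until ``n_iterations`` pairs
    are accepted) and evaluates −ln(limit)/k(T).
    """
    if not (0.0 < limit < 1.0):
        raise InvalidInputError(f"limit must lie in (0, 1), got {limit}")
    rng_params, _ = config.streams()
    pairs, acc = _accepted_parameters(dist, config.n_iterations, rng_params, region, config.discretize_bins)
    k = _rates(pairs, celsius_to_kelvin(T_celsius), T_ref)
    samples = -np.log(limit) / k
    return ShelfLifeDistribution(samples, config.summary_alpha, acceptance_rate=acc)


def _chunk_structure(scenario: ColdChainScenario):
    """Flattened (duration, distribution) chunks of the scenario."""
    chunks: list[tuple[float, TemperatureDistribution]] = []
    for stage in scenario.stages:
        for dur in stage.chunk_durations():
            chunks.append((float(dur), stage.distribution))
    return chunks


def double_mc_remaining_shelf_life(
    scenario: ColdChainScenario,
    dist: ParameterDistribution,
    region: Optional[JointConfidenceRegion],
    T_assess_celsius: float,
    limit: float,
    config: MonteCarloConfig,
    vary_parameters: bool = True,
    vary_temperatures: bool = True,
    T_ref: float = T_REF_FROZEN_K,
) -> ShelfLifeDistribution:
    """Nested Monte Carlo remaining shelf life over a cold-chain scenario.

    Per iteration: (1) a (k_ref, E_a) pair is drawn from its normal
    laws, (2) pairs outside the joint confidence region are excluded
    (redrawn), (3) one temperature is drawn per stage chunk and the
    quality function is accumulated along the realized history.  The
    remaining shelf life at the assessment temperature is returned for
    every iteration; negative values (limit already crossed) are kept so
    the expired fraction is well defined.

    ``vary_parameters=False`` pins the parameters at their means
    (temperature-variability-only mode); ``vary_temperatures=False``
    holds every stage at its distribution mean (parameter-uncertainty-
    only mode); disabling both collapses to the deterministic
    calculation.
    """
    if not (0.0 < limit < 1.0):
        raise InvalidInputError(f"limit must lie in (0, 1), got {limit}")
    n = config.n_iterations
    rng_params, rng_temps = config.streams()

    if vary_parameters:
        pairs, acc = _accepted_parameters(dist, n, rng_params, region, config.discretize_bins)
    else:
        pairs = np.column_stack([np.full(n, dist.mean_k_ref), np.full(n, dist.mean_E_a)])
        acc = 1.0

    chunks = _chunk_structure(scenario)
    durations = np.array([c[0] for c in chunks])
    if vary_temperatures:
        temps_C = np.column_stack([d.sample(rng_temps, n) for _, d in chunks])
    else:
        temps_C = np.tile([d.mean() for _, d in chunks], (n, 1))
    temps_K = celsius_to_kelvin(temps_C)

    k_chunks = _rates(pairs, temps_K, T_ref)  # (n, n_chunks); row i uses pair i
    Q = k_chunks @ durations if k_chunks.ndim == 2 else k_chunks * durations
    k_assess = _rates(pairs, celsius_to_kelvin(T_assess_celsius), T_ref)
    samples = (-np.log(limit) - Q) / k_assess
    return ShelfLifeDistribution(samples, config.summary_alpha, acceptance_rate=acc)


@dataclass(frozen=True)
class SensitivityResult:
    """Paired what-if comparison run under common random numbers."""

    base: ShelfLifeDistribution
    variant: ShelfLifeDistribution
    label: str = ""

    @property
    def variance_ratio(self) -> float:
        """variant variance / base variance."""
        return self.variant.variance / self.base.variance


def sensitivity_ci_width(
    base: ParameterDistribution,
    scale: float,
    scenario: ColdChainScenario,
    region: Optional[JointConfidenceRegion],
    T_assess_celsius: float,
    limit: float,
    config: MonteCarloConfig,
    vary_temperatures: bool = True,
) -> SensitivityResult:
    """What-if on the width of the kinetic-parameter confidence intervals.

    Reruns the double scheme with both parameter standard deviations
    multiplied by ``scale`` (broader or narrower experimental error),
    under the same seed so temperature histories are shared between
    arms.  ``vary_temperatures=False`` isolates the parameter-uncertainty
    contribution.
    """
    scaled = base.scaled(scale)
    kwargs = dict(
        scenario=scenario,
        region=region,
        T_assess_celsius=T_assess_celsius,
        limit=limit,
        config=config,
        vary_temperatures=vary_temperatures,
    )
    d_base = double_mc_remaining_shelf_life(dist=base, **kwargs)
    d_variant = double_mc_remaining_shelf_life(dist=scaled, **kwargs)
    return SensitivityResult(d_base, d_variant, label=f"ci-width x{scale}")


def sensitivity_stage_distribution(
    scenario: ColdChainScenario,
    stage_name: str,
    replacement: TemperatureDistribution,
    dist: ParameterDistribution,
    region: Optional[JointConfidenceRegion],
    T_assess_celsius: float,
    limit: float,
    config: MonteCarloConfig,
) -> SensitivityResult:
    """What-if on one stage's temperature law (e.g. a better home freezer).

    Runs the double scheme on the original and the modified scenario
    under the same seed; because the chunk structure is unchanged, both
    arms consume identical uniform draws and the comparison is paired.
    """
    modified = scenario.replace_stage(stage_name, replacement)
    kwargs = dict(
        dist=dist,
        region=region,
        T_assess_celsius=T_assess_celsius,
        limit=limit,
        config=config,
    )
    d_base = double_mc_remaining_shelf_life(scenario=scenario, **kwargs)
    d_variant = double_mc_remaining_shelf_life(scenario=modified, **kwargs)
    return SensitivityResult(d_base, d_variant, label=f"stage {stage_name} replaced")
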