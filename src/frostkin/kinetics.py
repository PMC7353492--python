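"""Primary and secondary kinetic models for frozen-food quality loss.

The primary model describes how a quality index decays with time at a
constant temperature (zero- or first-order); the secondary model is the
Arrhenius law describing how the rate constant depends on temperature.
Under a stepwise time–temperature history the accumulated *quality
function* Q = Σ k(T_i)·t_i determines retention, the effective rate
k_eff = Q / t_tot, and the effective temperature T_eff — the constant
temperature that would have produced the same quality change.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .units import GAS_CONSTANT, T_REF_FROZEN_K, celsius_to_kelvin

__all__ = [
    "ReactionOrder",
    "ArrheniusParameters",
    "TemperatureProfile",
    "QualityState",
    "rate_constant",
    "retention_isothermal",
    "retention_dynamic",
    "effective_rate_and_temperature",
    "shelf_life_isothermal",
    "remaining_shelf_life",
]


class ReactionOrder(enum.Enum):
    """Apparent reaction order of the primary model."""

    ZERO = 0
    FIRST = 1


@dataclass(frozen=True)
class ArrheniusParameters:
    """Arrhenius secondary model: k(T) = k_ref·exp(−(E_a/R)(1/T − 1/T_ref)).

    Parameters
    ----------
    k_ref : float
        Rate constant at the reference temperature, per day; must be > 0.
    E_a : float
        Activation energy in J/mol.
    T_ref : float
        Reference temperature in Kelvin (default 253.15 K, i.e. −20 °C,
        the conventional reference for frozen foods).
    """

    k_ref: float
    E_a: float
    T_ref: float = T_REF_FROZEN_K
    gas_constant: float = field(default=GAS_CONSTANT, repr=False)

    def __post_init__(self):
        if not (self.k_ref > 0):
            raise InvalidInputError(f"k_ref must be > 0, got {self.k_ref}")
        if not (self.T_ref > 0):
            raise InvalidInputError(f"T_ref must be > 0 K, got {self.T_ref}")
        if self.gas_constant != GAS_CONSTANT:
            raise InvalidInputError("gas_constant is fixed at 8.314 J/(mol K)")

    @classmethod
    def from_celsius(cls, k_ref: float, E_a: float, t_ref_celsius: float = -20.0) -> "ArrheniusParameters":
        """Construct with the reference temperature given in °C."""
        return cls(k_ref=k_ref, E_a=E_a, T_ref=celsius_to_kelvin(t_ref_celsius))

    @property
    def E_a_kJ(self) -> float:
        return self.E_a / 1000.0


@dataclass(frozen=True)
class TemperatureProfile:
    """A stepwise time–temperature history.

    ``steps`` is an ordered sequence of (duration in days, temperature in
    Kelvin); durations must be strictly positive.
    """

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.steps) == 0:
            raise InvalidInputError("temperature profile must contain at least one step")
        for i, (dur, temp) in enumerate(self.steps):
            if not (dur > 0):
                raise InvalidInputError(f"step {i}: duration must be > 0 d, got {dur}")
            if not (temp > 0):
                raise InvalidInputError(f"step {i}: temperature must be > 0 K, got {temp}")

    @classmethod
    def from_celsius_steps(cls, steps: Sequence[tuple[float, float]]) -> "TemperatureProfile":
        """Build from (duration_days, temperature_C) pairs."""
        return cls(tuple((float(d), celsius_to_kelvin(t)) for d, t in steps))

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for d, _ in self.steps])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for _, t in self.steps])

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def concat(self, other: "TemperatureProfile") -> "TemperatureProfile":
        return TemperatureProfile(self.steps + other.steps)


@dataclass(frozen=True)
class QualityState:
    """Quality accumulated along a temperature history.

    ``accumulated_quality`` is Q = Σ k(T_i)·t_i; for first-order kinetics
    retention = exp(−Q), for zero order retention = 1 − Q.
    """

    retention: float
    accumulated_quality: float


def rate_constant(params: ArrheniusParameters, T):
    """Arrhenius rate constant k(T) in per day; T in Kelvin (scalar or array).

    Strictly increasing in T when E_a > 0 and equal to k_ref at T = T_ref.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise InvalidInputError("temperature must be > 0 K")
    k = params.k_ref * np.exp(-(params.E_a / params.gas_constant) * (1.0 / T_arr - 1.0 / params.T_ref))
    return float(k) if np.ndim(T) == 0 else k


def _retention_from_quality(Q, order: ReactionOrder):
    if order is ReactionOrder.FIRST:
        return np.exp(-Q)
    return 1.0 - Q  # zero order; may go ≤ 0 past exhaustion


def retention_isothermal(params: ArrheniusParameters, T, t, order: ReactionOrder = ReactionOrder.FIRST):
    """Retention C/C0 after time t (days) at constant temperature T (Kelvin)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be nonnegative")
    Q = rate_constant(params, T) * t_arr
    r = _retention_from_quality(Q, order)
    return float(r) if np.ndim(t) == 0 and np.ndim(T) == 0 else r


def retention_dynamic(
    params: ArrheniusParameters,
    profile: TemperatureProfile,
    order: ReactionOrder = ReactionOrder.FIRST,
) -> QualityState:
    """Accumulate quality loss over a stepwise temperature history.

    Q = Σ_i k(T_i)·t_i; a single-step profile reproduces
    :func:`retention_isothermal` exactly, and Q is additive over
    concatenated profiles.
    """
    rates = rate_constant(params, profile.temperatures)
    Q = float(np.dot(rates, profile.durations))
    return QualityState(retention=float(_retention_from_quality(Q, order)), accumulated_quality=Q)


def effective_rate_and_temperature(
    params: ArrheniusParameters, profile: TemperatureProfile
) -> tuple[float, float]:
    """Effective rate and temperature of a variable history.

    k_eff = Q / t_tot is the constant rate giving the same quality change
    over the same total time; T_eff inverts the Arrhenius law at k_eff:

        T_eff = 1 / (1/T_ref − (R/E_a)·ln(k_eff/k_ref))

    Raises if E_a = 0 (the inversion is undefined; k_eff is still well
    defined and can be obtained from :func:`retention_dynamic`).
    """
    state = retention_dynamic(params, profile)
    k_eff = state.accumulated_quality / profile.total_duration
    if params.E_a == 0:
        raise InvalidInputError("T_eff is undefined when E_a = 0 (rate has no temperature dependence)")
    inv_T = 1.0 / params.T_ref - (params.gas_constant / params.E_a) * math.log(k_eff / params.k_ref)
    return k_eff, 1.0 / inv_T


def _quality_at_limit(limit: float, order: ReactionOrder) -> float:
    if not (0.0 < limit < 1.0):
        raise InvalidInputError(f"acceptability limit must lie in (0, 1), got {limit}")
    if order is ReactionOrder.FIRST:
        return -math.log(limit)
    return 1.0 - limit


def shelf_life_isothermal(
    params: ArrheniusParameters,
    T,
    limit: float,
    order: ReactionOrder = ReactionOrder.FIRST,
):
    """Days until retention reaches ``limit`` at constant temperature T (K).

    First order: −ln(limit)/k(T); zero order: (1 − limit)/k(T).
    """
    Q_limit = _quality_at_limit(limit, order)
    k = rate_constant(params, T)
    out = Q_limit / k
    return float(out) if np.ndim(T) == 0 else out


def remaining_shelf_life(
    state: QualityState,
    params: ArrheniusParameters,
    T_assess,
    limit: float,
    order: ReactionOrder = ReactionOrder.FIRST,
):
    """Days left at a constant assessment temperature until the limit.

    Computed as (Q_limit − Q_accumulated)/k(T_assess).  Negative values
    mean the limit was already crossed and are returned as-is (not
    clamped) so expired-fraction statistics remain computable downstream.
    """
    Q_limit = _quality_at_limit(limit, order)
    k = rate_constant(params, T_assess)
    out = (Q_limit - state.accumulated_quality) / k
    return float(out) if np.ndim(T_assess) == 0 else out
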