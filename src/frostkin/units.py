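"""Unit conventions and conversions.

All user-facing interfaces take temperatures in degrees Celsius and
activation energies in kJ/mol; internally every equation operates in
Kelvin and J/mol.  The universal gas constant is fixed at 8.314 J/(mol K).
"""

from __future__ import annotations

import numpy as np

GAS_CONSTANT: float = 8.314  # J/(mol K)
KELVIN_OFFSET: float = 273.15

#: Reference temperature conventionally used for frozen foods (−20 °C).
T_REF_FROZEN_K: float = 253.15


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (scalar or array)."""
    return np.asarray(t_celsius, dtype=float) + KELVIN_OFFSET if np.ndim(t_celsius) else float(t_celsius) + KELVIN_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert K to °C (scalar or array)."""
    return np.asarray(t_kelvin, dtype=float) - KELVIN_OFFSET if np.ndim(t_kelvin) else float(t_kelvin) - KELVIN_OFFSET


def joules_to_kilojoules(e: float) -> float:
    return e / 1000.0


def kilojoules_to_joules(e: float) -> float:
    return e * 1000.0


def ci_halfwidth_to_sigma(halfwidth: float, z: float = 1.959963984540054) -> float:
    """Convert a 95% confidence half-width to a normal standard deviation.

    Uses the large-sample normal factor z = Φ⁻¹(0.975) ≈ 1.96, the pairing
    under which a ±11.34 kJ/mol interval corresponds to σ ≈ 5.8 kJ/mol.
    """
    if halfwidth < 0:
        raise ValueError("confidence half-width must be nonnegative")
    return halfwidth / z
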