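"""Deterministic kinetics: rate constants, retention and shelf life.

Uses the frozen-green-peas vitamin C case study: first-order loss with
k_ref = 0.00177 d⁻¹ at the −20 °C reference and E_a = 104.24 kJ/mol.
"""

import frostkin as fk

params = fk.ArrheniusParameters.from_celsius(k_ref=0.00177, E_a=104240.0, t_ref_celsius=-20.0)

for T_C in (-20.0, -18.0, -15.0, -12.0):
    k = fk.rate_constant(params, T_C + 273.15)
    sl = fk.shelf_life_isothermal(params, T_C + 273.15, limit=0.5)
    print(f"{T_C:6.1f} °C: k = {k:.5f} d⁻¹, shelf life to 50% loss = {sl:6.1f} d")
# Each 2–3 °C of extra warmth roughly halves the time to the 50% vitamin C limit.

profile = fk.TemperatureProfile.from_celsius_steps([(60, -22.0), (40, -18.0), (30, -15.0)])
state = fk.retention_dynamic(params, profile)
k_eff, T_eff = fk.effective_rate_and_temperature(params, profile)
print(f"\n130-day stepwise history: retention = {state.retention:.3f}")
print(f"effective temperature = {T_eff - 273.15:.2f} °C (constant-T equivalent of the history)")

remaining = fk.remaining_shelf_life(state, params, 273.15 - 18.0, limit=0.5)
print(f"remaining shelf life at −18 °C after the history: {remaining:.1f} d")
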