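"""One-step vs two-step estimation of (k_ref, E_a) on synthetic data.

Generates an isothermal study (5 sub-zero temperatures, 8 sampling
times each, noise sd 0.02 on retention) from known ground truth, then
fits it both ways.  The one-step route uses all 40 observations in a
single nonlinear regression and yields tighter confidence intervals.
"""

import frostkin as fk

spec = fk.SyntheticSpec(noise_sd=0.02, seed=42)
dataset = fk.generate_isothermal(spec)
truth = spec.true_parameters
print(f"truth: k_ref = {truth.k_ref} d⁻¹, E_a = {truth.E_a / 1000:.2f} kJ/mol\n")

for fit in (fk.fit_one_step(dataset), fk.fit_two_step(dataset)):
    s = fit.summary()
    print(
        f"{s['method']:>8}: k_ref = {s['k_ref_per_day']:.5f} ± {s['ci95_k_ref_per_day']:.5f} d⁻¹, "
        f"E_a = {s['E_a_kJ_per_mol']:.2f} ± {s['ci95_E_a_kJ_per_mol']:.2f} kJ/mol (95% CI)"
    )
# The ± values are t-based 95% half-widths; the two-step intervals are
# wider because the Arrhenius step sees only 5 aggregated rate constants.
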