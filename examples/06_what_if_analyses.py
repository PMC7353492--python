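"""Paired what-if analyses: experimental precision and freezer quality.

Both analyses rerun the double Monte Carlo under common random numbers
so differences between arms reflect the intervention, not sampling
noise.
"""

import frostkin as fk
from frostkin.montecarlo import case_study_parameter_distribution

dist = case_study_parameter_distribution()
scenario = fk.case_study_scenario()
config = fk.MonteCarloConfig(n_iterations=10_000, seed=1)

print("Effect of kinetic-parameter CI width (parameter contribution isolated):")
for scale in (3.0, 0.1):
    res = fk.sensitivity_ci_width(dist, scale, scenario, None, -18.0, 0.5, config, vary_temperatures=False)
    print(f"  CI × {scale:>3}: parameter-only sd {res.base.sd:5.1f} d → {res.variant.sd:5.1f} d "
          f"(variance ratio {res.variance_ratio:.3f})")
# Broader experimental error (×3) makes parameter uncertainty a dominant
# contributor; tighter data (×0.1) make it negligible next to the chain's
# temperature variability.

print("\nEffect of the domestic freezer (the chain's weakest link):")
better = fk.TruncatedNormal(mean_C=-18.0, sd_C=1.0, lower_C=-30.0, upper_C=-2.0)
res = fk.sensitivity_stage_distribution(scenario, "domestic", better, dist, None, -18.0, 0.5, config)
print(f"  broad home storage:   mean {res.base.mean:6.1f} d, sd {res.base.sd:5.1f} d, "
      f"expired {res.base.fraction_expired:.1%}")
print(f"  −18 °C ± 1 °C freezer: mean {res.variant.mean:6.1f} d, sd {res.variant.sd:5.1f} d, "
      f"expired {res.variant.fraction_expired:.1%}")
# A colder, steadier home freezer both extends the mean remaining shelf
# life and sharply narrows its distribution.
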