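# frostkin

Shelf-life kinetics and cold-chain uncertainty propagation for frozen
foods.

Frozen products degrade slowly but surely: a nutrient such as vitamin C
in frozen green peas is lost by an apparent first-order reaction whose
rate depends strongly on storage temperature. Practitioners usually fit
kinetic parameters, plug in an average storage temperature, and quote a
single shelf-life number. That number hides two real sources of spread:
the statistical uncertainty of the fitted kinetic parameters, and the
variability of temperatures a pack actually experiences across the
warehouse, retail and domestic stages of the cold chain. `frostkin`
computes shelf life as a *distribution* that carries both.

## The model

Quality loss follows first-order kinetics with an Arrhenius secondary
model:

    C/C0 = exp(−k(T)·t),       k(T) = k_ref · exp(−(E_a/R)·(1/T − 1/T_ref))

with `T_ref = −20 °C` (the frozen-food convention), `R = 8.314 J/(mol·K)`.
Under a stepwise temperature history the quality function
`Q = Σ k(T_i)·t_i` accumulates, giving retention `exp(−Q)`, the
effective temperature of the history, and the remaining shelf life
`(−ln(limit) − Q)/k(T_assess)` at an assessment temperature.

On top of this deterministic core the package provides:

* **Estimation** — a one-step nonlinear least-squares fit of
  `(k_ref, E_a)` to all isothermal observations jointly (analytic
  Jacobian, asymptotic covariance `(JᵀJ)⁻¹·SSE/(n−p)`, t-based 95%
  intervals), alongside the traditional two-step route for comparison.
* **Joint confidence regions** — the F-based SSE contour
  `SSE ≤ SSE_min·(1 + p/(n−p)·F(p, n−p, 1−α))`, which captures the
  strong k_ref–E_a correlation and filters implausible parameter pairs.
* **Cold-chain scenarios** — ordered stages with durations and
  truncated-normal or histogram temperature laws, including a packaged
  synthetic 130-day warehouse/retail/domestic case study.
* **Double Monte Carlo** — nested sampling of kinetic parameters
  (region-filtered) and stage temperatures into distributions of
  (remaining) shelf life, plus paired what-if analyses for experimental
  precision and freezer quality.

## Worked example

```python
import frostkin as fk

bundle = fk.generate_case_study_bundle(seed=1)        # synthetic peas study + fit
region = fk.JointConfidenceRegion.from_fit(bundle.fit, bundle.dataset)
s = bundle.fit.summary()
dist = fk.ParameterDistribution.from_fit_summary(
    s["k_ref_per_day"], s["ci95_k_ref_per_day"],
    s["E_a_kJ_per_mol"] * 1000, s["ci95_E_a_kJ_per_mol"] * 1000,
)
config = fk.MonteCarloConfig(n_iterations=10_000, seed=1)
d = fk.double_mc_remaining_shelf_life(bundle.scenario, dist, region, -18.0, 0.5, config)
print(f"mean {d.mean:.1f} d, sd {d.sd:.1f} d, expired {d.fraction_expired:.1%}")
```

Running the narrative scripts in `examples/` prints, among others:

```
  parameters + temperatures: mean  112.7 d, sd  75.2 d, expired 7.6%
            parameters only: mean  144.9 d, sd   3.2 d, expired 0.0%
          temperatures only: mean  112.7 d, sd  75.0 d, expired 7.6%

deterministic (mean parameters, mean temperatures): 144.9 d
```

Read: after 130 days in the chain, the deterministic calculation
promises ~145 days of remaining shelf life at −18 °C, but once
temperature variability enters, the expectation drops to ~113 days with
a ±75-day spread — and about 8% of packs are already past the 50%
vitamin C limit. Temperature variability, not parameter uncertainty,
dominates the spread for this well-designed dataset; the what-if
scripts show how that balance shifts with broader experimental error or
a better domestic freezer.

A thin CLI mirrors the library (`frostkin fit | region | shelf-life |
simulate-chain | sensitivity | synth`); every run writes a manifest
with its seed and configuration.

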