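"""Design-based confidence intervals via the Rao-Wu PSU bootstrap.

Simulates a weighted multistage sample (49 strata x 2 PSUs, log-normal
weights), fits the two-knot model, then refits it on 200 PSU-bootstrap
resamples to get design-based standard errors and bootstrap-t intervals
for every interpretable parameter, plus an odds-ratio curve against a
BMI-25 reference.
"""

import warnings

import numpy as np

import freeknot as fk

data, truth = fk.simulate_dataset(
    fk.SimConfig(n=4000, p0=0.33, weighted=True),
    rng=np.random.default_rng(8))
print(f"n={data.n}, strata H={data.design.H}, "
      f"weight sum {data.design.weight.sum():,.0f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fk.fit_fixed_start(data, [24.0, 33.0])
    inf = fk.bootstrap_inference(data, fit, D2=200, rng=99)

print(f"\nfitted knots {np.round(fit.spec.knots, 2)}; "
      f"{inf.n_dropped} of {inf.D2} replicates dropped")
print("\nparameter table (bootstrap-t 95% CI):")
print(inf.table().round(3).to_string())

pw = fit.to_piecewise()
print("\nodds ratios vs BMI 25 (covariate-free by construction):")
curve = fk.or_curve(pw, 25.0, [18.0, 22.0, 28.0, 36.0, 44.0])
print(curve.round(3).to_string(index=False))
print("\nOR > 1 at low and high BMI reflects the U-shaped risk; the flat")
print("middle segment keeps the OR near 1 between the knots.")
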