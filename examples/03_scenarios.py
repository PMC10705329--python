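"""Stochastic 10-year projections under the five management scenarios.

Each scenario redraws the three stage survivals every projection year from
uniform distributions on their 95% confidence intervals (fecundities held
fixed), projects 1000 replicate trajectories from the stable-stage start of
(192, 32, 276), and summarizes the per-replicate realized growth rate
lambda = (N10/N0)^(1/10).  Scenario 1 is the observed situation; 2 removes
antlerless harvest; 3 adds a 5% harvest; 4 and 5 raise fawn survival to
moderate (0.270) and high (0.430) literature values.
"""

import deerpop as dp

scenarios = dp.builtin_scenarios(seed=1)
print("scenario summaries (1000 replicates x 10 years):")
results = {}
for key, spec in scenarios.items():
    res = dp.run_scenario(spec)
    results[key] = res
    s = res.summary
    print(f"  {spec.name:36s} mean λ {s['mean_lambda']:.3f} "
          f"(IQR {s['iqr_low']:.3f}-{s['iqr_high']:.3f}), "
          f"{100 * s['fraction_positive']:>5.1f}% of replicates growing")

print("\nonly improved fawn survival (scenarios 4-5) yields mean growth above 1;")
print("harvest restriction alone (scenario 2) still projects decline\n")

print("scenario 1 averaged perturbation metrics (all 10,000 drawn matrices):")
print(dp.sensitivity_report(results["1"]).round(3).to_string(index=False))
print("\nadult survival dominates: each +1% of adult survival moves mean λ by")
print(f"{results['1'].sensitivity['S_a'] * 0.01:.3f}; +1% fawn survival moves it by "
      f"{results['1'].sensitivity['S_f'] * 0.01:.3f}")
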