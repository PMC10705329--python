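"""End-to-end pipeline, in both parameterization modes.

Mode A runs the five built-in scenarios from the published parameter table
and writes the full report bundle (summary JSON, parameter and sensitivity
CSVs, replicate trajectories, growth-rate histograms, run log).

Mode B is the parameter-recovery route: simulate telemetry at the same
true rates, estimate stage survivals from the synthetic encounter
histories (substituting a literature yearling estimate, as one would when
a small collared yearling sample shows no deaths), and project from the
estimates.  The two scenario-1 growth rates agree closely.
"""

import json
import tempfile
from pathlib import Path

import deerpop as dp

out = Path(tempfile.mkdtemp(prefix="deerpop_"))
config = dp.AnalysisConfig(replicates=1000, seed=11, out_dir=out)
results = dp.run_pipeline(config)
print(f"mode A: report bundle written to {out}")
for line in json.loads((out / "summary.json").read_text()):
    print(f"  scenario {line['scenario']!r}: mean λ = {line['mean_lambda']:.3f}")

adults = dp.generate_collared_cohort(
    dp.CohortSpec(n_animals=2000, stage="adult", true_annual_survival=0.835,
                  harvest_fraction_of_mortality=2 / 11, n_years=1,
                  horizon=730.0, seed=101)
)
fawns = dp.generate_fawn_cohort(n_dams=1400, birth_rate=1.43,
                                true_12wk_survival=0.157, seed=102)
yearling_lit = dp.SurvivalEstimate(point=0.952, ci_low=0.866, ci_high=1.000,
                                   n=21, n_events=1, horizon=365.0)
spec = dp.scenario_from_records(
    fawn_records=fawns, yearling_records=None, adult_records=adults,
    yearling_substitute=yearling_lit, name="estimated from synthetic telemetry",
    replicates=1000, seed=11,
)
res = dp.run_scenario(spec)
direct = results["1"].summary["mean_lambda"]
print(f"\nmode B: scenario built from estimated survivals "
      f"(S_f {spec.S_f_bounds}, S_a {spec.S_a_bounds})")
print(f"  mean λ estimated-parameter run: {res.summary['mean_lambda']:.3f}")
print(f"  mean λ table-parameterized run: {direct:.3f}")
print("  note: large synthetic samples shrink the CIs, so the estimated run")
print("  hews closer to the deterministic growth rate at the point estimates")
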