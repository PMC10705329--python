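# deerpop

Stage-structured demographic analysis for a declining white-tailed deer
(*Odocoileus virginianus*) population, built for wildlife biologists who
want to turn telemetry-based vital rates into population projections and
management comparisons. The package covers the whole workflow: synthetic
staggered-entry encounter histories, Kaplan–Meier survival estimation,
Leslie matrix eigen-analysis, and stochastic 10-year projections under
harvest and fawn-survival scenarios.

## The model

The population is female-only with three stages — fawn (0–1 yr), yearling
(1–2 yr), adult (≥2 yr) — projected annually by **n**(t+1) = **A n**(t)
with

```
        | 0    F_y  F_a |
    A = | S_f  0    0   |
        | 0    S_y  S_a |
```

where S_i are annual stage survivals and F_i = (B_i × S_i)/2 converts a
birth rate B_i (fawns per female per year) into female fawns per female
under a 1:1 birth sex ratio. The dominant eigenvalue λ of **A** is the
asymptotic annual growth multiplier; its right eigenvector **w** is the
stable stage distribution and its left eigenvector **v** the reproductive
values. Sensitivities s_ij = v_i w_j / ⟨**v**, **w**⟩ and elasticities
e_ij = (a_ij/λ) s_ij quantify how λ responds to each vital rate.

Environmental uncertainty enters through the survival rates: each
projection year every S_i is redrawn from a uniform distribution on its
95% confidence interval (fecundities stay fixed), and 1000 replicate
10-year trajectories are summarized by the per-replicate realized growth
rate λ = (N₁₀/N₀)^(1/10) — its mean, interquartile range, and the
fraction of replicates with λ > 1.

Stage survivals come from staggered-entry Kaplan–Meier estimation:
animals join the risk set at their individual capture days, variance is
Greenwood's, and 95% CIs use the complementary log–log transform.
Hunter-harvest mortalities can be removed from the sample to estimate
natural survival.

## Worked example

```python
import deerpop as dp

A = dp.assemble(S_f=0.157, S_y=0.952, S_a=0.835, F_y=0.519, F_a=0.597)
eig = dp.dominant_eigen(A)
print(round(eig.lam, 4))                       # 0.945
print(dp.stable_stage_abundances(A, 500))      # [192  32 276]

res = dp.run_scenario(dp.builtin_scenarios(seed=1)["1"])
print(res.summary)
```

prints a deterministic growth rate of 0.945 (a 5.5% annual decline at the
point estimates), a stable stage allocation of 192 fawns, 32 yearlings and
276 adults out of 500, and the stochastic scenario-1 summary

```
{'scenario': '1 observed vital rates', 'mean_lambda': 0.9596..., 'iqr_low': 0.9496...,
 'iqr_high': 0.9697..., 'fraction_positive': 0.007, 'replicates': 1000, 'years': 10}
```

i.e. a mean realized growth rate of 0.960 (4.0% annual decline) with only
0.7% of replicates growing. Running all five scenarios
(`examples/03_scenarios.py`) shows that removing antlerless harvest alone
(scenario 2, mean λ ≈ 0.979) does not reverse the decline, while moderate
or high fawn survival (scenarios 4–5, mean λ ≈ 1.018 and 1.084) does —
the analysis' central management message. The averaged elasticity of λ to
adult survival is ≈ 0.684: adult survival is the proportionally dominant
rate, with each +1% of adult survival worth ≈ 0.008 of λ and each +1% of
fawn survival ≈ 0.006.

The `examples/` directory holds one short narrative script per
capability; the `deerpop` console command exposes the same pipeline as
`simulate-data`, `estimate-survival`, `project` and `report` subcommands.

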