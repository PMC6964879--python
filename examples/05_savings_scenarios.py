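"""Counterfactual savings from permanent annual reductions in smoking.

Fits the model, then simulates 5%-a-year permanent relative reductions in
smoking prevalence and mean consumption per smoker over five years; savings
per capita come with Monte-Carlo 95% prediction intervals from draws of the
elasticities (Cholesky factor of the cluster-robust covariance).
"""

import smokecast as sc

_, panel, _ = sc.generate_panel(sc.SynthConfig(seed=1))
fit = sc.fit_2sls(sc.build_design(panel, sc.ModelSpec()))

base_year = 2014
rows = panel.data[panel.data.year == base_year]
baseline = float((rows.hexp * rows.population).sum() / rows.population.sum())
population = float(rows.population.sum())

scen = sc.ScenarioSpec(r_prev=0.05, r_cons=0.05, horizon=5,
                       n_trials=50_000, seed=0, population=population)
result = sc.simulate_savings(fit, scen, baseline)

print(f"baseline expenditure: ${baseline:,.0f}/capita; population {population/1e6:.1f}M")
print("\nper-capita savings by year (mean [95% interval]):")
for year, row in result.per_capita.iterrows():
    nat = result.national.loc[year]
    print(f"  year {year}: ${row['mean']:6.0f}  [${row['low']:.0f}, ${row['high']:.0f}]"
          f"  = {row['pct_of_baseline']:.2f}% of baseline"
          f"  | national ${nat['mean']/1e9:.1f}B")
print("\nSavings accumulate roughly linearly because the log effect is")
print("t * (b_prev ln(0.95) + b_cons ln(0.95)); intervals reflect coefficient")
print("uncertainty only (other drivers of expenditure held constant).")
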