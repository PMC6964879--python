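"""Estimate the smoking/expenditure elasticities by fixed-effects 2SLS.

Mean consumption per smoker is instrumented with deeper lags of the smoking
variables to absorb measurement error; standard errors are clustered by
state.  The printed elasticities answer: by how many percent does next
year's real per-capita healthcare expenditure move when a state's smoking
prevalence (or consumption per smoker) moves by one percent?
"""

import smokecast as sc

_, panel, _ = sc.generate_panel(sc.SynthConfig(seed=1))
spec = sc.ModelSpec()              # prev/cons/income/elderly/black/hispanic,
                                   # region tax terms, 3 national trends
design = sc.build_design(panel, spec)
fit = sc.fit_2sls(design)

print(fit.summary())
print()
ci = fit.conf_int(0.95)
for var in ("prev", "cons"):
    print(f"{var}: {fit.beta[var]:.4f} (95% CI {ci.loc[var, 'low']:.4f}, "
          f"{ci.loc[var, 'high']:.4f})  first-stage F = "
          f"{fit.first_stage.get('cons', {}).get('F', float('nan')):.1f}")
r2 = sc.panel_r2(fit, design)
print(f"\nwithin R2 {r2.within:.3f} | between {r2.between:.3f} | total {r2.total:.3f} "
      f"| rho {r2.rho:.3f} | RMSE {r2.rmse:.4f}")
print("\nThe generator's true elasticities are 0.104 (prevalence) and 0.113")
print("(consumption); the estimates should fall within ~2 cluster SEs of those.")
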