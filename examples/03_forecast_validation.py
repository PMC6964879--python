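"""Recursive out-of-sample validation of the forecasting model.

Re-estimates the model on expanding samples (1992-2006, then adding a year
at a time) and forecasts each next year; summarizes accuracy by log-scale
RMSFE, mean relative bias in dollars, and forecast-observed correlation.
"""

import smokecast as sc

_, panel, _ = sc.generate_panel(sc.SynthConfig(seed=1))
spec = sc.ModelSpec()

fits = sc.recursive_fit(panel, spec, base_end=2006, final_end=2013)
forecasts = sc.one_step_forecasts(fits, panel)
metrics = sc.forecast_metrics(forecasts)

print(f"{len(forecasts)} one-step forecasts "
      f"({len(fits)} origins x {len(panel.states)} states)")
print(f"RMSFE (log scale)        : {metrics.rmsfe:.4f}")
print(f"mean relative bias       : {metrics.mean_relative_bias_pct:+.2f}%")
print(f"forecast/observed corr   : {metrics.correlation:.3f}")
print("\nper-target-year accuracy:")
print(metrics.per_year.round(4).to_string())
print("\nA RMSFE near the in-sample sigma (~0.03) and bias under 1% indicate")
print("the reduced form forecasts next-year expenditure without degradation")
print("out of sample; the correlation is inflated by state fixed effects.")
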