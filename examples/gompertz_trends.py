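"""Fit Gompertz growth curves to daily GPP and trend them along treatments.

Generates the synthetic 18-mesocosm experiment's daily metabolism table,
fits the three-parameter sigmoid per stream, and regresses the asymptote K
against the % cattle dung gradient.
"""

from riversubsidy.growthfit import fit_gompertz, parameter_trend, time_to_fraction
from riversubsidy.synthdata import (
    ExperimentDesign,
    daily_metabolism_table,
    generate_metabolism_truth,
)

design = ExperimentDesign()
truth = generate_metabolism_truth(design, seed=1)
table = daily_metabolism_table(truth, design, seed=2)

fits = []
for stream, g in table.groupby("stream"):
    fit = fit_gompertz(g["day"], g["gpp"],
                       treatment_pct_cattle=g["treatment_pct_cattle"].iloc[0],
                       stream=stream)
    fits.append(fit)

print("stream   %cattle     K    rate    lag    t(90% of K)")
for f in sorted(fits, key=lambda f: f.treatment_pct_cattle)[:6]:
    t90 = time_to_fraction(f, 0.9)
    print(f"{f.stream:7s}  {f.treatment_pct_cattle:5.0f}  {f.K:6.2f}  "
          f"{f.rate:.3f}  {f.lag:5.1f}  {t90:6.1f} d")

trend = parameter_trend(fits, "K")
print(f"\nK vs % cattle: slope {trend.slope:.4f} (t = {trend.slope_t:.1f}), "
      f"curvature flagged: {trend.curvature}")
# Maximum GPP rises roughly linearly with the cattle-dung share (~0.05 units
# per percentage point here), while growth rate and lag respond nonlinearly.
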