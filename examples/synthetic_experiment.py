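"""Run the whole pipeline on one seeded synthetic experiment.

Generates 18 mesocosms of diel DO, inverts daily metabolism, summarises
weekly trophic state, fits Gompertz curves, and prints the headline
treatment responses.
"""

from riversubsidy.io import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=42, metabolism_day_stride=2, parafac_n_starts=2)
summary = run_pipeline(cfg)

print("theta sensitivity (rank correlation of treatment means across "
      f"theta = 1.045 vs 1.1085): GPP {summary['theta_rank_correlation']['gpp']:.2f}, "
      f"ER {summary['theta_rank_correlation']['er']:.2f}")
k = summary["gompertz_K_vs_treatment"]
print(f"Gompertz K(GPP) vs % cattle: slope {k['slope']:.4f} (t = {k['slope_t']:.1f})")
er = summary["er_K_vs_treatment"]
print(f"Gompertz K(ER) vs % cattle: slope {er['slope']:.5f} (t = {er['slope_t']:.1f})")
print(f"stream-weeks heterotrophic in week 1: "
      f"{100 * summary['week1_heterotrophic_frac']:.0f}%")
print(f"stream-weeks autotrophic in weeks 2-6: "
      f"{100 * summary['later_autotrophic_frac']:.0f}%")
print(f"PARAFAC explained variance: {summary['parafac_explained_variance_pct']:.1f}%")
# Expected pattern: GPP's asymptote climbs with the cattle-dung share while
# ER shows no treatment trend, and every mesocosm flips from net
# heterotrophy (week 1) to net autotrophy once the biofilm establishes.
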