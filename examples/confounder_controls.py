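"""Check that a detected optimum is not an artifact of heat or light.

Two controls on one site: (i) partial Spearman correlation of SM and ER
holding radiation, temperature and VPD fixed, compared with the
uncontrolled correlation; (ii) a random forest of ER on all four drivers,
whose exact TreeSHAP soil-moisture attributions are pushed through the same
boundary-line detection.  On a confounder-free site both re-detections land
near the observational optimum.
"""

from fluxresp import (
    PipelineConfig,
    SyntheticSiteConfig,
    detect_optimum_shap,
    generate_site,
    partial_spearman,
    shap_response,
    site_pipeline,
)
from fluxresp.io import filter_quality, growing_season_mask

cfg = PipelineConfig()
site, truth = generate_site(SyntheticSiteConfig(n_records=8000, seed=5))
_, obs = site_pipeline(site, cfg)
print(f"observational optimum: {obs.smer_opt:.2f}% (truth {truth['true_opt']:.1f}%)")

clean = filter_quality(site)
mask = growing_season_mask(clean)
d = clean.data.loc[mask, ["er", "sm", "isr", "tair", "vpd"]].dropna()

r_marginal = partial_spearman(d["er"], d["sm"])
r_partial = partial_spearman(d["er"], d["sm"], d[["isr", "tair", "vpd"]].to_numpy())
print(f"Spearman r(SM, ER):          {r_marginal:+.3f}")
print(f"partial r | ISR, Tair, VPD:  {r_partial:+.3f}")

attr = shap_response(d, n_trees=300, seed=0)
shares = attr.contributions.abs().mean()
print("mean |SHAP| per driver:",
      ", ".join(f"{k}={v:.2f}" for k, v in shares.items()))
_, shap_res = detect_optimum_shap(attr.sm_values, attr.sm, cfg)
print(f"SHAP-based optimum: {shap_res.smer_opt:.2f}% (detected = {shap_res.detected})")
print("\nA SHAP optimum close to the observational one says the peak is "
      "carried by soil moisture itself, not by co-varying weather.")
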