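"""A site that never gets wet enough to pass its optimum is not 'detected'.

The generator truncates the soil-moisture range below the response apex, so
ER increases monotonically over everything the site experiences.  The
pipeline must report a failure code rather than invent an optimum - sites
like this are the reason some flux towers yield no optimum estimate.
"""

from fluxresp import (
    PipelineConfig,
    SyntheticSiteConfig,
    generate_monotone_site,
    generate_site,
    site_pipeline,
)

cfg = SyntheticSiteConfig(seed=17)

truncated, truth = generate_monotone_site(cfg, mode="truncated")
_, res = site_pipeline(truncated, PipelineConfig())
print(f"truncated-range site: detected = {res.detected}, reason = {res.reason}")
print(f"  (tent apex sits at {truth['tent_apex']:.1f}% SM, above the site's "
      f"max of {truncated.data.sm.max():.1f}%)")

control, truth2 = generate_site(cfg)
_, res2 = site_pipeline(control, PipelineConfig())
print(f"full-range control (same seed): detected = {res2.detected}, "
      f"optimum = {res2.smer_opt:.1f}% (truth {truth2['true_opt']:.1f}%)")
print("\nDetection failure is a data outcome, not an error: the reason code "
      "distinguishes range truncation from weak trends.")
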