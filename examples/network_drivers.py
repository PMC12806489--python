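"""Cross-site analysis: what controls where the optimum sits?

Generates a 25-site network whose true optima follow
smer_opt = 3 + 0.86 * SM_growth (+ scatter), detects the optimum at every
site, summarises the population and attributes the cross-site variation to
the 12 candidate drivers.  Growing-season moisture should dominate the
variance partition and its regression slope should recover ~0.86.
"""

import pandas as pd

from fluxresp import (
    NetworkConfig,
    SyntheticSiteConfig,
    attribute_drivers,
    generate_network,
    site_pipeline,
)
from fluxresp.sitestats import network_summary

net = NetworkConfig(n_sites=25, seed=3,
                    site_template=SyntheticSiteConfig(n_records=8000))
network = generate_network(net)

results = []
for site in network.sites:
    _, res = site_pipeline(site)
    results.append(res)

summary = network_summary(results)
print(f"detected at {summary['n_detected']}/{summary['n_sites']} sites")
print(f"optimum: median {summary['smer_opt']['median']:.1f}%, "
      f"range {summary['smer_opt']['min']:.1f}-{summary['smer_opt']['max']:.1f}%")
print(f"sensitivities: Sen_below median {summary['sen_below']['median']:.2f}, "
      f"Sen_above median {summary['sen_above']['median']:.2f} "
      f"(paired Wilcoxon p = {summary['wilcoxon']['p']:.2e})")

rows = pd.DataFrame(
    [{"site_id": s.site_id, "detected": r.detected, "smer_opt": r.smer_opt}
     for s, r in zip(network.sites, results)]
)
attr = attribute_drivers(network.covariates, rows, n_boot=500, seed=0)
print(f"\ndrivers explain {100 * attr.weights.total_r2:.0f}% of optimum variance")
print("top three relative weights (%):")
print(attr.weights.rescaled.sort_values(ascending=False).head(3).round(1).to_string())
fit = attr.site_fit
print(f"optimum ~ SM_growth slope: {fit.slope:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}; design value 0.86)")
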