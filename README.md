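# fluxresp

Boundary-line analysis of the ecosystem-respiration response to soil
moisture in half-hourly eddy-covariance records: response-curve
construction, detection of the apparent optimum soil moisture, side-specific
sensitivities, confounder controls, and cross-site attribution of where the
optimum sits.

## The problem

Ecosystem respiration (ER), the CO₂ flux from land to atmosphere, is usually
modelled as increasing monotonically with soil moisture (SM).  Flux-tower
records instead often show a *unimodal* response: ER rises with moisture up
to an apparent optimum (SM<sub>opt</sub>) and declines beyond it, as
progressive soil anoxia suppresses root and microbial respiration.  Locating
SM<sub>opt</sub> per site, quantifying how steeply ER falls off on either
side, and explaining why wetter sites operate at higher optima are the jobs
of this package.  It is written for ecosystem ecologists and carbon-cycle
modellers working with FLUXNET-style half-hourly site files.

## The method

Per site, on growing-season records with non-gap-filled night-time ER
(quality flag 0):

1. **Boundary line** — group (SM, ER) pairs into 0.05 % volumetric-water
   bins anchored at zero; in each bin take the 90 % empirical quantile of ER
   (outliers beyond the within-bin mean ± 2 SD removed first).  The upper
   quantile isolates the moisture response from other limiting factors.
2. **Smoothing** — running average over every 3 bins, then a penalized
   cubic B-spline smooth (a univariate GAM, penalty by generalized
   cross-validation) through the smoothed points.
3. **Detection** — SM<sub>opt</sub> is the SM at the unique interior maximum
   of the fitted curve, accepted only when OLS on the smoothed points shows
   a significantly increasing trend below it and a significantly decreasing
   trend above it (two-sided, α = 0.05, ≥ 3 points per side).  The absolute
   segment slopes are Sen<sub>below</sub> and Sen<sub>above</sub>
   (µmol m⁻² s⁻¹ per % SM).
4. **Controls** — partial Spearman correlation of SM and ER given
   radiation, air temperature and VPD, compared against the uncontrolled
   correlation across sites; and a random-forest ER model whose exact
   TreeSHAP soil-moisture attributions are pushed through the identical
   detection chain.
5. **Drivers** — across sites, relative weight analysis (Johnson's
   orthogonal-transformation variance partition) and standardized ridge
   regression with bootstrap CIs attribute SM<sub>opt</sub> variation to 12
   candidate climatic, edaphic and vegetation drivers, and OLS fits
   SM<sub>opt</sub> against growing-season moisture at site and biome level.

A first-class synthetic-data module generates single sites and multi-site
networks with known tent-shaped responses, controllable confounding and a
known cross-site law, so every stage is testable without downloads.

## Worked example

```bash
python examples/single_site_response.py
```

```
site: SYN-001, 20000 half-hourly records, SM range 5.0-45.0%
boundary curve: 798 smoothed bins, spline R2 = 0.877
detected: True
optimum soil moisture: 25.97%  (truth: 25.0%)
sensitivity below optimum: 0.293 umol m-2 s-1 per % (truth 0.30), p = 2.68e-229
sensitivity above optimum: 0.138 umol m-2 s-1 per % (truth 0.15), p = 1.12e-84
```

The generator placed the true optimum at 25 % SM with tent slopes
0.30/0.15; the pipeline recovers the optimum within one SM point and both
sensitivities within a few percent.  `examples/negative_control.py` shows a
site whose moisture range never reaches its optimum (correctly rejected
with reason `boundary_max`), `examples/confounder_controls.py` the partial
Spearman and SHAP re-detection, and `examples/network_drivers.py` a 25-site
network in which growing-season moisture carries ~80 % of the explained
variance in the optimum and the cross-site slope CI covers the design value
0.86.

## Command line

```bash
fluxresp simulate --out data/ --seed 1 --n-sites 20   # synthetic network
fluxresp detect data/                                  # per-site optima
fluxresp robustness data/                              # confounder controls
fluxresp drivers data/results/detection_results.csv data/covariates.csv
```

Per-site detection failures are findings (recorded with a reason code, exit
0); configuration and I/O problems exit nonzero.  Reading real FLUXNET-style
files needs only a column map in the YAML config (defaults cover the
standard `RECO_NT_VUT_REF` / `SWC_F_MDS_1` / … names).

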