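"""Robustness of optimum detection against radiation, temperature and VPD.

Two independent controls verify that an apparent ER-soil-moisture optimum is
not an artifact of co-varying heat and light:

* partial Spearman rank correlation between SM and ER controlling for
  incoming shortwave radiation, air temperature and VPD, compared site by
  site against the uncontrolled Spearman correlation (a network-level
  regression of one on the other should have slope ~1 when confounding is
  negligible);
* a random-forest regression of ER on all four drivers, with exact tree
  SHAP attributions isolating the soil-moisture contribution per record; the
  optimum is then re-detected on the SHAP response with the same
  boundary-line machinery used for the observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .curve import OptimumResult, ResponseCurve, curve_from_pairs, detect_optimum, site_pipeline
from .errors import CurveFitError, EmptySeriesError, SampleSizeError, UndefinedStatisticError
from .io import SiteSeries, filter_quality, growing_season_mask

logger = logging.getLogger(__name__)

SHAP_FEATURES = ("sm", "isr", "tair", "vpd")


@dataclass
class ShapAttribution:
    """Per-record exact TreeSHAP attributions of a forest ER model."""

    contributions: pd.DataFrame  # one column per feature
    baseline: float              # expected value; prediction = baseline + row sum
    prediction: np.ndarray
    sm_values: np.ndarray        # the SM feature values, aligned with rows

    @property
    def sm(self) -> np.ndarray:
        """SM attribution per record."""
        return self.contributions["sm"].to_numpy()


@dataclass
class RobustnessResult:
    """Per-site confounder-control summary."""

    site_id: str
    r_marginal: float
    r_partial: float
    smer_opt_obs: float
    detected_obs: bool
    smer_opt_shap: float
    detected_shap: bool


def partial_spearman(y, x, covariates=None) -> float:
    """Partial Spearman correlation of y and x controlling for covariates.

    All variables are rank-transformed (average ranks for ties); ranked y
    and ranked x are each regressed on the ranked covariates (with
    intercept) by least squares, and the Pearson correlation of the two
    residual series is returned.  With no covariates this reduces exactly
    to the ordinary Spearman correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if np.unique(y).size < 2 or np.unique(x).size < 2:
        raise UndefinedStatisticError("constant input column: correlation undefined")
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    if covariates is None or (np.size(covariates) == 0):
        return float(stats.pearsonr(ry, rx)[0])
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != y.size:
        Z = Z.T
    if Z.shape[0] != y.size:
        raise ValueError("covariate matrix does not match y length")
    if y.size <= Z.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")
    for j in range(Z.shape[1]):
        if np.unique(Z[:, j]).size < 2:
            raise UndefinedStatisticError(f"covariate column {j} is constant")
    RZ = np.column_stack([np.ones(y.size)] + [stats.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    res_y = ry - RZ @ np.linalg.lstsq(RZ, ry, rcond=None)[0]
    res_x = rx - RZ @ np.linalg.lstsq(RZ, rx, rcond=None)[0]
    return float(stats.pearsonr(res_y, res_x)[0])


@dataclass
class SlopeVsUnity:
    slope: float
    ci_low: float
    ci_high: float
    contains_one: bool
    intercept: float
    n: int


def slope_vs_unity(r_partial_sites, r_marginal_sites) -> SlopeVsUnity:
    """OLS of site-level partial on marginal correlations, with 95% slope CI.

    When the CI contains 1, controlling for the confounders leaves the
    SM-ER association essentially unchanged across the network.
    """
    import statsmodels.api as sm_api

    yp = np.asarray(r_partial_sites, dtype=float)
    xm = np.asarray(r_marginal_sites, dtype=float)
    if yp.size != xm.size or yp.size < 3:
        raise ValueError("need >= 3 paired site-level correlations")
    if np.ptp(xm) == 0:
        raise UndefinedStatisticError("marginal correlations have zero variance")
    model = sm_api.OLS(yp, sm_api.add_constant(xm)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return SlopeVsUnity(
        slope=float(model.params[1]), ci_low=float(lo), ci_high=float(hi),
        contains_one=bool(lo <= 1.0 <= hi), intercept=float(model.params[0]),
        n=int(yp.size),
    )


def shap_response(
    records: pd.DataFrame | SiteSeries,
    n_trees: int = 500,
    seed: int = 0,
    min_records: int = 100,
) -> ShapAttribution:
    """Fit a regression forest ER ~ (SM, ISR, Tair, VPD) and return exact
    per-record TreeSHAP attributions.

    The forest is LightGBM in random-forest mode (bagged trees, no
    boosting); attributions are the library's exact path-dependent TreeSHAP
    values, rescaled by the tree count because RF mode reports per-tree
    sums.  Additivity (baseline + attributions = prediction) holds to
    floating precision for every record.
    """
    import lightgbm as lgb

    d = records.data if isinstance(records, SiteSeries) else records
    cols = ["er", *SHAP_FEATURES]
    use = d[cols].dropna()
    if len(use) < min_records:
        raise SampleSizeError(
            f"forest needs >= {min_records} complete records, got {len(use)}"
        )
    X = use[list(SHAP_FEATURES)]
    y = use["er"].to_numpy()
    model = lgb.LGBMRegressor(
        boosting_type="rf",
        n_estimators=n_trees,
        bagging_fraction=0.8,
        bagging_freq=1,
        feature_fraction=0.9,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    contrib = np.asarray(model.predict(X, pred_contrib=True), dtype=float)
    contrib /= n_trees  # RF mode sums tree contributions instead of averaging
    pred = np.asarray(model.predict(X), dtype=float)
    return ShapAttribution(
        contributions=pd.DataFrame(contrib[:, :-1], columns=list(SHAP_FEATURES)),
        baseline=float(contrib[0, -1]),
        prediction=pred,
        sm_values=X["sm"].to_numpy(),
    )


def detect_optimum_shap(
    sm, shap_sm, config: PipelineConfig | None = None
) -> tuple[ResponseCurve | None, OptimumResult]:
    """Re-detect the optimum on the SHAP soil-moisture response.

    Runs the identical chain (binning, boundary quantile, running average,
    spline fit, two-sided trend validation) on (SM, SHAP value) pairs.
    """
    cfg = config or PipelineConfig()
    try:
        curve = curve_from_pairs(sm, shap_sm, cfg)
    except (EmptySeriesError, CurveFitError):
        return None, OptimumResult(False, reason="too_few_bins")
    return curve, detect_optimum(curve, alpha=cfg.alpha)


def site_robustness(
    series: SiteSeries,
    config: PipelineConfig | None = None,
    obs_result: OptimumResult | None = None,
) -> RobustnessResult:
    """Full per-site robustness check (partial Spearman + SHAP re-detection).

    ``obs_result`` can carry a previously computed observational detection
    to avoid re-running the pipeline.
    """
    cfg = config or PipelineConfig()
    if obs_result is None:
        _, obs_result = site_pipeline(series, cfg)
    clean = filter_quality(series)
    mask = growing_season_mask(
        clean, threshold_frac=cfg.gs_threshold_frac, smooth_days=cfg.gs_smooth_days
    )
    d = clean.data.loc[mask, ["er", *SHAP_FEATURES]].dropna()
    r_marg = partial_spearman(d["er"], d["sm"])
    r_part = partial_spearman(d["er"], d["sm"], d[["isr", "tair", "vpd"]].to_numpy())
    attr = shap_response(d, n_trees=cfg.n_trees, seed=cfg.seed)
    _, shap_res = detect_optimum_shap(attr.sm_values, attr.sm, cfg)
    return RobustnessResult(
        site_id=series.site_id,
        r_marginal=r_marg,
        r_partial=r_part,
        smer_opt_obs=obs_result.smer_opt,
        detected_obs=obs_result.detected,
        smer_opt_shap=shap_res.smer_opt,
        detected_shap=shap_res.detected,
    )
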