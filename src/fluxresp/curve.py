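"""Boundary-line ER-soil-moisture response curves and optimum detection.

The response of ecosystem respiration (ER) to soil moisture (SM) at a site
is characterised by boundary-line analysis: half-hourly (SM, ER) pairs are
grouped into narrow SM bins (default 0.05 volumetric %), the upper ER
quantile of each bin (default the 90th percentile) is taken as the response
under otherwise non-limiting conditions, a 3-bin running average smooths the
boundary, and a penalized-spline smooth (a univariate GAM) is fitted through
the smoothed points.

The apparent optimum soil moisture is the SM at the unique interior maximum
of the fitted curve, accepted only when ordinary least squares on the
smoothed points shows a significantly increasing trend below and a
significantly decreasing trend above the candidate.  The absolute segment
slopes are the side-specific sensitivities (Sen_below, Sen_above).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import CurveFitError, EmptySeriesError, InputError
from .io import SiteSeries, apply_outlier_screen, filter_quality, growing_season_mask

logger = logging.getLogger(__name__)

#: Reason codes reported when detection fails.
REASONS = (
    "boundary_max",
    "nonsig_below",
    "nonsig_above",
    "too_few_points",
    "multiple_maxima",
    "too_few_bins",
    "empty_after_quality",
    "empty_after_season",
    "empty_after_outliers",
    "no_bins",
)

# Guard against float rounding at bin edges: 10.0/0.05 evaluates to
# 199.999...97, which floor() would put in the wrong bin.
_EDGE_EPS = 1e-9


@dataclass
class ResponseCurve:
    """Smoothed boundary points with the spline fit through them."""

    points: pd.DataFrame  # columns sm_center, er_boundary, n_obs
    gam_fitted: np.ndarray
    gam_r2: float
    bin_width: float = 0.05
    quantile: float = 0.90
    window: int = 3
    penalty: float = float("nan")

    @property
    def sm(self) -> np.ndarray:
        return self.points["sm_center"].to_numpy()

    @property
    def er(self) -> np.ndarray:
        return self.points["er_boundary"].to_numpy()


@dataclass
class OptimumResult:
    """Outcome of optimum detection at one site."""

    detected: bool
    reason: str | None = None
    smer_opt: float = float("nan")
    sen_below: float = float("nan")
    sen_above: float = float("nan")
    p_below: float = float("nan")
    p_above: float = float("nan")
    n_below: int = 0
    n_above: int = 0
    gam_r2: float = float("nan")
    site_id: str | None = None

    def as_row(self) -> dict:
        return {
            "site_id": self.site_id,
            "detected": self.detected,
            "reason": self.reason,
            "smer_opt": self.smer_opt,
            "sen_below": self.sen_below,
            "sen_above": self.sen_above,
            "p_below": self.p_below,
            "p_above": self.p_above,
            "gam_r2": self.gam_r2,
            "n_below": self.n_below,
            "n_above": self.n_above,
        }


def bin_and_boundary(
    sm, er, bin_width: float = 0.05, quantile: float = 0.90,
    screen_k: float | None = None,
) -> pd.DataFrame:
    """Bin (SM, ER) pairs and take the within-bin upper ER quantile.

    Bins are half-open intervals ``[k*w, (k+1)*w)`` anchored at SM = 0 with
    centres at ``(k + 0.5)*w``; empty bins are omitted.  The boundary value
    is the empirical quantile with linear interpolation between order
    statistics (numpy's default definition).

    ``screen_k`` switches on within-bin outlier screening: ER values outside
    the bin mean +/- ``screen_k`` SD are dropped before the quantile (bins
    with < 3 records, or zero SD, are left untouched).  Screening per bin
    rather than globally keeps the boundary statistic scale-equivariant: a
    global threshold on a flux whose magnitude varies with soil moisture
    preferentially deletes valid high-flux records near the response peak.

    Returns a DataFrame with columns ``sm_center, er_boundary, n_obs``
    ordered by increasing centre; empty when no finite pair exists.
    ``n_obs`` counts the records the quantile was computed from.
    """
    if bin_width <= 0:
        raise InputError(f"bin_width must be positive, got {bin_width}")
    if not 0 < quantile < 1:
        raise InputError(f"quantile must be in (0,1), got {quantile}")
    sm = np.asarray(sm, dtype=float)
    er = np.asarray(er, dtype=float)
    if sm.shape != er.shape:
        raise InputError("sm and er must have equal length")
    ok = np.isfinite(sm) & np.isfinite(er)
    if not ok.any():
        return pd.DataFrame(columns=["sm_center", "er_boundary", "n_obs"])
    sm, er = sm[ok], er[ok]
    idx = np.floor(sm / bin_width + _EDGE_EPS).astype(np.int64)
    frame = pd.DataFrame({"k": idx, "er": er})
    if screen_k is not None:
        g = frame.groupby("k")["er"]
        mu = g.transform("mean")
        sd = g.transform("std").fillna(0.0)
        n = g.transform("size")
        keep = (n < 3) | (sd == 0) | ((frame["er"] - mu).abs() <= screen_k * sd)
        frame = frame.loc[keep]
    grouped = frame.groupby("k", sort=True)["er"]
    out = pd.DataFrame(
        {
            "sm_center": (grouped.size().index.to_numpy() + 0.5) * bin_width,
            "er_boundary": grouped.quantile(quantile).to_numpy(),
            "n_obs": grouped.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def running_average(points: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Centred running mean of the boundary points over ``window`` bins.

    Both the SM centre and the boundary ER are averaged; ``n_obs`` is the
    total count inside the window.  Output length is ``n - window + 1``;
    an input shorter than the window yields an empty frame with a warning
    (the site cannot support detection).
    """
    if window < 1 or window % 2 == 0:
        raise InputError(f"window must be a positive odd integer, got {window}")
    n = len(points)
    if n < window:
        logger.warning("running_average: %d points < window %d, curve dropped", n, window)
        return points.iloc[0:0].copy()
    if window == 1:
        return points.reset_index(drop=True).copy()
    roll = points[["sm_center", "er_boundary"]].rolling(window, center=True).mean()
    out = roll.dropna().reset_index(drop=True)
    out["n_obs"] = (
        points["n_obs"].rolling(window, center=True).sum().dropna().to_numpy().astype(int)
    )
    return out


def fit_gam(
    points: pd.DataFrame,
    basis_df: int = 10,
    bin_width: float = 0.05,
    quantile: float = 0.90,
    window: int = 3,
) -> ResponseCurve:
    """Fit a penalized B-spline smooth of boundary ER on SM centre.

    One univariate cubic regression-spline smooth with basis dimension
    ``min(basis_df, n - 1)`` and penalty weight selected by generalized
    cross-validation over a logarithmic grid.  ``gam_r2`` is the in-sample
    coefficient of determination on the smoothed points (0 when the points
    are constant).

    Raises :class:`CurveFitError` for fewer than 8 points.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    n = len(points)
    if n < 8:
        raise CurveFitError(f"need >= 8 boundary points for the smooth, got {n}")
    x = points["sm_center"].to_numpy(dtype=float)
    y = points["er_boundary"].to_numpy(dtype=float)
    if np.ptp(y) == 0:  # constant boundary: flat fit, nothing to smooth
        return ResponseCurve(
            points=points.reset_index(drop=True), gam_fitted=y.copy(), gam_r2=0.0,
            bin_width=bin_width, quantile=quantile, window=window, penalty=float("nan"),
        )
    df = int(min(basis_df, n - 1))
    df = max(df, 4)  # cubic spline needs at least degree+1 basis functions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        basis = BSplines(x[:, None], df=[df], degree=[3], include_intercept=True)
        grid = np.logspace(-4, 7, 23)
        model = GLMGam(y, smoother=basis, alpha=1.0)
        model.fit()  # populates scale; required before penalty selection
        try:
            alpha_opt = float(np.atleast_1d(model.select_penweight(criterion="gcv", alphas=[grid])[0])[0])
        except Exception:  # degenerate designs: fall back to a mild penalty
            alpha_opt = 1.0
        res = GLMGam(y, smoother=basis, alpha=alpha_opt).fit()
    fitted = np.asarray(res.fittedvalues, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / sst
    r2 = float(min(max(r2, 0.0), 1.0))
    return ResponseCurve(
        points=points.reset_index(drop=True),
        gam_fitted=fitted,
        gam_r2=r2,
        bin_width=bin_width,
        quantile=quantile,
        window=window,
        penalty=alpha_opt,
    )


def _segment_trend(sm: np.ndarray, er: np.ndarray) -> tuple[float, float]:
    """OLS slope and two-sided p-value of boundary ER on SM."""
    fit = stats.linregress(sm, er)
    return float(fit.slope), float(fit.pvalue)


def detect_optimum(curve: ResponseCurve, alpha: float = 0.05) -> OptimumResult:
    """Locate and validate the apparent optimum soil moisture on a curve.

    The candidate is the SM centre at the unique maximum of the fitted
    spline (adjacent exact ties collapse to their midpoint; non-adjacent
    ties abort with ``multiple_maxima``).  Detection succeeds only when the
    candidate is strictly interior, each side holds at least 3 smoothed
    points (the optimum point belongs to both sides), and OLS on the
    smoothed points shows slope > 0 with p <= alpha below and slope < 0
    with p <= alpha above.
    """
    f = np.asarray(curve.gam_fitted, dtype=float)
    sm = curve.sm
    er = curve.er
    n = len(f)
    if n < 3:
        return OptimumResult(False, reason="too_few_bins", gam_r2=curve.gam_r2)
    tied = np.flatnonzero(f == f.max())
    i0, i1 = int(tied[0]), int(tied[-1])
    if len(tied) > 1 and not np.array_equal(tied, np.arange(i0, i1 + 1)):
        return OptimumResult(False, reason="multiple_maxima", gam_r2=curve.gam_r2)
    if i0 == 0 or i1 == n - 1:
        return OptimumResult(False, reason="boundary_max", gam_r2=curve.gam_r2)
    smer_opt = float((sm[i0] + sm[i1]) / 2.0)
    n_below = i0 + 1
    n_above = n - i1
    if n_below < 3 or n_above < 3:
        return OptimumResult(
            False, reason="too_few_points", smer_opt=smer_opt,
            n_below=n_below, n_above=n_above, gam_r2=curve.gam_r2,
        )
    slope_b, p_b = _segment_trend(sm[: i0 + 1], er[: i0 + 1])
    slope_a, p_a = _segment_trend(sm[i1:], er[i1:])
    base = dict(
        smer_opt=smer_opt, sen_below=abs(slope_b), sen_above=abs(slope_a),
        p_below=p_b, p_above=p_a, n_below=n_below, n_above=n_above,
        gam_r2=curve.gam_r2,
    )
    if not (slope_b > 0 and p_b <= alpha):
        return OptimumResult(False, reason="nonsig_below", **base)
    if not (slope_a < 0 and p_a <= alpha):
        return OptimumResult(False, reason="nonsig_above", **base)
    return OptimumResult(True, reason=None, **base)


def curve_from_pairs(
    sm, er, config: PipelineConfig | None = None, min_bin_n: int | None = None
) -> ResponseCurve:
    """Boundary -> running average -> spline on raw (SM, response) pairs.

    The shared tail of the pipeline, reused both for observational ER and
    for SHAP-attribution responses.  ``min_bin_n`` (default from config)
    drops bins supported by fewer records before smoothing.
    """
    cfg = config or PipelineConfig()
    if min_bin_n is None:
        min_bin_n = cfg.min_bin_n
    pts = bin_and_boundary(
        sm, er, bin_width=cfg.bin_width, quantile=cfg.quantile, screen_k=cfg.outlier_k
    )
    if min_bin_n > 1 and len(pts):
        pts = pts[pts["n_obs"] >= min_bin_n].reset_index(drop=True)
    if not len(pts):
        raise EmptySeriesError("no populated soil-moisture bins")
    smoothed = running_average(pts, window=cfg.window)
    if not len(smoothed):
        raise CurveFitError("fewer boundary bins than the smoothing window")
    return fit_gam(
        smoothed, basis_df=cfg.gam_df,
        bin_width=cfg.bin_width, quantile=cfg.quantile, window=cfg.window,
    )


def site_pipeline(
    series: SiteSeries,
    config: PipelineConfig | None = None,
    day_range: tuple[int, int] | None = None,
) -> tuple[ResponseCurve | None, OptimumResult]:
    """Full per-site chain: quality filter, growing season, outlier screen,
    boundary curve, spline fit, optimum detection.

    Detection failure at any stage is a data outcome, returned as a
    not-detected :class:`OptimumResult` carrying the stage or reason code;
    only malformed inputs raise.
    """
    cfg = config or PipelineConfig()
    sid = series.site_id
    try:
        clean = filter_quality(series)
    except EmptySeriesError:
        return None, OptimumResult(False, reason="empty_after_quality", site_id=sid)
    mask = growing_season_mask(
        clean, threshold_frac=cfg.gs_threshold_frac,
        smooth_days=cfg.gs_smooth_days, day_range=day_range,
    )
    if not mask.any():
        return None, OptimumResult(False, reason="empty_after_season", site_id=sid)
    seasonal = clean.with_data(clean.data.loc[mask])
    try:
        # SM is screened globally here; ER is screened within each bin by
        # curve_from_pairs (see bin_and_boundary on scale-equivariance).
        screened = apply_outlier_screen(seasonal, k=cfg.outlier_k, fields=("sm",))
    except (EmptySeriesError, InputError):
        return None, OptimumResult(False, reason="empty_after_outliers", site_id=sid)
    try:
        curve = curve_from_pairs(screened.data["sm"], screened.data["er"], cfg)
    except EmptySeriesError:
        return None, OptimumResult(False, reason="no_bins", site_id=sid)
    except CurveFitError:
        return None, OptimumResult(False, reason="too_few_bins", site_id=sid)
    result = detect_optimum(curve, alpha=cfg.alpha)
    result.site_id = sid
    return curve, result
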