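"""Synthetic half-hourly flux sites and multi-site networks with known truth.

The generator emulates the statistical structure the response-curve analysis
assumes: a bounded soil-moisture series with seasonal and AR(1) structure, an
ER response that rises to a peak at a known optimum and declines beyond it
(a piecewise-linear "tent", so the side slopes have exact generator values),
multiplicative temperature (Q10) and lognormal noise, meteorological
confounders with a controllable correlation to soil moisture, and a known
linear cross-site law linking each site's optimum to its growing-season
moisture.

A deliberate normalisation: the stochastic multiplier (Q10 term x lognormal
noise) is scaled so that its 90th percentile equals 1.  The within-bin 90%
quantile used by boundary-line analysis then targets the tent itself, making
the configured optimum and slopes the exact ground truth of the boundary
line rather than of the conditional median.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .errors import InfeasibleConfoundError, InputError
from .io import DEFAULT_COLUMN_MAP, IGBP_CLASSES, MISSING_SENTINEL, SiteSeries, growing_season_mask

logger = logging.getLogger(__name__)

_SECONDS_PER_DAY = 86400.0


@dataclass
class SyntheticSiteConfig:
    """Generator settings for a single site.

    Soil moisture is a clipped seasonal sinusoid plus stationary AR(1)
    noise; ER is ``tent(SM) * Q10^((Tair - t_ref)/10) * lognormal`` with the
    multiplier normalised to unit 90th percentile (see module docstring).
    ``confound_r`` is the target correlation between soil moisture and each
    meteorological confounder (0 = confounder-free, the default network).
    """

    n_records: int = 20_000
    sm_mean: float = 25.0          # volumetric %, centre of the site's wet-dry range
    sm_span: float = 40.0          # % width of the wet-dry range the site visits
    sm_seasonal_amp: float = 5.0   # latent weight of the seasonal cycle
    sm_ar1: float = 0.95           # lag-1 autocorrelation at half-hour steps
    sm_noise_sd: float = 8.0       # latent weight of the AR(1) component
    # Moisture peaks in early spring, a quarter cycle before the radiation
    # peak (day 172): the seasonal component then averages to ~zero over the
    # GPP-defined growing season, so the realized growing-season moisture
    # mean (the SM_growth covariate) equals the site's range centre.
    sm_phase_doy: float = 81.0     # day of year of the seasonal moisture peak
    true_opt: float = 25.0         # % SM at the ER peak
    er_max: float = 8.0            # umol m-2 s-1 at the peak
    slope_below: float = 0.30      # umol m-2 s-1 per % below the optimum
    slope_above: float = 0.15      # umol m-2 s-1 per % above the optimum
    q10: float = 2.0               # temperature sensitivity of ER
    t_ref: float = 15.0            # degC reference for the Q10 term
    noise_sd_log: float = 0.3      # SD of the lognormal noise (log scale)
    confound_r: float = 0.0        # target corr(SM, confounder)
    gpp_max: float = 25.0          # umol m-2 s-1 light-saturated GPP
    start: str = "2010-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InputError("n_records must be >= 1")
        if not 0 <= self.sm_ar1 < 1:
            raise InputError(f"sm_ar1 must be in [0,1), got {self.sm_ar1}")
        if self.slope_below < 0 or self.slope_above < 0:
            raise InputError("tent slopes must be >= 0")
        if not -1 < self.confound_r < 1:
            raise InputError(f"confound_r must be in (-1,1), got {self.confound_r}")


@dataclass
class NetworkConfig:
    """Generator settings for a multi-site network.

    Site optima follow ``true_opt = cross_intercept + cross_slope *
    sm_growth_target + N(0, site_scatter_sd)`` with per-site growing-season
    moisture targets drawn uniformly from ``sm_growth_range``.
    """

    n_sites: int = 100
    sm_growth_range: tuple[float, float] = (12.0, 35.0)
    cross_slope: float = 0.86
    cross_intercept: float = 3.0
    site_scatter_sd: float = 3.0
    site_template: SyntheticSiteConfig = field(default_factory=SyntheticSiteConfig)
    seed: int = 0


@dataclass
class NetworkResult:
    """Sites plus the covariate and ground-truth tables of one network."""

    sites: list
    covariates: pd.DataFrame
    truth: pd.DataFrame
    metadata: pd.DataFrame


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary zero-mean AR(1) series of length n with marginal SD sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], innov)


def _mix_weight(target_r: float, extra_var: float, stoch_sd: float) -> float:
    """Latent mixing weight giving corr(target) on a series whose variance is
    stoch_sd^2 plus an SM-independent component of variance extra_var."""
    if target_r == 0:
        return 0.0
    rho = target_r * np.sqrt(stoch_sd**2 + extra_var) / stoch_sd
    if abs(rho) > 1:
        raise InfeasibleConfoundError(
            f"confound_r={target_r} unreachable: deterministic variance "
            f"{extra_var:.1f} dilutes the stochastic channel (sd {stoch_sd:.1f})"
        )
    return float(rho)


def _environment(cfg: SyntheticSiteConfig, rng: np.random.Generator):
    """Timestamps, soil moisture and the three meteorological confounders."""
    # Records are strided so any site spans at least one full annual cycle:
    # a small n then mimics the temporal sparseness of quality-filtered flux
    # records rather than truncating the year (which would alias the
    # seasonal moisture cycle into the growing-season means).
    step = max(1, int(np.ceil(365.25 * 48 / cfg.n_records)))
    ts = pd.date_range(cfg.start, periods=cfg.n_records, freq=f"{30 * step}min")
    hfrac = (ts.hour + ts.minute / 60.0).to_numpy() / 24.0
    doy = ts.dayofyear.to_numpy() + hfrac

    # Soil moisture: seasonal + AR(1) latent dynamics mapped rank-preservingly
    # onto the site's bounded wet-dry range.  The probability-integral map
    # gives a near-uniform marginal, so 0.05%-wide bins are evenly occupied
    # across the range (uneven occupancy would tilt the upper-quantile
    # boundary through small-sample quantile bias).
    season = np.cos(2 * np.pi * (doy - cfg.sm_phase_doy) / 365.25)
    latent = cfg.sm_seasonal_amp * season + _ar1(rng, cfg.n_records, cfg.sm_ar1, cfg.sm_noise_sd)
    latent_sd = np.sqrt(cfg.sm_seasonal_amp**2 / 2.0 + cfg.sm_noise_sd**2)
    half = min(cfg.sm_span / 2.0, cfg.sm_mean - 0.1, 99.9 - cfg.sm_mean)
    sm = cfg.sm_mean + half * (2.0 * norm.cdf(latent / max(latent_sd, 1e-12)) - 1.0)
    sm = np.clip(sm, 0.1, 99.9)
    z_sm = (sm - sm.mean()) / max(sm.std(), 1e-12)

    # Air temperature: diurnal cycle + fast synoptic noise partially coupled
    # to SM.  Deliberately no deterministic seasonal term: any slow
    # temperature component phase-locks with the seasonal moisture cycle
    # within the growing season and would tilt the boundary line outside the
    # explicit confound_r coupling, which is the only intended SM-T channel.
    t_diurnal_amp, t_sd, t_mean = 5.0, 4.0, 12.0
    rho_t = _mix_weight(cfg.confound_r, t_diurnal_amp**2 / 2.0, t_sd)
    # Short temperature memory (hours): records falling in one narrow SM bin
    # then sample many independent weather states, so the within-bin upper
    # quantile has near-independent errors across bins.
    mix_t = rho_t * z_sm + np.sqrt(1 - rho_t**2) * _ar1(rng, cfg.n_records, 0.6, 1.0)
    tair = t_mean - t_diurnal_amp * np.cos(2 * np.pi * hfrac) + t_sd * mix_t

    # Shortwave radiation: clear-sky day-length/solar cycle times a cloudiness
    # factor; the SM coupling acts on the cloudiness driver (the day-night
    # cycle makes an arbitrary whole-series correlation unreachable).
    daylight = np.maximum(0.0, np.sin(np.pi * (hfrac * 24.0 - 6.0) / 12.0))
    season_sun = 0.65 + 0.35 * np.cos(2 * np.pi * (doy - 172.0) / 365.25)
    z_cloud = cfg.confound_r * z_sm + np.sqrt(1 - cfg.confound_r**2) * _ar1(
        rng, cfg.n_records, 0.9, 1.0
    )
    cloud = 0.35 + 0.65 * norm.cdf(z_cloud)
    isr = 800.0 * daylight * season_sun * cloud

    # VPD: diurnal cycle + coupled stochastic part, floored at 0.1 hPa.
    v_diurnal_amp, v_sd, v_mean = 3.0, 3.5, 8.0
    rho_v = _mix_weight(cfg.confound_r, v_diurnal_amp**2 / 2.0, v_sd)
    mix_v = rho_v * z_sm + np.sqrt(1 - rho_v**2) * _ar1(rng, cfg.n_records, 0.95, 1.0)
    vpd = np.maximum(0.1, v_mean - v_diurnal_amp * np.cos(2 * np.pi * hfrac) + v_sd * mix_v)

    gpp = cfg.gpp_max * (1.0 - np.exp(-isr / 250.0))
    gpp = np.maximum(0.0, gpp * (1.0 + 0.1 * rng.normal(size=cfg.n_records)))

    achieved = {
        "corr_sm_tair": float(np.corrcoef(sm, tair)[0, 1]),
        "corr_sm_vpd": float(np.corrcoef(sm, vpd)[0, 1]),
        "corr_sm_isr": float(np.corrcoef(sm, isr)[0, 1]),
        "corr_sm_cloud_driver": float(np.corrcoef(sm, z_cloud)[0, 1]),
    }
    return ts, sm, tair, isr, vpd, gpp, achieved


def tent_response(sm, true_opt: float, er_max: float, slope_below: float, slope_above: float):
    """Piecewise-linear unimodal ER response, floored at zero."""
    sm = np.asarray(sm, dtype=float)
    below = np.maximum(true_opt - sm, 0.0)
    above = np.maximum(sm - true_opt, 0.0)
    return np.maximum(0.0, er_max - slope_below * below - slope_above * above)


def _er_series(
    cfg: SyntheticSiteConfig, rng: np.random.Generator, sm, tair, true_opt: float,
    slope_above: float | None = None,
) -> np.ndarray:
    sa = cfg.slope_above if slope_above is None else slope_above
    tent = tent_response(sm, true_opt, cfg.er_max, cfg.slope_below, sa)
    mult = cfg.q10 ** ((tair - cfg.t_ref) / 10.0) * np.exp(
        rng.normal(0.0, cfg.noise_sd_log, size=len(sm))
    )
    # Normalize so the 90th percentile of the multiplier AFTER a 2-SD
    # within-scale screen equals 1.  The analysis screens each bin's ER at
    # bin-mean +/- 2 SD before taking the 90% quantile; because that screen is
    # scale-equivariant, the same clip applies to the multiplier in every bin
    # and the configured tent becomes the exact infinite-data boundary of the
    # post-screen data.
    inside = np.abs(mult - mult.mean()) <= 2.0 * mult.std()
    mult = mult / np.quantile(mult[inside], 0.90)
    return tent * mult


def _assemble(cfg, ts, sm, er, gpp, isr, tair, vpd, site_id: str, igbp: str | None):
    data = pd.DataFrame(
        {
            "timestamp": ts,
            "er": er,
            "er_qc": 0,
            "sm": sm,
            "gpp": gpp,
            "isr": isr,
            "tair": tair,
            "vpd": vpd,
        }
    )
    return SiteSeries(site_id=site_id, data=data, igbp=igbp)


def generate_site(
    cfg: SyntheticSiteConfig, site_id: str = "SYN-001", igbp: str | None = None
) -> tuple[SiteSeries, dict]:
    """Generate one unimodal-response site and its ground-truth record.

    Raises :class:`InputError` when the configured optimum falls outside the
    soil-moisture range the site actually visits (no interior peak would be
    observable), and :class:`InfeasibleConfoundError` when ``confound_r``
    cannot be realised.
    """
    rng = np.random.default_rng(cfg.seed)
    ts, sm, tair, isr, vpd, gpp, achieved = _environment(cfg, rng)
    if not sm.min() + 0.5 < cfg.true_opt < sm.max() - 0.5:
        raise InputError(
            f"true_opt {cfg.true_opt} outside generated SM range "
            f"[{sm.min():.1f}, {sm.max():.1f}]"
        )
    er = _er_series(cfg, rng, sm, tair, cfg.true_opt)
    series = _assemble(cfg, ts, sm, er, gpp, isr, tair, vpd, site_id, igbp)
    truth = {
        "site_id": site_id,
        "mode": "unimodal",
        **asdict(cfg),
        "sm_min": float(sm.min()),
        "sm_max": float(sm.max()),
        **achieved,
    }
    return series, truth


def generate_monotone_site(
    cfg: SyntheticSiteConfig,
    mode: str = "truncated",
    site_id: str = "SYN-M01",
    igbp: str | None = None,
) -> tuple[SiteSeries, dict]:
    """Generate a negative-control site with no detectable interior optimum.

    ``mode="truncated"`` places the tent apex above the soil-moisture range
    the site visits (the site never gets wet enough to pass its optimum), so
    the response is monotone increasing; ``mode="plateau"`` keeps the apex
    interior but sets the above-optimum slope to zero, so no declining trend
    exists.  The truth record marks the absent interior optimum with NaN.
    """
    rng = np.random.default_rng(cfg.seed)
    ts, sm, tair, isr, vpd, gpp, achieved = _environment(cfg, rng)
    if mode == "truncated":
        opt_eff = float(sm.max()) + 5.0
        er = _er_series(cfg, rng, sm, tair, opt_eff)
    elif mode == "plateau":
        opt_eff = cfg.true_opt
        er = _er_series(cfg, rng, sm, tair, opt_eff, slope_above=0.0)
    else:
        raise InputError(f"unknown monotone mode {mode!r}")
    series = _assemble(cfg, ts, sm, er, gpp, isr, tair, vpd, site_id, igbp)
    truth = {
        "site_id": site_id,
        "mode": mode,
        **asdict(cfg),
        "true_opt": float("nan"),
        "tent_apex": opt_eff,
        "sm_min": float(sm.min()),
        "sm_max": float(sm.max()),
        **achieved,
    }
    return series, truth


def _growing_season_sm(series: SiteSeries) -> dict:
    """Realized growing-season means of SM and the confounders."""
    mask = growing_season_mask(series)
    d = series.data.loc[mask]
    return {
        "sm_growth": float(d["sm"].mean()),
        "tem": float(d["tair"].mean()),
        "isr": float(d["isr"].mean()),
        "vpd": float(d["vpd"].mean()),
    }


def generate_network(net: NetworkConfig) -> NetworkResult:
    """Generate a multi-site network following the configured cross-site law.

    Per-site growing-season moisture targets are drawn uniformly; each true
    optimum follows the linear law plus Gaussian scatter.  When a drawn
    optimum is infeasible for the site's moisture range, the site's AR(1)
    noise SD is widened (logged) until the optimum is interior.  Drivers
    other than the realized moisture/meteorology means are independent noise
    unless the template couples them via ``confound_r``.
    """
    rng = np.random.default_rng(net.seed)
    lo, hi = net.sm_growth_range
    sites: list[SiteSeries] = []
    truth_rows, cov_rows, meta_rows = [], [], []
    for i in range(net.n_sites):
        sid = f"SYN-{i + 1:03d}"
        igbp = IGBP_CLASSES[i % len(IGBP_CLASSES)]
        sm_target = float(rng.uniform(lo, hi))
        true_opt = float(
            net.cross_intercept + net.cross_slope * sm_target
            + rng.normal(0.0, net.site_scatter_sd)
        )
        site_seed = int(rng.integers(2**31))
        cfg = replace(net.site_template, sm_mean=sm_target, true_opt=true_opt, seed=site_seed)
        for attempt in range(5):
            half_range = min(cfg.sm_span / 2.0, sm_target - 0.1, 99.9 - sm_target)
            if abs(true_opt - sm_target) < half_range - 2.0:
                break
            cfg = replace(cfg, sm_span=cfg.sm_span * 1.3)
            logger.info("%s: widened sm_span to %.1f for optimum %.1f",
                        sid, cfg.sm_span, true_opt)
        series, truth = generate_site(cfg, site_id=sid, igbp=igbp)
        truth["sm_growth_target"] = sm_target
        sites.append(series)
        truth_rows.append(truth)
        realized = _growing_season_sm(series)
        cov_rows.append(
            {
                "site_id": sid,
                "igbp": igbp,
                **realized,
                "st": realized["tem"] - 2.0 + rng.normal(0.0, 0.8),
                "pre": float(rng.uniform(300.0, 1500.0)),
                "lai": float(rng.uniform(0.5, 6.0)),
                "bd": float(rng.uniform(0.9, 1.6)),
                "soc": float(rng.uniform(0.5, 8.0)),
                "cec": float(rng.uniform(5.0, 40.0)),
                "ph": float(rng.uniform(4.5, 8.5)),
                "sand": float(rng.uniform(10.0, 90.0)),
            }
        )
        meta_rows.append({"site_id": sid, "igbp": igbp, "lat": float(rng.uniform(-40, 70)),
                          "lon": float(rng.uniform(-120, 150))})
    return NetworkResult(
        sites=sites,
        covariates=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
        metadata=pd.DataFrame(meta_rows),
    )


# ---------------------------------------------------------------------------
# FLUXNET-dialect output

_INV_MAP = {field: col for field, col in DEFAULT_COLUMN_MAP.items()}


def write_site_csv(series: SiteSeries, path) -> None:
    """Write a site in the same CSV dialect :mod:`fluxresp.io` reads."""
    d = series.data
    out = pd.DataFrame()
    out[_INV_MAP["timestamp"]] = d["timestamp"].dt.strftime("%Y%m%d%H%M")
    for fld in ("er", "er_qc", "sm", "gpp", "isr", "tair", "vpd"):
        col = d[fld].astype(float).round(6)
        out[_INV_MAP[fld]] = col.fillna(MISSING_SENTINEL)
    out[_INV_MAP["er_qc"]] = out[_INV_MAP["er_qc"]].astype(int)
    out.to_csv(path, index=False)


def write_network(net_result: NetworkResult, outdir, seed: int | None = None,
                  force: bool = False) -> dict:
    """Write a generated network (site CSVs, metadata, covariates, truth).

    Refuses a non-empty output directory unless ``force``; returns the
    manifest (also written as ``manifest.json``) listing files, seed and
    per-file checksums so reruns can be verified byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name != "manifest.json"]
    if existing and not force:
        raise InputError(f"{outdir} is not empty; pass force=True to overwrite")
    files = []
    for series in net_result.sites:
        fname = f"{series.site_id}.csv"
        write_site_csv(series, outdir / fname)
        files.append(fname)
    net_result.metadata.to_csv(outdir / "site_metadata.csv", index=False)
    net_result.covariates.to_csv(outdir / "covariates.csv", index=False)
    net_result.truth.to_csv(outdir / "truth.csv", index=False)
    files += ["site_metadata.csv", "covariates.csv", "truth.csv"]
    manifest = {
        "n_sites": len(net_result.sites),
        "seed": seed,
        "files": files,
        "sha256": {
            f: hashlib.sha256((outdir / f).read_bytes()).hexdigest() for f in files
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
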