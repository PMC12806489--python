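"""Reading and filtering FLUXNET-style half-hourly site files.

A site file is a wide CSV with one row per half hour, a ``TIMESTAMP_START``
column in YYYYMMDDHHMM form and the sentinel -9999 for missing values.  The
semantic fields (ER, its QC flag, soil moisture, GPP, radiation, air
temperature, VPD) are located through a remappable column map so that any
FLUXNET dialect can be ingested.

Filtering follows the analysis chain: keep only original (non-gap-filled)
night-time-partitioned ER (QC flag 0) with a concurrent soil-moisture value,
restrict to the GPP-defined growing season, and screen extremes at
mean +/- k standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DEFAULT_COLUMN_MAP
from .errors import ConfigurationError, EmptySeriesError, InputError

logger = logging.getLogger(__name__)

MISSING_SENTINEL = -9999
IGBP_CLASSES = ("CRO", "CSH", "DBF", "EBF", "ENF", "GRA", "MF", "OSH", "SAV", "WSA")

#: Internal record columns, in canonical order.
RECORD_FIELDS = ("timestamp", "er", "er_qc", "sm", "gpp", "isr", "tair", "vpd")


@dataclass
class SiteSeries:
    """Half-hourly records of one flux site plus its metadata.

    ``data`` holds one row per half hour with the canonical columns
    ``timestamp, er, er_qc, sm, gpp, isr, tair, vpd`` (site-local time,
    missing values as NaN).
    """

    site_id: str
    data: pd.DataFrame
    igbp: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.igbp is not None and self.igbp not in IGBP_CLASSES:
            raise InputError(f"{self.site_id}: unknown IGBP class {self.igbp!r}")
        missing = [c for c in RECORD_FIELDS if c not in self.data.columns]
        if missing:
            raise InputError(f"{self.site_id}: data lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame) -> "SiteSeries":
        return replace(self, data=data.reset_index(drop=True))


def read_site_csv(
    path,
    column_map: dict[str, str] | None = None,
    site_id: str | None = None,
    igbp: str | None = None,
    latitude: float | None = None,
    longitude: float | None = None,
) -> SiteSeries:
    """Read one half-hourly site CSV into a :class:`SiteSeries`.

    Parameters
    ----------
    path : path-like
        CSV file, one row per half hour.
    column_map : dict, optional
        Mapping semantic field -> file column name; defaults to the
        FLUXNET2015 names (``RECO_NT_VUT_REF`` etc.).  ``er_qc``, ``gpp``,
        ``isr``, ``tair`` and ``vpd`` may be absent from the file, in which
        case they are filled with NaN (``er_qc`` with 0 is *not* assumed).

    Raises
    ------
    ConfigurationError
        A mandatory mapped column (timestamp, er, sm) is absent.
    InputError
        A timestamp cannot be parsed.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path)
    for field in ("timestamp", "er", "sm"):
        if cmap[field] not in frame.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {cmap[field]!r} (field {field!r}) not found"
            )
    out = pd.DataFrame()
    ts_raw = frame[cmap["timestamp"]]
    ts = pd.to_datetime(ts_raw.astype(str), format="%Y%m%d%H%M", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise InputError(
            f"{path}: unparseable timestamp {ts_raw.iloc[row]!r} at row {row}"
        )
    out["timestamp"] = ts
    for field in RECORD_FIELDS[1:]:
        col = cmap[field]
        if col in frame.columns:
            vals = pd.to_numeric(frame[col], errors="coerce")
            vals = vals.mask(vals == MISSING_SENTINEL)
            vals = vals.mask(~np.isfinite(vals.to_numpy(dtype=float)))
            out[field] = vals.astype(float)
        else:
            out[field] = np.nan
    out = out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    sid = site_id or str(path)
    return SiteSeries(site_id=sid, data=out, igbp=igbp, latitude=latitude, longitude=longitude)


def read_site_metadata(path) -> pd.DataFrame:
    """Read the per-site metadata table (site_id, igbp, lat, lon)."""
    meta = pd.read_csv(path)
    required = {"site_id", "igbp", "lat", "lon"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigurationError(f"{path}: metadata lacks columns {sorted(missing)}")
    return meta


def filter_quality(series: SiteSeries) -> SiteSeries:
    """Keep only records with ER QC flag 0 and both ER and SM present.

    Raises :class:`EmptySeriesError` when nothing survives (the site is
    then skipped downstream and logged, not treated as a crash).
    """
    d = series.data
    keep = (d["er_qc"] == 0) & d["er"].notna() & d["sm"].notna()
    if not keep.any():
        raise EmptySeriesError(f"{series.site_id}: no records with QC=0 and ER+SM present")
    return series.with_data(d.loc[keep])


def growing_season_mask(
    series: SiteSeries,
    threshold_frac: float = 0.10,
    smooth_days: int = 15,
    day_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Boolean mask over records marking the GPP-defined growing season.

    Daily-mean GPP is smoothed with a centred ``smooth_days`` moving mean;
    a day is in season when its smoothed GPP is at least
    ``p5 + threshold_frac * (p95 - p5)`` of the smoothed daily series.
    With zero dynamic range (constant GPP) every day qualifies.

    ``day_range=(start_doy, end_doy)`` overrides the GPP rule with an
    explicit day-of-year window (inclusive; use when GPP is unavailable).
    """
    d = series.data
    doy = d["timestamp"].dt.dayofyear.to_numpy()
    if day_range is not None:
        lo, hi = day_range
        return (doy >= lo) & (doy <= hi)
    if d["gpp"].isna().all():
        raise InputError(
            f"{series.site_id}: GPP entirely missing; pass an explicit day_range instead"
        )
    date = d["timestamp"].dt.floor("D")
    daily = d.groupby(date, sort=True)["gpp"].mean()
    smooth = daily.rolling(smooth_days, center=True, min_periods=1).mean()
    p5, p95 = np.nanpercentile(smooth.to_numpy(), [5, 95])
    threshold = p5 + threshold_frac * (p95 - p5)
    in_season_days = smooth >= threshold
    return in_season_days.reindex(date).to_numpy(dtype=bool)


def remove_outliers(values, k: float = 2.0) -> np.ndarray:
    """Keep-mask screening values outside mean +/- k standard deviations.

    Mean and SD (sample SD, ddof=1) are computed over the finite values
    only; non-finite entries are marked for removal.  A zero SD means no
    outlier is definable and everything finite is kept.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise InputError(f"remove_outliers needs >= 3 finite values, got {int(finite.sum())}")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return finite.copy()
    keep = finite & (np.abs(x - mu) <= k * sd)
    return keep


def apply_outlier_screen(
    series: SiteSeries, k: float = 2.0, fields: tuple[str, ...] = ("er", "sm")
) -> SiteSeries:
    """Drop records where any of ``fields`` is an outlier (mean +/- k SD)."""
    d = series.data
    keep = np.ones(len(d), dtype=bool)
    for f in fields:
        keep &= remove_outliers(d[f], k=k)
    if not keep.any():
        raise EmptySeriesError(f"{series.site_id}: outlier screen removed every record")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.debug("%s: outlier screen dropped %d records", series.site_id, n_drop)
    return series.with_data(d.loc[keep])
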