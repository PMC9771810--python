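"""Drivers of marsh change: sea level, hurricanes, urbanization, panels.

Builds the watershed x epoch covariate panel — local sea-level change
(LSLC) from decomposed tide-gauge records, hurricane exposure from
HURDAT2 storm tracks buffered by storm diameter, impervious-surface
increments — and fits two-way fixed-effects panel regressions for loss
and gain responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Point, Polygon
from statsmodels.tsa.seasonal import seasonal_decompose

from .ndvi import EpochSpec

NMI_TO_KM = 1.852
#: Saffir-Simpson lower bounds in knots for categories 1..5 (configurable).
SAFFIR_SIMPSON_KT = (64.0, 83.0, 96.0, 113.0, 137.0)
MISSING = -999


def saffir_simpson(max_wind_kt: float,
                   thresholds: tuple[float, ...] = SAFFIR_SIMPSON_KT) -> int:
    """Hurricane category 0-5 from maximum sustained wind (knots).

    Below the category-1 bound (64 kt by default) is 0: not a hurricane.
    Lower bounds are inclusive.
    """
    if max_wind_kt < 0:
        raise ValueError("wind speed must be non-negative")
    return int(np.searchsorted(thresholds, max_wind_kt, side="right"))


@dataclass
class HurricaneTrack:
    """One storm: id, name, and its 6-hourly points as a DataFrame.

    Point columns: ``datetime, lat, lon, max_wind_kt, r34_ne, r34_se,
    r34_sw, r34_nw`` (34-kt quadrant radii in nmi, NaN where the archive
    records the -999 sentinel).
    """

    storm_id: str
    name: str
    points: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def year(self) -> int:
        return int(self.storm_id[4:8])


def parse_hurdat2(text: str) -> list[HurricaneTrack]:
    """Parse HURDAT2 archive text into tracks.

    Header lines carry basin-number-year id, storm name and row count;
    data rows are comma delimited with hemisphere-suffixed coordinates.
    A row-count mismatch produces a warning, not an error; -999 sentinel
    radii become NaN (missing).
    """
    tracks: list[HurricaneTrack] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        header = [f.strip() for f in lines[i].split(",")]
        if len(header) < 3 or len(header[0]) != 8 or not header[0][4:8].isdigit():
            raise ValueError(f"malformed HURDAT2 header at line {i + 1}: {lines[i]!r}")
        storm_id, name, n_rows = header[0], header[1], int(header[2])
        i += 1
        rows = []
        while i < len(lines) and len(rows) < n_rows:
            f = [x.strip() for x in lines[i].split(",")]
            if len(f) < 8:
                break
            lat = float(f[4][:-1]) * (1 if f[4].endswith("N") else -1)
            lon = float(f[5][:-1]) * (1 if f[5].endswith("E") else -1)
            radii = []
            for k in range(8, 12):
                v = float(f[k]) if k < len(f) and f[k] not in ("", None) else MISSING
                radii.append(np.nan if v == MISSING else v)
            rows.append({
                "datetime": pd.Timestamp(f"{f[0][:4]}-{f[0][4:6]}-{f[0][6:8]} "
                                         f"{f[1][:2]}:{f[1][2:]}"),
                "lat": lat, "lon": lon, "max_wind_kt": float(f[6]),
                "r34_ne": radii[0], "r34_se": radii[1],
                "r34_sw": radii[2], "r34_nw": radii[3],
            })
            i += 1
        if len(rows) != n_rows:
            warnings.warn(f"storm {storm_id}: expected {n_rows} points, "
                          f"parsed {len(rows)}", stacklevel=2)
        tracks.append(HurricaneTrack(storm_id=storm_id, name=name,
                                     points=pd.DataFrame(rows)))
    return tracks


class LocalPlane:
    """Equirectangular projection onto a local km-scale plane.

    Adequate for the topological contract here (buffer intersects /
    does not intersect a watershed), not for sub-metre geodesy.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0, self.lon0 = lat0, lon0
        self.kx = 111.320 * np.cos(np.radians(lat0))
        self.ky = 110.574

    def to_plane(self, lon, lat) -> tuple[float, float]:
        return ((lon - self.lon0) * self.kx, (lat - self.lat0) * self.ky)

    def polygon(self, poly: Polygon) -> Polygon:
        xs, ys = poly.exterior.coords.xy
        return Polygon([self.to_plane(x, y) for x, y in zip(xs, ys)])


def point_diameter_km(point_row, category_mean_diameters_km: dict[int, float],
                      thresholds: tuple[float, ...] = SAFFIR_SIMPSON_KT) -> float | None:
    """Storm diameter at one track point, in km.

    Twice the maximum available 34-kt quadrant radius; if all radii are
    missing, the mean diameter for the point's category is used.  Returns
    None when neither is available (the point is skipped with a warning).
    """
    radii = np.array([point_row[k] for k in ("r34_ne", "r34_se", "r34_sw", "r34_nw")],
                     dtype=float)
    if np.isfinite(radii).any():
        return 2.0 * np.nanmax(radii) * NMI_TO_KM
    cat = saffir_simpson(point_row["max_wind_kt"], thresholds)
    return category_mean_diameters_km.get(cat)


def storm_footprint(track: HurricaneTrack,
                    category_mean_diameters_km: dict[int, float],
                    plane: LocalPlane) -> list[Polygon]:
    """Circular buffer (radius = diameter / 2) around each track point."""
    polys = []
    for _, row in track.points.iterrows():
        d = point_diameter_km(row, category_mean_diameters_km)
        if d is None:
            warnings.warn(f"storm {track.storm_id}: point at {row['datetime']} "
                          "has no radii and no category fallback; skipped",
                          stacklevel=2)
            continue
        x, y = plane.to_plane(row["lon"], row["lat"])
        polys.append(Point(x, y).buffer(d / 2.0))
    return polys


def watershed_exposure(
    tracks: list[HurricaneTrack],
    watersheds: dict[int, Polygon],
    epochs: list[EpochSpec],
    category_mean_diameters_km: dict[int, float] | None = None,
    thresholds: tuple[float, ...] = SAFFIR_SIMPSON_KT,
) -> pd.DataFrame:
    """Hurricane landfall flag and highest category per watershed-epoch.

    A watershed is affected in an epoch if any hurricane-strength track
    point (category >= 1) dated within the epoch's years has a diameter
    buffer intersecting the watershed polygon; the recorded category is
    the maximum over intersecting points.  Returns one row per
    (watershed, epoch) with ``landfall`` and ``category`` (0 = none).
    """
    if not watersheds:
        raise ValueError("empty watershed set")
    category_mean_diameters_km = category_mean_diameters_km or {}
    all_pts = [p for poly in watersheds.values() for p in poly.exterior.coords]
    lat0 = float(np.mean([p[1] for p in all_pts]))
    lon0 = float(np.mean([p[0] for p in all_pts]))
    plane = LocalPlane(lat0, lon0)
    planar = {wid: plane.polygon(poly) for wid, poly in watersheds.items()}

    records = {(wid, ep.label): 0 for wid in watersheds for ep in epochs}
    for track in tracks:
        for _, row in track.points.iterrows():
            cat = saffir_simpson(row["max_wind_kt"], thresholds)
            if cat < 1:
                continue
            year = row["datetime"].year
            hit_epochs = [ep.label for ep in epochs
                          if ep.start_year <= year <= ep.end_year]
            if not hit_epochs:
                continue
            d = point_diameter_km(row, category_mean_diameters_km, thresholds)
            if d is None:
                continue
            x, y = plane.to_plane(row["lon"], row["lat"])
            buf = Point(x, y).buffer(d / 2.0)
            for wid, poly in planar.items():
                if buf.intersects(poly):
                    for lab in hit_epochs:
                        records[(wid, lab)] = max(records[(wid, lab)], cat)
    rows = [{"watershed": wid, "epoch": lab, "landfall": cat > 0, "category": cat}
            for (wid, lab), cat in records.items()]
    return pd.DataFrame(rows).sort_values(["watershed", "epoch"]).reset_index(drop=True)


def decompose_monthly(series: pd.DataFrame):
    """Classical additive decomposition of a monthly sea-level series.

    Trend is the centred 2x12-month moving average (half weight at the
    endpoints), the seasonal component is the month-wise mean of the
    detrended series centred to sum to zero, and the residual is the
    remainder; the trend is undefined over the first and last six months.
    Input columns: ``year, month, msl_mm``.  Returns a frame with
    ``year, month, msl_mm, trend, seasonal, resid``.
    """
    if len(series) < 24:
        raise ValueError("decomposition needs at least 24 consecutive months")
    msl = series["msl_mm"].to_numpy(dtype=float)
    res = seasonal_decompose(msl, model="additive", period=12,
                             extrapolate_trend=0)
    out = series[["year", "month", "msl_mm"]].copy().reset_index(drop=True)
    out["trend"] = np.asarray(res.trend)
    out["seasonal"] = np.asarray(res.seasonal)
    out["resid"] = np.asarray(res.resid)
    return out


def lslc_trend(decomposed: pd.DataFrame, epoch: EpochSpec | None = None) -> float:
    """OLS slope (mm/yr) of the decomposed trend component vs decimal year.

    Restricted to the epoch's years when an epoch is given.  Returns NaN
    (missing, not an exception) when fewer than 12 trend months are
    defined in the window.
    """
    df = decomposed
    if epoch is not None:
        df = df[(df["year"] >= epoch.start_year) & (df["year"] <= epoch.end_year)]
    df = df.dropna(subset=["trend"])
    if len(df) < 12:
        return float("nan")
    t = df["year"] + (df["month"] - 0.5) / 12.0
    slope = np.polyfit(t.to_numpy(), df["trend"].to_numpy(), 1)[0]
    return float(slope)


def watershed_lslc(tide_records: pd.DataFrame,
                   epochs: list[EpochSpec]) -> pd.DataFrame:
    """Per-watershed, per-epoch local sea-level trend from tide stations.

    ``tide_records`` columns: ``station, watershed, year, month, msl_mm``.
    Each station's record is split into epochs, each epoch decomposed
    separately and given an OLS trend; watersheds with several stations
    average the station trends.  Epochs with fewer than 24 station months
    yield no estimate for that station.
    """
    rows = []
    for (station, wshed), g in tide_records.groupby(["station", "watershed"]):
        g = g.sort_values(["year", "month"])
        for ep in epochs:
            chunk = g[(g["year"] >= ep.start_year) & (g["year"] <= ep.end_year)]
            if len(chunk) < 24:
                continue
            trend = lslc_trend(decompose_monthly(chunk))
            if np.isfinite(trend):
                rows.append({"station": station, "watershed": wshed,
                             "epoch": ep.label, "trend_mm_yr": trend})
    if not rows:
        return pd.DataFrame(columns=["watershed", "epoch", "lslc_mm_yr", "n_stations"])
    per_station = pd.DataFrame(rows)
    out = (per_station.groupby(["watershed", "epoch"])
           .agg(lslc_mm_yr=("trend_mm_yr", "mean"),
                n_stations=("trend_mm_yr", "size"))
           .reset_index())
    return out


@dataclass
class PanelFit:
    """Two-way fixed-effects panel fit: covariate table + bookkeeping."""

    response: str
    coefficients: pd.DataFrame  # index covariate; columns coef, se, p
    n_rows: int
    n_dropped: int
    fixed_effects: str = "watershed + epoch"
    model: object | None = None


def fit_panel(panel: pd.DataFrame, response: str = "response",
              covariates: tuple[str, ...] | None = None) -> PanelFit:
    """Fit a linear panel model with watershed and epoch fixed effects.

    Rows with any missing covariate or response are dropped (count
    reported).  A rank-deficient design raises, naming the collinear
    columns.
    """
    from .simulate import PANEL_COVARIATES
    covariates = tuple(covariates) if covariates is not None else PANEL_COVARIATES
    if panel.duplicated(["watershed", "epoch"]).any():
        raise ValueError("duplicated (watershed, epoch) keys in panel")
    if panel["watershed"].nunique() < 2 or panel["epoch"].nunique() < 2:
        raise ValueError("panel needs at least 2 watersheds and 2 epochs")
    cols = ["watershed", "epoch", response, *covariates]
    df = panel[cols]
    kept = df.dropna()
    n_dropped = len(df) - len(kept)

    X = pd.get_dummies(
        kept[list(covariates)].assign(
            watershed=kept["watershed"].astype("category"),
            epoch=kept["epoch"].astype("category")),
        columns=["watershed", "epoch"], drop_first=True, dtype=float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    fit = sm.OLS(kept[response].to_numpy(dtype=float), X).fit()
    coefs = pd.DataFrame({
        "coef": fit.params[list(covariates)],
        "se": fit.bse[list(covariates)],
        "p": fit.pvalues[list(covariates)],
    })
    return PanelFit(response=response, coefficients=coefs, n_rows=len(kept),
                    n_dropped=n_dropped, model=fit)
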