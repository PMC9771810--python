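"""Synthetic driver inputs with known truth: tide gauges, storm tracks, panels.

Companions to :mod:`marshchange.scene` for exercising the driver-analysis
stage end to end: monthly sea-level series with a known linear trend,
HURDAT2-format storm-track text, and watershed x epoch covariate panels
generated from known regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COVARIATES = ("lslc", "buffer_loss", "buffer_gain", "urbanization",
                    "hurricane_cat")


def generate_tide_series(
    trend_mm_per_yr: float,
    seasonal_amp_mm: float,
    noise_sd_mm: float,
    months: int,
    seed: int = 0,
    start_year: int = 2000,
    level_mm: float = 7000.0,
) -> pd.DataFrame:
    """Monthly mean sea level = linear trend + 12-month sinusoid + noise.

    Returns a frame with columns ``year, month, msl_mm``; the generating
    parameters are attached as ``frame.attrs['truth']``.
    """
    if months < 24:
        raise ValueError("need at least 24 months (two full seasonal cycles)")
    rng = np.random.default_rng(seed)
    idx = np.arange(months)
    years = start_year + idx // 12
    mon = idx % 12 + 1
    t_yr = idx / 12.0
    msl = (
        level_mm
        + trend_mm_per_yr * t_yr
        + seasonal_amp_mm * np.sin(2 * np.pi * idx / 12.0)
        + (rng.normal(0.0, noise_sd_mm, months) if noise_sd_mm > 0 else 0.0)
    )
    out = pd.DataFrame({"year": years, "month": mon, "msl_mm": msl})
    out.attrs["truth"] = {
        "trend_mm_per_yr": trend_mm_per_yr,
        "seasonal_amp_mm": seasonal_amp_mm,
        "noise_sd_mm": noise_sd_mm,
    }
    return out


@dataclass
class TrackSpec:
    """One storm for the HURDAT2 writer.

    ``points`` rows: (datetime 'YYYYMMDD HHMM', lat, lon, max_wind_kt,
    optional 4-tuple of 34-kt quadrant radii in nmi).
    """

    basin: str
    number: int
    year: int
    name: str
    points: list[tuple] = field(default_factory=list)

    @property
    def storm_id(self) -> str:
        return f"{self.basin}{self.number:02d}{self.year}"


def generate_hurdat(tracks: list[TrackSpec]) -> str:
    """Emit HURDAT2-format text for the given track specs.

    The dialect matches the National Hurricane Center archive: a header
    line ``ID, NAME, N_ROWS,`` then one comma-delimited row per 6-hourly
    point with hemisphere-suffixed coordinates; missing wind radii are
    written as the -999 sentinel.
    """
    lines = []
    for tr in tracks:
        lines.append(f"{tr.storm_id},{tr.name.upper():>19},{len(tr.points):7d},")
        for pt in tr.points:
            stamp, lat, lon, wind = pt[0], pt[1], pt[2], pt[3]
            radii = pt[4] if len(pt) > 4 and pt[4] is not None else None
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"latitude {lat} outside [-90, 90]")
            if not -180.0 <= lon <= 180.0:
                raise ValueError(f"longitude {lon} outside [-180, 180]")
            date, time = stamp.split()
            lat_s = f"{abs(lat):.1f}{'N' if lat >= 0 else 'S'}"
            lon_s = f"{abs(lon):.1f}{'E' if lon >= 0 else 'W'}"
            r = list(radii) if radii is not None else [-999] * 4
            fields = [
                date, f" {time}", "  ", " HU",
                f"{lat_s:>6}", f"{lon_s:>7}",
                f"{int(round(wind)):4d}", f"{-999:5d}",
                *[f"{int(v):5d}" for v in r],
                *[f"{-999:5d}"] * 8,
            ]
            lines.append(",".join(fields) + ",")
    return "\n".join(lines) + "\n"


def generate_panel_covariates(
    n_watersheds: int,
    n_epochs: int,
    coefficients: dict[str, float] | np.ndarray,
    noise_sd: float,
    seed: int = 0,
    fixed_effect_sd: float = 1.0,
) -> pd.DataFrame:
    """A watershed x epoch panel whose response has known coefficients.

    Response = sum(coef * covariate) + watershed effect + epoch effect +
    Gaussian noise.  Covariates (sea-level trend, 100-m buffer loss/gain,
    impervious-surface increment, hurricane category) are drawn on
    realistic scales.  Truth coefficients and effects are attached as
    ``frame.attrs['truth']``.
    """
    if isinstance(coefficients, dict):
        missing = set(coefficients) - set(PANEL_COVARIATES)
        if missing:
            raise ValueError(f"unknown covariates: {sorted(missing)}")
        beta = np.array([coefficients.get(c, 0.0) for c in PANEL_COVARIATES])
    else:
        beta = np.asarray(coefficients, dtype=float)
        if beta.shape != (len(PANEL_COVARIATES),):
            raise ValueError(
                f"coefficient vector must have length {len(PANEL_COVARIATES)}")
    n_params = len(beta) + n_watersheds + n_epochs
    if n_watersheds * n_epochs < n_params + 2:
        raise ValueError("panel too small for the parameter count")

    rng = np.random.default_rng(seed)
    rows = n_watersheds * n_epochs
    X = np.column_stack([
        rng.normal(3.0, 2.0, rows),       # lslc, mm/yr
        rng.exponential(0.05, rows),      # buffer loss, km2
        rng.exponential(0.05, rows),      # buffer gain, km2
        rng.exponential(0.5, rows),       # urbanization, km2 added
        rng.integers(0, 6, rows).astype(float),  # hurricane category
    ])
    w_eff = rng.normal(0.0, fixed_effect_sd, n_watersheds)
    e_eff = rng.normal(0.0, fixed_effect_sd, n_epochs)
    e_eff -= e_eff.mean()
    wid = np.repeat(np.arange(n_watersheds), n_epochs)
    eid = np.tile(np.arange(n_epochs), n_watersheds)
    y = X @ beta + w_eff[wid] + e_eff[eid]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, rows)

    panel = pd.DataFrame(X, columns=list(PANEL_COVARIATES))
    panel.insert(0, "epoch", eid)
    panel.insert(0, "watershed", wid)
    panel["response"] = y
    panel.attrs["truth"] = {
        "coefficients": dict(zip(PANEL_COVARIATES, beta)),
        "watershed_effects": w_eff,
        "epoch_effects": e_eff,
        "noise_sd": noise_sd,
    }
    return panel
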