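"""Stratified area estimation and change-rate bookkeeping.

Implements the standard good-practice estimator for bias-adjusted class
areas from a stratified accuracy-assessment sample: with map strata i of
weight W_i and a reference-labelled sample n_ij,

    p_hat_j  = sum_i W_i * n_ij / n_i.
    SE(p_j)  = sqrt( sum_i W_i^2 * p_ij (1 - p_ij) / (n_i. - 1) )

where p_ij = n_ij / n_i.; areas are total_area * p_hat_j with 90%
confidence intervals at z = 1.645.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ndvi as _ndvi

Z90 = 1.645  # fixed large-sample z for 90% CIs

CLASS_NAMES = {_ndvi.STABLE: "stable", _ndvi.LOSS: "loss", _ndvi.GAIN: "gain",
               _ndvi.RECOVERED: "recovered"}


@dataclass
class ConfusionSample:
    """A stratified accuracy-assessment sample.

    ``classes``: stratum/class labels (map classes, in order);
    ``mapped_counts``: mapped pixel count per stratum (sets the weights);
    ``matrix``: n_ij counts, rows = map class i, columns = reference class j.
    """

    classes: list[str]
    mapped_counts: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.mapped_counts = np.asarray(self.mapped_counts, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("confusion matrix must be square over the classes")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return self.mapped_counts / self.mapped_counts.sum()

    @property
    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def pixel_count_areas(classes: np.ndarray,
                      pixel_area_m2: float = _ndvi.PIXEL_AREA_M2,
                      mask: np.ndarray | None = None) -> pd.Series:
    """Mapped area (km^2) per class from a class-code raster.

    ``classes`` may be a single (H, W) raster or an (E, H, W) stack, in
    which case counts are per epoch summed into one Series per call.
    """
    arr = np.asarray(classes)
    if mask is not None:
        arr = arr[..., mask] if arr.ndim == 3 else arr[mask]
    out = {}
    for code, name in CLASS_NAMES.items():
        out[name] = np.count_nonzero(arr == code) * pixel_area_m2 / 1e6
    return pd.Series(out, name="area_km2")


def stratified_area(sample: ConfusionSample, total_area_km2: float) -> pd.DataFrame:
    """Bias-adjusted class areas with SE and 90% CI, plus accuracies.

    Returns a frame indexed by class with columns ``mapped_km2,
    adjusted_km2, se_km2, ci90_low, ci90_high, users_acc, producers_acc``
    and the overall accuracy in ``frame.attrs['overall_accuracy']``.
    """
    n_i = sample.row_totals
    bad = np.flatnonzero(n_i < 2)
    if bad.size:
        raise ValueError(
            f"stratum {sample.classes[bad[0]]!r} has fewer than 2 sample points")
    W = sample.weights
    p = sample.matrix / n_i[:, None]              # p_ij
    p_j = W @ p                                    # bias-adjusted proportions
    var_j = (W[:, None] ** 2 * p * (1 - p) / (n_i[:, None] - 1)).sum(axis=0)
    se_j = np.sqrt(var_j)

    adj = total_area_km2 * p_j
    se = total_area_km2 * se_j
    mapped = total_area_km2 * W
    diag = np.diag(sample.matrix)
    users = diag / n_i
    # producer's accuracy on the bias-adjusted scale
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = np.where(p_j > 0, W * np.diag(p) / p_j, np.nan)
    overall = float((W * np.diag(p)).sum())

    out = pd.DataFrame({
        "mapped_km2": mapped,
        "adjusted_km2": adj,
        "se_km2": se,
        "ci90_low": adj - Z90 * se,
        "ci90_high": adj + Z90 * se,
        "users_acc": users,
        "producers_acc": producers,
    }, index=pd.Index(sample.classes, name="class"))
    out.attrs["overall_accuracy"] = overall
    return out


def aggregate_changes(estimates: pd.DataFrame,
                      by: str | None = None) -> pd.DataFrame:
    """Aggregate per-region loss/gain estimates into net change.

    ``estimates`` rows carry ``region, loss_km2, gain_km2`` and optional
    ``loss_se_km2, gain_se_km2, recovery_km2``.  Areas sum; standard
    errors combine as the root sum of squares (regions treated as
    independent).  Net change = gross loss - gross gain; recovery is
    carried through separately, never subtracted.  ``by=None`` collapses
    everything into one global row.
    """
    df = estimates.copy()
    if "region" in df.columns and df["region"].duplicated().any() and by is None:
        dups = df.loc[df["region"].duplicated(), "region"].unique()
        raise ValueError(f"duplicate region keys: {list(dups)}")
    keys = [by] if by else []
    grouped = df.groupby(keys) if keys else [((), df)]

    rows = []
    for key, g in grouped:
        row = {by: key if not isinstance(key, tuple) else key[0]} if by else {}
        for col in ("loss_km2", "gain_km2", "recovery_km2"):
            if col in g:
                row[col] = g[col].sum()
        for col in ("loss_se_km2", "gain_se_km2", "recovery_se_km2"):
            if col in g:
                row[col] = float(np.sqrt((g[col] ** 2).sum()))
        row["net_km2"] = row.get("loss_km2", 0.0) - row.get("gain_km2", 0.0)
        if "loss_se_km2" in row and "gain_se_km2" in row:
            row["net_se_km2"] = float(np.hypot(row["loss_se_km2"], row["gain_se_km2"]))
        rows.append(row)
    return pd.DataFrame(rows)


def change_rate(net_area_km2: float, base_extent_km2: float, years: float) -> float:
    """Net change rate in % per year relative to the base extent."""
    if base_extent_km2 <= 0:
        raise ValueError("base extent must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return 100.0 * net_area_km2 / (base_extent_km2 * years)
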