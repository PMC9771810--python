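"""Per-pixel NDVI anomaly change detection.

Change is detected by comparing each pixel's mean NDVI over the
peak-biomass months of a five-year analysis epoch against its mean over a
multi-year reference window.  A departure of more than 0.2 NDVI (strictly
greater in absolute value) marks the pixel as a loss or gain anomaly; a
loss pixel is *recovered* if its mean in any later epoch returns to at
least the reference mean.

Class codes used throughout (and in exported rasters):
``0`` stable, ``1`` loss, ``2`` gain, ``3`` recovered, ``255`` no-data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STABLE = 0
LOSS = 1
GAIN = 2
RECOVERED = 3
NODATA = 255

#: Peak-biomass months by hemisphere: late summer in each.
PEAK_MONTHS = {"N": (8, 9), "S": (2, 3)}

DEFAULT_THRESHOLD = 0.2
PIXEL_AREA_M2 = 900.0  # 30 m Landsat pixel


def compute_ndvi(red, nir):
    """Normalized difference vegetation index, ``(NIR - Red)/(NIR + Red)``.

    Accepts scalars or arrays of reflectance in [0, 1].  Where both bands
    are zero the result is NaN (no-data), not an exception.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red < 0) or np.any(nir < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class EpochSpec:
    """A labelled analysis window with its peak-biomass months."""

    label: str
    start_year: int
    end_year: int
    peak_months: tuple[int, ...]

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError(f"epoch {self.label}: end year before start year")
        if not self.peak_months:
            raise ValueError(f"epoch {self.label}: peak months must be non-empty")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def default_epochs(hemisphere: str = "N") -> list[EpochSpec]:
    """The four five-year analysis epochs, 2000-2019."""
    months = PEAK_MONTHS[hemisphere]
    return [
        EpochSpec(f"{y}-{y + 4}", y, y + 4, months)
        for y in (2000, 2005, 2010, 2015)
    ]


def reference_epoch(hemisphere: str = "N", start_year: int = 1984,
                    end_year: int = 1999) -> EpochSpec:
    """The reference (baseline) window, 1984-1999 by default.

    A 1984-2004 window is used for Siberian watersheds where pre-2000
    imagery is sparse; pass ``end_year=2004`` (see
    :func:`compute_change_map`'s ``ref_overrides``).
    """
    return EpochSpec(f"ref-{start_year}-{end_year}", start_year, end_year,
                     PEAK_MONTHS[hemisphere])


@dataclass
class ReflectanceStack:
    """Dated per-pixel NDVI observations with QA flags on a 30-m grid.

    ``ndvi`` has shape (T, H, W); ``qa`` is True where the observation
    passed quality filtering; ``years``/``months`` give each layer's date.
    Red/NIR bands, when present, satisfy ``compute_ndvi(red, nir) == ndvi``.
    """

    ndvi: np.ndarray
    qa: np.ndarray
    years: np.ndarray
    months: np.ndarray
    red: np.ndarray | None = None
    nir: np.ndarray | None = None
    pixel_area_m2: float = PIXEL_AREA_M2

    def __post_init__(self):
        t, h, w = self.ndvi.shape
        if self.qa.shape != (t, h, w):
            raise ValueError("qa shape must match ndvi")
        if len(self.years) != t or len(self.months) != t:
            raise ValueError("years/months must have one entry per layer")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ndvi.shape[1:]


def epoch_mean(stack: ReflectanceStack, epoch: EpochSpec):
    """Per-pixel mean NDVI over QA-passing, peak-month observations.

    Returns ``(mean, count)``: mean is NaN wherever count is zero.
    """
    sel = (
        (stack.years >= epoch.start_year)
        & (stack.years <= epoch.end_year)
        & np.isin(stack.months, epoch.peak_months)
    )
    vals = stack.ndvi[sel].astype(float)
    valid = stack.qa[sel] & np.isfinite(vals)
    count = valid.sum(axis=0)
    total = np.where(valid, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def classify_change(ref_mean, epoch_mean, threshold: float = DEFAULT_THRESHOLD):
    """Classify the NDVI anomaly ``epoch_mean - ref_mean`` per pixel.

    Strictly greater than ``threshold`` in magnitude: a delta of exactly
    -0.2 is stable.  Undefined means (NaN) propagate to NODATA.
    """
    ref = np.asarray(ref_mean, dtype=float)
    epo = np.asarray(epoch_mean, dtype=float)
    delta = epo - ref
    cls = np.full(delta.shape, STABLE, dtype=np.uint8)
    cls[delta < -threshold] = LOSS
    cls[delta > threshold] = GAIN
    cls[~np.isfinite(delta)] = NODATA
    if cls.ndim == 0:
        return int(cls)
    return cls


@dataclass
class ChangeMap:
    """Per-pixel, per-epoch anomaly classes with their NDVI deltas."""

    epochs: list[EpochSpec]
    classes: np.ndarray      # (E, H, W) uint8
    delta: np.ndarray        # (E, H, W) float, NaN where no-data
    counts: np.ndarray       # (E, H, W) int valid-observation counts
    ref_mean: np.ndarray     # (H, W)
    epoch_means: np.ndarray  # (E, H, W)

    def epoch_index(self, label: str) -> int:
        for i, e in enumerate(self.epochs):
            if e.label == label:
                return i
        raise KeyError(label)


def compute_change_map(
    stack: ReflectanceStack,
    epochs: list[EpochSpec] | None = None,
    reference: EpochSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    ref_overrides: dict[int, EpochSpec] | None = None,
    watersheds: np.ndarray | None = None,
) -> ChangeMap:
    """Run the anomaly classification for every epoch against the baseline.

    ``ref_overrides`` maps watershed id -> alternative reference window
    (e.g. the 1984-2004 baseline used where early imagery is sparse);
    it requires ``watersheds``, a label raster aligned with the stack.
    """
    epochs = epochs if epochs is not None else default_epochs()
    reference = reference if reference is not None else reference_epoch()
    ref_mean, ref_count = epoch_mean(stack, reference)
    if ref_overrides:
        if watersheds is None:
            raise ValueError("ref_overrides requires a watershed raster")
        if watersheds.shape != stack.shape:
            raise ValueError("watershed raster misaligned with stack")
        for wid, window in ref_overrides.items():
            alt_mean, alt_count = epoch_mean(stack, window)
            inside = watersheds == wid
            ref_mean = np.where(inside, alt_mean, ref_mean)
            ref_count = np.where(inside, alt_count, ref_count)
    ref_mean = np.where(ref_count > 0, ref_mean, np.nan)

    e_means, e_counts, e_classes, e_delta = [], [], [], []
    for ep in epochs:
        m, c = epoch_mean(stack, ep)
        e_means.append(m)
        e_counts.append(c)
        e_classes.append(classify_change(ref_mean, m, threshold))
        e_delta.append(m - ref_mean)
    return ChangeMap(
        epochs=list(epochs),
        classes=np.stack(e_classes),
        delta=np.stack(e_delta),
        counts=np.stack(e_counts),
        ref_mean=ref_mean,
        epoch_means=np.stack(e_means),
    )


@dataclass
class RecoveryMap:
    """First-loss epoch and (optional) recovery epoch per pixel.

    ``loss_epoch``/``recovery_epoch`` hold epoch indices, -1 where absent.
    """

    loss_epoch: np.ndarray
    recovery_epoch: np.ndarray
    recovered: np.ndarray
    epochs: list[EpochSpec] = field(default_factory=list)


def detect_recovery(change: ChangeMap) -> RecoveryMap:
    """Find loss pixels whose NDVI later returns to the reference mean.

    Loss is attributed to the earliest epoch in which the pixel classifies
    as loss.  The pixel is recovered if any strictly later epoch's mean is
    at least the reference mean (inclusive); the recovery epoch is the
    earliest such epoch.
    """
    n_epochs, h, w = change.classes.shape
    is_loss = change.classes == LOSS
    any_loss = is_loss.any(axis=0)
    loss_epoch = np.where(any_loss, is_loss.argmax(axis=0), -1)

    at_or_above_ref = change.epoch_means >= change.ref_mean  # NaN -> False
    recovery_epoch = np.full((h, w), -1, dtype=int)
    # scan from latest to earliest so the stored epoch ends up the earliest
    for e in range(n_epochs - 1, -1, -1):
        ok = any_loss & (e > loss_epoch) & at_or_above_ref[e]
        recovery_epoch[ok] = e
    recovered = recovery_epoch >= 0
    return RecoveryMap(loss_epoch=loss_epoch, recovery_epoch=recovery_epoch,
                       recovered=recovered, epochs=list(change.epochs))


def buffer_anomalies(
    change: ChangeMap,
    buffer_mask: np.ndarray,
    watersheds: np.ndarray,
    pixel_area_m2: float = PIXEL_AREA_M2,
) -> pd.DataFrame:
    """Loss/gain anomaly areas inside the 100-m buffer, per watershed-epoch.

    Returns a tidy frame with columns
    ``watershed, epoch, loss_km2, gain_km2``.  Areas are pixel counts
    times the nominal pixel area.
    """
    if buffer_mask.shape != change.classes.shape[1:]:
        raise ValueError("buffer mask misaligned with change map")
    if watersheds.shape != change.classes.shape[1:]:
        raise ValueError("watershed raster misaligned with change map")
    wids = np.unique(watersheds[watersheds > 0])
    rows = []
    for e, ep in enumerate(change.epochs):
        cls = change.classes[e]
        for wid in wids:
            sel = buffer_mask & (watersheds == wid)
            loss = int(np.count_nonzero(cls[sel] == LOSS))
            gain = int(np.count_nonzero(cls[sel] == GAIN))
            rows.append({
                "watershed": int(wid),
                "epoch": ep.label,
                "loss_km2": loss * pixel_area_m2 / 1e6,
                "gain_km2": gain * pixel_area_m2 / 1e6,
            })
    return pd.DataFrame(rows)
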