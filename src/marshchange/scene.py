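"""Synthetic Landsat-like scenes with known change ground truth.

Generates monthly per-pixel NDVI (plus a consistent red/NIR pair) on a
30-m grid over a marsh extent mask, with a seasonal cycle peaking in the
hemisphere's peak-biomass months, Gaussian observation noise, i.i.d.
Bernoulli QA dropout, and injected loss / gain / recovery-after-loss
events whose pixels, onset epochs and NDVI deltas are returned as a
truth table.  Every draw is controlled by a single seed, so two calls
with the same config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ndvi import (
    EpochSpec,
    ReflectanceStack,
    PEAK_MONTHS,
    default_epochs,
    reference_epoch,
)

BUFFER_100M_PX = 100.0 / 30.0   # 100-m covariate buffer in pixel units
BUFFER_1800M_PX = 1800.0 / 30.0  # 1.8-km processing buffer


@dataclass(frozen=True)
class ChangeEvent:
    """A truth-injected change: a pixel set, its kind, onset and delta.

    ``kind`` is ``loss``, ``gain`` or ``recovery`` (loss followed by a
    return to baseline); ``delta``'s sign is implied by the kind.
    ``recovery_epoch`` (an epoch index > onset) applies only to recovery.
    """

    pixels: tuple[tuple[int, int], ...]
    kind: str
    onset_epoch: int
    delta: float = 0.3
    recovery_epoch: int | None = None

    def __post_init__(self):
        if self.kind not in ("loss", "gain", "recovery"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "recovery":
            if self.recovery_epoch is None or self.recovery_epoch <= self.onset_epoch:
                raise ValueError("recovery epoch must be after the onset epoch")
        elif self.recovery_epoch is not None:
            raise ValueError("recovery_epoch is only valid for recovery events")


@dataclass
class SceneConfig:
    """Everything needed to generate a scene deterministically."""

    height: int = 64
    width: int = 64
    ref_start: int = 1984
    ref_end: int = 1999
    epochs: list[EpochSpec] | None = None
    hemisphere: str = "N"
    base_ndvi: float = 0.5
    seasonal_amplitude: float = 0.15
    noise_sd: float = 0.05
    dropout: float = 0.3
    marsh_margin: int = 8           # pixels of non-marsh border around the marsh block
    n_watersheds: int = 3
    events: list[ChangeEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.epochs is None:
            self.epochs = default_epochs(self.hemisphere)
        labels = [(e.start_year, e.end_year) for e in self.epochs]
        if labels != sorted(labels):
            raise ValueError("epochs must be ordered")
        for (s0, e0), (s1, _) in zip(labels, labels[1:]):
            if s1 <= e0:
                raise ValueError("epochs must be disjoint")
        for e in self.epochs:
            if e.n_years != 5:
                raise ValueError(f"analysis epoch {e.label} must span 5 years")
            if e.start_year <= self.ref_end:
                raise ValueError("epochs may not overlap the reference window")


@dataclass
class SyntheticScene:
    """A generated stack plus its masks, watersheds and truth table."""

    stack: ReflectanceStack
    marsh_mask: np.ndarray
    buffer_mask: np.ndarray       # 100-m ring around the marsh
    processing_mask: np.ndarray   # marsh + 1.8-km buffer
    watersheds: np.ndarray
    truth: pd.DataFrame           # one row per event pixel
    events: list[ChangeEvent]
    config: SceneConfig
    reference: EpochSpec


def _masks(cfg: SceneConfig):
    marsh = np.zeros((cfg.height, cfg.width), dtype=bool)
    m = cfg.marsh_margin
    if cfg.height - 2 * m <= 0 or cfg.width - 2 * m <= 0:
        raise ValueError("marsh mask has zero area; shrink the margin")
    marsh[m:cfg.height - m, m:cfg.width - m] = True
    dist = ndimage.distance_transform_edt(~marsh)
    buffer100 = (dist > 0) & (dist <= BUFFER_100M_PX)
    processing = dist <= BUFFER_1800M_PX
    return marsh, buffer100, processing


def _watershed_labels(cfg: SceneConfig) -> np.ndarray:
    # vertical strips labelled 1..n
    edges = np.linspace(0, cfg.width, cfg.n_watersheds + 1).astype(int)
    labels = np.zeros((cfg.height, cfg.width), dtype=np.int32)
    for i in range(cfg.n_watersheds):
        labels[:, edges[i]:edges[i + 1]] = i + 1
    return labels


def _seasonal(months: np.ndarray, hemisphere: str, amplitude: float) -> np.ndarray:
    peak = np.mean(PEAK_MONTHS[hemisphere])  # 8.5 N, 2.5 S
    return amplitude * np.cos(2 * np.pi * (months - peak) / 12.0)


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate the full scene: stack, masks, watersheds and truth.

    The per-pixel signal is ``base + seasonal(month) + event shift +
    noise``; event shifts apply from the onset epoch's first year onward
    (and are removed again at the recovery epoch for recovery events).
    """
    marsh, buffer100, processing = _masks(cfg)
    watersheds = _watershed_labels(cfg)
    rng = np.random.default_rng(cfg.seed)

    epochs = cfg.epochs
    start_year, end_year = cfg.ref_start, epochs[-1].end_year
    n_months = (end_year - start_year + 1) * 12
    years = np.repeat(np.arange(start_year, end_year + 1), 12)
    months = np.tile(np.arange(1, 13), end_year - start_year + 1)

    base = np.full((cfg.height, cfg.width), cfg.base_ndvi, dtype=np.float32)
    seasonal = _seasonal(months, cfg.hemisphere, cfg.seasonal_amplitude)

    ndvi = base[None, :, :] + seasonal[:, None, None].astype(np.float32)

    truth_rows = []
    for event in cfg.events:
        onset_year = epochs[event.onset_epoch].start_year
        signed = -abs(event.delta) if event.kind in ("loss", "recovery") else abs(event.delta)
        active = years >= onset_year
        if event.kind == "recovery":
            active &= years < epochs[event.recovery_epoch].start_year
        for r, c in event.pixels:
            if not processing[r, c]:
                raise ValueError(f"event pixel ({r}, {c}) outside processing mask")
            ndvi[active, r, c] += signed
            truth_rows.append({
                "row": r, "col": c, "kind": event.kind,
                "onset_epoch": event.onset_epoch, "delta": signed,
                "recovery_epoch": event.recovery_epoch if event.kind == "recovery" else -1,
            })

    if cfg.noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, cfg.noise_sd,
                                 size=(n_months, cfg.height, cfg.width)).astype(np.float32)
    ndvi = np.clip(ndvi, -1.0, 1.0)

    qa = rng.random((n_months, cfg.height, cfg.width)) >= cfg.dropout

    # paired bands chosen so (nir - red) / (nir + red) reproduces ndvi
    red = (1.0 - ndvi) / 4.0
    nir = (1.0 + ndvi) / 4.0

    stack = ReflectanceStack(ndvi=ndvi, qa=qa, years=years, months=months,
                             red=red, nir=nir)
    truth = pd.DataFrame(
        truth_rows,
        columns=["row", "col", "kind", "onset_epoch", "delta", "recovery_epoch"],
    )
    reference = reference_epoch(cfg.hemisphere, cfg.ref_start, cfg.ref_end)
    return SyntheticScene(stack=stack, marsh_mask=marsh, buffer_mask=buffer100,
                          processing_mask=processing, watersheds=watersheds,
                          truth=truth, events=list(cfg.events), config=cfg,
                          reference=reference)


def random_events(
    cfg: SceneConfig,
    n_loss: int,
    n_gain: int,
    n_recovery: int = 0,
    patch: int = 3,
    delta: float = 0.3,
    seed: int | None = None,
) -> list[ChangeEvent]:
    """Place square event patches at random, non-overlapping marsh locations."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    marsh, _, _ = _masks(cfg)
    taken = np.zeros_like(marsh)
    events: list[ChangeEvent] = []
    kinds = ["loss"] * n_loss + ["gain"] * n_gain + ["recovery"] * n_recovery
    n_epochs = len(cfg.epochs)
    for kind in kinds:
        for _ in range(1000):
            r = int(rng.integers(0, cfg.height - patch))
            c = int(rng.integers(0, cfg.width - patch))
            block = np.s_[r:r + patch, c:c + patch]
            if marsh[block].all() and not taken[block].any():
                taken[block] = True
                break
        else:
            raise RuntimeError("could not place event patch; marsh too small")
        if kind == "recovery":
            onset = int(rng.integers(0, n_epochs - 1))
            recov = int(rng.integers(onset + 1, n_epochs))
        else:
            onset = int(rng.integers(0, n_epochs))
            recov = None
        pixels = tuple(
            (rr, cc)
            for rr in range(r, r + patch)
            for cc in range(c, c + patch)
        )
        events.append(ChangeEvent(pixels=pixels, kind=kind, onset_epoch=onset,
                                  delta=delta, recovery_epoch=recov))
    return events
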