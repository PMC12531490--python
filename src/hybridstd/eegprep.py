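"""Epoching, preprocessing, and the neuroanatomy-based channel partition.

The decoder consumes 60-channel EEG split into three functional regions —
temporal, frontal, and parieto-occipital — of exactly 20 channels each.
The packaged lookup table anchors each region on the canonical 10-20
electrodes (T7/T8, TP7/TP8 temporal; Fp1/Fp2, AF3/AF4, F3/F4, Fz, FC1/FC2
frontal; P3/P4, PO3/PO4, O1/O2, CP1/CP2 parieto-occipital) and extends by
scalp proximity to fill 20 slots per region.  The table is a package
choice and can be overridden with a JSON {label: region} file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MontageError",
    "RegionPartition",
    "PreprocConfig",
    "EEGEpoch",
    "STANDARD_60",
    "REGION_TABLE",
    "build_partition",
    "load_partition_override",
    "preprocess",
    "extract_training_epochs",
    "reject_artifacts",
]


class MontageError(ValueError):
    """Raised for unknown labels or wrong channel counts."""


# Old 10-20 temporal names map onto the modern 10-10 grid.
_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_FRONTAL = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FC1", "FCz", "FC2",
]
_TEMPORAL = [
    "FT7", "FC5", "FC3", "T7", "C5", "C3", "TP7", "CP5", "CP3", "P7",
    "FT8", "FC6", "FC4", "T8", "C6", "C4", "TP8", "CP6", "CP4", "P8",
]
_PARIETO_OCC = [
    "C1", "Cz", "C2", "CP1", "CPz", "CP2",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
    "PO7", "PO3", "PO4", "PO8", "O1", "Oz", "O2",
]

STANDARD_60: list[str] = _FRONTAL + _TEMPORAL + _PARIETO_OCC

REGION_TABLE: dict[str, str] = {}
for _lab in _TEMPORAL:
    REGION_TABLE[_lab] = "T"
for _lab in _FRONTAL:
    REGION_TABLE[_lab] = "F"
for _lab in _PARIETO_OCC:
    REGION_TABLE[_lab] = "P"


@dataclass(frozen=True)
class RegionPartition:
    """Channel-label → region map plus per-region ordered index lists."""

    mapping: dict[str, str]
    region_order: dict[str, list[int]]

    def region_labels(self, region: str, labels: list[str]) -> list[str]:
        return [labels[i] for i in self.region_order[region]]


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (1.0, 49.0)
    baseline_window: tuple[float, float] = (0.0, 1.0)
    reference: str = "common_average"
    artifact_amp_uv: float = 100.0


@dataclass
class EEGEpoch:
    """One channels × time window, possibly aligned to a target onset."""

    data: np.ndarray
    srate: float
    channel_labels: list[str] = field(default_factory=lambda: list(STANDARD_60))
    label: str = "nontarget"
    onset_index: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels × samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("row count must match channel labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.srate <= 0:
            raise ValueError("srate must be positive")


def _canonical(label: str) -> str:
    return _ALIASES.get(label, label)


def build_partition(channel_labels: list[str],
                    table: dict[str, str] | None = None) -> RegionPartition:
    """Assign each channel to a region; independent of label order.

    Raises :class:`MontageError` listing offending labels if any label is
    unrecognised, labels are duplicated, or region sizes are not 20/20/20.
    """
    table = REGION_TABLE if table is None else table
    canon = [_canonical(l) for l in channel_labels]
    if len(canon) != 60:
        raise MontageError(f"expected 60 channels, got {len(canon)}")
    dupes = {l for l in canon if canon.count(l) > 1}
    if dupes:
        raise MontageError(f"duplicate channels: {sorted(dupes)}")
    unknown = [l for l in canon if l not in table]
    if unknown:
        raise MontageError(f"unknown channel labels: {unknown}")
    mapping = {lab: table[c] for lab, c in zip(channel_labels, canon)}
    region_order: dict[str, list[int]] = {"T": [], "F": [], "P": []}
    # canonical region order: sort by the packaged montage position so the
    # mapping is invariant to the input label permutation
    ref_pos = {l: i for i, l in enumerate(STANDARD_60)}
    for region in ("T", "F", "P"):
        idx = [i for i, c in enumerate(canon) if table[c] == region]
        idx.sort(key=lambda i: ref_pos.get(canon[i], 999))
        region_order[region] = idx
    sizes = {r: len(v) for r, v in region_order.items()}
    if any(s != 20 for s in sizes.values()):
        raise MontageError(f"region sizes must be 20/20/20, got {sizes}")
    return RegionPartition(mapping=mapping, region_order=region_order)


def load_partition_override(path: str, channel_labels: list[str]) -> RegionPartition:
    with open(path) as fh:
        table = json.load(fh)
    return build_partition(channel_labels, table=table)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _fir_taps(srate: float, band: tuple[float, float], n_samples: int) -> np.ndarray:
    low, high = band
    if not 0 < low < high < srate / 2:
        raise ValueError(f"band {band} outside (0, Nyquist) at srate {srate}")
    # windowed-sinc; length adapts so filtfilt padding fits short epochs
    desired = int(round(3.3 * srate / max(0.5, low)))
    numtaps = min(desired, max(9, n_samples // 3))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=srate)


def preprocess(epoch: EEGEpoch, cfg: PreprocConfig | None = None) -> EEGEpoch:
    """Zero-phase FIR bandpass, baseline correction, common-average reference."""
    cfg = cfg or PreprocConfig()
    x = epoch.data
    n = x.shape[1]
    b0, b1 = cfg.baseline_window
    i0, i1 = int(round(b0 * epoch.srate)), int(round(b1 * epoch.srate))
    if not 0 <= i0 < i1 <= n:
        raise ValueError("epoch does not cover the baseline window")
    taps = _fir_taps(epoch.srate, cfg.band, n)
    padlen = min(3 * len(taps), n - 1)
    y = signal.filtfilt(taps, [1.0], x, axis=1, padlen=padlen)
    y = y - y[:, i0:i1].mean(axis=1, keepdims=True)
    if cfg.reference == "common_average":
        y = y - y.mean(axis=0, keepdims=True)
    return EEGEpoch(y, epoch.srate, list(epoch.channel_labels),
                    epoch.label, epoch.onset_index)


def extract_training_epochs(trial: np.ndarray, onset_s: float, srate: float,
                            channel_labels: list[str] | None = None
                            ) -> tuple[EEGEpoch, EEGEpoch]:
    """Cut the target [0, 1) s and nontarget [-3, -2) s epochs around onset.

    `trial` is a continuous channels × samples array whose first sample is
    t = 0; intervals are half-open with 0-based sample indexing.
    """
    trial = np.asarray(trial, dtype=np.float64)
    labels = channel_labels or list(STANDARD_60)
    on = int(round(onset_s * srate))
    w = int(round(srate))
    if on - 3 * w < 0 or on + w > trial.shape[1]:
        raise ValueError("trial must span [onset-3 s, onset+1 s]")
    target = EEGEpoch(trial[:, on:on + w].copy(), srate, list(labels),
                      "target", onset_index=0)
    nontarget = EEGEpoch(trial[:, on - 3 * w:on - 2 * w].copy(), srate,
                         list(labels), "nontarget", onset_index=None)
    return target, nontarget


def reject_artifacts(epochs: list[EEGEpoch], threshold_uv: float
                     ) -> tuple[list[EEGEpoch], list[EEGEpoch]]:
    """Flag epochs whose absolute amplitude exceeds the threshold anywhere."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    kept, rejected = [], []
    for ep in epochs:
        (rejected if np.abs(ep.data).max() > threshold_uv else kept).append(ep)
    return kept, rejected
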