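"""Log-Mel feature extraction, a reference confidence-emitting detector,
the softmax confidence map, and the accumulator decision rule.

The spectrogram dialect is pinned explicitly because only the FFT length
(2048), hop (345 samples) and mel-band count (128) are fixed by the
analysis protocol: Hann window, no center padding (so a 1-s clip at
44.1 kHz yields floor((44100-2048)/345)+1 = 122 frames), power spectrum,
triangular mel filters spanning 0–22050 Hz, natural-log compression with
floor 1e-10.

The detector is deliberately plain artifact plumbing — a two-block
convolutional network with global average pooling and a linear head —
standing in for any full-scale sound-event-detection backbone; anything
that emits a (noise, target) logit pair honours the same contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from ._nn import Tensor
from .synthio import AUDIO_SR

__all__ = [
    "LogMelParams",
    "ConfidencePair",
    "AccumulatorState",
    "DetectorConfig",
    "DetectorTrainConfig",
    "Detector",
    "NoQualifyingCheckpoint",
    "mel_filterbank",
    "logmel",
    "confidence",
    "detector_forward",
    "train_detector",
    "accumulate",
    "save_detector",
    "load_detector",
]


@dataclass(frozen=True)
class LogMelParams:
    sr: int = AUDIO_SR
    n_fft: int = 2048
    hop: int = 345
    n_mels: int = 128
    eps: float = 1e-10


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def rms_normalize(wave: np.ndarray) -> np.ndarray:
    """Scale a waveform to unit RMS (automatic gain control for analysis
    windows; keeps within-window SNR intact)."""
    rms = np.sqrt((np.asarray(wave, dtype=np.float64) ** 2).mean())
    if rms <= 0:
        return np.asarray(wave, dtype=np.float64)
    return wave / rms


def mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular mel filters on FFT bins, 0 Hz to Nyquist, unnormalised."""
    n_bins = n_fft // 2 + 1
    fft_freqs = np.linspace(0, sr / 2, n_bins)
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sr / 2), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0, None)
    return fb


_FB_CACHE: dict[tuple, np.ndarray] = {}


def logmel(clip: np.ndarray, params: LogMelParams | None = None) -> np.ndarray:
    """Log-power mel spectrogram (n_mels × frames) of a 1-s clip."""
    p = params or LogMelParams()
    clip = np.asarray(clip, dtype=np.float64)
    if clip.ndim != 1 or len(clip) != p.sr:
        raise ValueError(f"expected a mono clip of exactly {p.sr} samples")
    n_frames = (len(clip) - p.n_fft) // p.hop + 1
    idx = np.arange(p.n_fft)[None, :] + p.hop * np.arange(n_frames)[:, None]
    frames = clip[idx] * np.hanning(p.n_fft)[None, :]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2      # (frames, bins)
    key = (p.sr, p.n_fft, p.n_mels)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(*key)
    mel = power @ _FB_CACHE[key].T                         # (frames, mels)
    return np.log(np.maximum(mel, p.eps)).T                # (mels, frames)


@dataclass(frozen=True)
class ConfidencePair:
    p1: float   # noise-class confidence
    p2: float   # target-class confidence
    label: int  # 0 noise, 1 target


def confidence(x1: float, x2: float) -> ConfidencePair:
    """Map a (noise, target) logit pair to softmax confidences.

    Class is target iff x1 < x2; stabilised by max-subtraction.
    """
    if not (np.isfinite(x1) and np.isfinite(x2)):
        raise ValueError("logits must be finite")
    m = max(x1, x2)
    e1, e2 = np.exp(x1 - m), np.exp(x2 - m)
    p1 = e1 / (e1 + e2)
    return ConfidencePair(float(p1), float(1.0 - p1), int(x1 < x2))


# ---------------------------------------------------------------------------
# reference detector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorConfig:
    channels: tuple[int, int] = (16, 32)
    kernel: int = 3
    stride: int = 2
    hidden: int = 32
    seed: int = 0


class Detector(_nn.Module):
    """Two strided conv blocks + global average pooling + a small head.

    Inputs are standardised per mel bin with statistics learned from the
    training set (stored on the model as ``norm``), which flattens the
    strong low-frequency tilt of wind-like noise.
    """

    def __init__(self, cfg: DetectorConfig | None = None):
        self.cfg = cfg or DetectorConfig()
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        k, s = c.kernel, c.stride
        self.conv1 = _nn.Conv2d(1, c.channels[0], k, k, rng,
                                stride=(s, s), pad=(k // 2, k // 2))
        self.bn1 = _nn.BatchNorm(c.channels[0])
        self.conv2 = _nn.Conv2d(c.channels[0], c.channels[1], k, k, rng,
                                stride=(s, s), pad=(k // 2, k // 2))
        self.bn2 = _nn.BatchNorm(c.channels[1])
        self.fc1 = _nn.Linear(c.channels[1], c.hidden, rng)
        self.fc = _nn.Linear(c.hidden, 2, rng)
        self.norm: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, specs: np.ndarray, train: bool = False) -> Tensor:
        x = Tensor(np.asarray(specs)[:, None, :, :])
        h = self.bn1(self.conv1(x), train).elu()
        h = self.bn2(self.conv2(h), train).elu()
        return self.fc(self.fc1(h.mean(axis=(2, 3))).elu())


def detector_forward(spec: np.ndarray, model: Detector) -> tuple[float, float]:
    """Logits (x1 noise, x2 target) for one mel_bins × frames spectrogram."""
    spec = np.asarray(spec)
    if spec.ndim != 2:
        raise ValueError("expected a single mel_bins × frames spectrogram")
    logits = model.forward(spec[None]).data[0]
    return float(logits[0]), float(logits[1])


class NoQualifyingCheckpoint(RuntimeError):
    """No epoch satisfied the validation FAR/recall checkpoint rule."""


@dataclass(frozen=True)
class DetectorTrainConfig:
    """Training protocol; reference values are lr 1e-5 / batch 64 / 300
    epochs, with an explicit desk-scale override used in simulation."""

    learning_rate: float = 1e-5
    batch_size: int = 64
    epochs: int = 300
    val_fraction: float = 0.2
    far_ceiling: float = 0.10
    recall_floor: float = 0.90
    seed: int = 0

    @staticmethod
    def desk_scale(epochs: int = 25, learning_rate: float = 1e-3,
                   seed: int = 0) -> "DetectorTrainConfig":
        return DetectorTrainConfig(learning_rate=learning_rate, epochs=epochs,
                                   seed=seed)


def _val_metrics(model: Detector, specs: np.ndarray, y: np.ndarray):
    logits = model.forward(specs).data
    pred = (logits[:, 1] > logits[:, 0]).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    far = fp / (fp + tn) if fp + tn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * recall / (prec + recall) if prec + recall else 0.0
    return recall, far, f1


def train_detector(specs: np.ndarray, labels: np.ndarray,
                   cfg: DetectorTrainConfig | None = None,
                   model_cfg: DetectorConfig | None = None
                   ) -> tuple[Detector, dict]:
    """Train on an 80/20 split; checkpoints are saved only at epochs whose
    validation FAR < 10% and recall > 90%, and the best saved checkpoint by
    validation F1 is returned.  Raises :class:`NoQualifyingCheckpoint` if
    no epoch qualifies."""
    cfg = cfg or DetectorTrainConfig()
    specs = np.asarray(specs, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(y))
    n_val = int(round(cfg.val_fraction * len(y)))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    model = Detector(model_cfg or DetectorConfig(seed=cfg.seed))
    opt = _nn.Adam(model.parameters(), lr=cfg.learning_rate)
    best = None
    history = {"val_recall": [], "val_far": [], "val_f1": [],
               "n_train": len(tr_idx), "n_val": len(val_idx)}
    # per-mel-bin standardisation from the training split
    mu = specs[tr_idx].mean(axis=(0, 2))[:, None]
    sd = specs[tr_idx].std(axis=(0, 2))[:, None] + 1e-9
    zs = (specs - mu) / sd
    for _epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        for i in range(0, len(order), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            logits = model.forward(zs[b], train=True)
            loss = _nn.softmax_cross_entropy(logits, y[b])
            opt.zero_grad()
            loss.backward()
            opt.step()
        recall, far, f1 = _val_metrics(model, zs[val_idx], y[val_idx])
        history["val_recall"].append(recall)
        history["val_far"].append(far)
        history["val_f1"].append(f1)
        if far < cfg.far_ceiling and recall > cfg.recall_floor:
            if best is None or f1 > best[0]:
                best = (f1, model.state())
    if best is None:
        raise NoQualifyingCheckpoint(
            f"no epoch reached FAR < {cfg.far_ceiling} and recall > "
            f"{cfg.recall_floor} on the validation split")
    model.load_state(best[1])
    history["best_val_f1"] = best[0]
    model.norm = (mu, sd)
    return model, history


def normalize_spec(spec: np.ndarray, model: Detector) -> np.ndarray:
    """Apply the detector's training-time per-bin z-scoring, if any."""
    if getattr(model, "norm", None) is None:
        return spec
    mu, sd = model.norm
    return (spec - mu) / sd


# ---------------------------------------------------------------------------
# accumulator
# ---------------------------------------------------------------------------

@dataclass
class AccumulatorState:
    """Sliding count of target-class frame decisions.

    The decision is Target iff the number of target frames inside the
    window strictly exceeds ``threshold``.  ``window`` = 30 frames (3 s at
    the 0.1-s frame cadence) matches the target-clip duration; mode
    'cumulative_reset' instead counts since the last noise frame.
    """

    threshold: int = 3
    window: int = 30
    mode: str = "sliding"           # 'sliding' | 'cumulative_reset'
    buffer: list = field(default_factory=list)
    count: int = 0


def accumulate(state: AccumulatorState, frame_class: int
               ) -> tuple[AccumulatorState, str]:
    if frame_class not in (0, 1):
        raise ValueError("frame class must be 0 or 1")
    if state.mode == "sliding":
        state.buffer.append(frame_class)
        if len(state.buffer) > state.window:
            state.buffer.pop(0)
        state.count = sum(state.buffer)
    elif state.mode == "cumulative_reset":
        state.count = state.count + 1 if frame_class == 1 else 0
    else:
        raise ValueError(f"unknown accumulator mode {state.mode!r}")
    decision = "Target" if state.count > state.threshold else "NoTarget"
    return state, decision


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_detector(path: str, model: Detector) -> None:
    meta = {"config": model.cfg.__dict__ | {"channels": list(model.cfg.channels)}}
    arrays = {f"arr{i}": a for i, a in enumerate(model.state())}
    if getattr(model, "norm", None) is not None:
        arrays["norm_mu"], arrays["norm_sd"] = model.norm
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_detector(path: str) -> Detector:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    c = dict(meta["config"])
    c["channels"] = tuple(c["channels"])
    model = Detector(DetectorConfig(**c))
    n = len([k for k in z.files if k.startswith("arr")])
    model.load_state([z[f"arr{i}"] for i in range(n)])
    if "norm_mu" in z.files:
        model.norm = (z["norm_mu"], z["norm_sd"])
    return model
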