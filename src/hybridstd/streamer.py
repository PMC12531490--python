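"""Streaming-mode detection: sliding-window EEG decode cycles with
majority voting, frame-wise audio detection with the accumulator, hybrid
arbitration via the calibrated confidence interval, and event-level
recall/FAR scoring.

Protocol: EEG is consumed in 2-s windows advancing by 1 s; each window is
cut into 11 overlapping 1-s segments (0.1-s step) that are decoded
independently, and the cycle outputs Target iff more than 5 of the 11
segments are classified target.  Audio is consumed in 1-s frames
advancing by 0.1 s; each frame's class feeds the accumulator.  The hybrid
stream applies the result selector per audio frame, holding the most
recent EEG decision.  An event counts as recalled iff at least one Target
output falls within 3 s of its onset; Target outputs outside every such
window are false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .acoustic import (AccumulatorState, Detector, accumulate, confidence,
                       logmel, normalize_spec, rms_normalize)
from .eegprep import RegionPartition
from .fusion import FusionCalibration, select_result
from .synthio import AUDIO_SR
from .trisdanet import TriSdanet

__all__ = [
    "Decision",
    "EventScore",
    "segment_cycle",
    "vote",
    "run_bci_stream",
    "run_auto_stream",
    "run_hybrid",
    "score",
    "window_count",
]

SEEN_TYPES = frozenset({1, 2, 3})


@dataclass(frozen=True)
class Decision:
    t: float            # decision timestamp, seconds
    source: str         # 'bci' | 'auto' | 'hybrid'
    decision: str       # 'Target' | 'NoTarget'
    frame_class: int | None = None
    p1: float | None = None


def window_count(length_s: float, window_s: float, step_s: float) -> int:
    """Number of full windows: floor((L - w)/s) + 1 (0 if L < w)."""
    if length_s < window_s:
        return 0
    return int(np.floor((length_s - window_s) / step_s + 1e-9)) + 1


def segment_cycle(window: np.ndarray, srate: float) -> list[np.ndarray]:
    """Cut a 2-s multichannel window into 11 overlapping 1-s segments at
    offsets 0.0, 0.1, …, 1.0 s (half-open intervals)."""
    window = np.asarray(window)
    n2 = int(round(2.0 * srate))
    if window.shape[-1] != n2:
        raise ValueError(f"window must be exactly 2 s ({n2} samples), "
                         f"got {window.shape[-1]}")
    w = int(round(srate))
    segs = []
    for i in range(11):
        start = int(round(i * 0.1 * srate))
        segs.append(window[..., start:start + w])
    return segs


def vote(segment_labels) -> str:
    """Target iff strictly more than 5 of the 11 segments say target."""
    labels = list(segment_labels)
    if len(labels) != 11:
        raise ValueError("exactly 11 segment labels required")
    return "Target" if sum(int(l) for l in labels) >= 6 else "NoTarget"


def run_bci_stream(eeg: np.ndarray, model: TriSdanet,
                   partition: RegionPartition | None = None,
                   srate: float = 100.0,
                   threshold: float = 0.5) -> list[Decision]:
    """Decode a continuous 60-channel signal: one voted decision per
    second, the first at t = 2 s.

    ``threshold`` sets the segment-level operating point: a segment is
    called target iff P(target) ≥ threshold (0.5 = argmax; a validation-
    calibrated equal-error threshold balances TPR against FPR).
    """
    eeg = np.asarray(eeg)
    n = eeg.shape[-1]
    n2 = int(round(2.0 * srate))
    log: list[Decision] = []
    n_windows = window_count(n / srate, 2.0, 1.0)
    all_segs = []
    for k in range(n_windows):
        start = int(round(k * 1.0 * srate))
        all_segs.extend(segment_cycle(eeg[:, start:start + n2], srate))
    if not all_segs:
        return log
    probs = model.predict_proba(np.stack(all_segs))
    labels = (probs[:, 1] >= threshold).astype(int)
    for k in range(n_windows):
        seg_labels = labels[k * 11:(k + 1) * 11]
        log.append(Decision(t=float(k + 2.0), source="bci",
                            decision=vote(seg_labels)))
    return log


def run_auto_stream(audio: np.ndarray, detector: Detector,
                    accumulator: AccumulatorState | None = None,
                    sr: int = AUDIO_SR, batch: int = 128) -> list[Decision]:
    """Frame-wise detection (1-s window, 0.1-s step): logits → confidence
    → class, accumulator decision per frame."""
    audio = np.asarray(audio, dtype=np.float64)
    if len(audio) < sr:
        raise ValueError("audio must be at least 1 s long")
    step = int(round(0.1 * sr))
    n_frames = window_count(len(audio) / sr, 1.0, 0.1)
    specs = np.stack([
        normalize_spec(logmel(rms_normalize(audio[k * step:k * step + sr])),
                       detector)
        for k in range(n_frames)])
    logits = np.concatenate([detector.forward(specs[i:i + batch]).data
                             for i in range(0, n_frames, batch)])
    state = accumulator or AccumulatorState()
    log: list[Decision] = []
    for k in range(n_frames):
        pair = confidence(float(logits[k, 0]), float(logits[k, 1]))
        state, decision = accumulate(state, pair.label)
        log.append(Decision(t=float(k * 0.1), source="auto",
                            decision=decision, frame_class=pair.label,
                            p1=pair.p1))
    return log


def run_hybrid(bci_log: list[Decision], auto_log: list[Decision],
               calib: FusionCalibration) -> list[Decision]:
    """Apply the result selector per audio frame, holding the most recent
    BCI decision (hold-last-value alignment)."""
    if not bci_log:
        warnings.warn("empty BCI log; hybrid stream falls back to the "
                      "automatic stream", stacklevel=2)
        return [Decision(d.t, "hybrid", d.decision, d.frame_class, d.p1)
                for d in auto_log]
    bci_sorted = sorted(bci_log, key=lambda d: d.t)
    bts = np.array([d.t for d in bci_sorted])
    out: list[Decision] = []
    for d in auto_log:
        i = int(np.searchsorted(bts, d.t + 1e-9)) - 1
        if i < 0:
            chosen = d.decision
        else:
            chosen = select_result(d.p1, d.decision, bci_sorted[i].decision,
                                   calib)
        out.append(Decision(d.t, "hybrid", chosen, d.frame_class, d.p1))
    return out


@dataclass(frozen=True)
class EventScore:
    events: list
    detected: list
    recall: float
    far: float
    false_alarms: int
    n_outside: int
    subsets: dict = field(default_factory=dict)


def score(decision_log: list[Decision], events: list, recall_window_s: float = 3.0
          ) -> EventScore:
    """Event-level recall and frame-level FAR.

    An event (onset, dur, type, snr) is detected iff ≥1 Target output lies
    in [onset, onset + recall_window_s]; each Target output is credited to
    at most one (the earliest containing) event window.  FAR is the
    fraction of outputs outside all event windows that say Target.
    """
    log = sorted(decision_log, key=lambda d: d.t)
    onsets = [e[0] for e in events]
    if any(onsets[i] > onsets[i + 1] for i in range(len(onsets) - 1)):
        raise ValueError("events must be sorted by onset")
    detected = [False] * len(events)
    false_alarms = 0
    n_outside = 0
    for d in log:
        containing = [i for i, on in enumerate(onsets)
                      if on <= d.t <= on + recall_window_s]
        if containing:
            if d.decision == "Target":
                detected[containing[0]] = True
        else:
            n_outside += 1
            if d.decision == "Target":
                false_alarms += 1
    recall = float(np.mean(detected)) if events else 0.0
    far = false_alarms / n_outside if n_outside else 0.0
    subsets: dict = {}
    for name, pred in (("seen", lambda e: e[2] in SEEN_TYPES),
                       ("unseen", lambda e: e[2] not in SEEN_TYPES)):
        for snr in sorted({e[3] for e in events}):
            sel = [i for i, e in enumerate(events) if pred(e) and e[3] == snr]
            if sel:
                subsets[f"{name}@{snr:g}dB"] = float(
                    np.mean([detected[i] for i in sel]))
        sel = [i for i, e in enumerate(events) if pred(e)]
        if sel:
            subsets[name] = float(np.mean([detected[i] for i in sel]))
    return EventScore(events=list(events), detected=detected, recall=recall,
                      far=far, false_alarms=false_alarms, n_outside=n_outside,
                      subsets=subsets)
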