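"""Tri-SDANet: a region-partitioned spatiotemporal attention network for
single-trial auditory target decoding from 60-channel EEG.

Five stages, each with an ablation switch:

* **NSP** — neuroanatomy-based spatial partitioning into temporal, frontal
  and parieto-occipital 20-channel blocks (ablated: fixed random groups).
* **RSF** — region-specific spatiotemporal filtering: one spatial
  convolution per region (temporal: full-height kernel 20, no padding;
  frontal: kernel 10 with symmetric padding 4; parieto-occipital: kernel 5
  with stride 2) followed by region-matched temporal convolutions
  (15/25/35 samples, i.e. 150/250/350 ms at 100 Hz), BN, ELU, dropout.
* **DAW** — dynamic attention weighting: early/mid/late temporal
  convolutions (15/35/55 samples) over the concatenated branch features,
  fused with softmax attention weights (ablated: unweighted sum).
* **TG** — temporal gating: a learnable sigmoid mask applied inside a
  configurable post-onset window, identity outside (ablated: identity).
* **DS-TCN head** — depthwise + pointwise temporal convolution, global
  average pooling over time, and a two-layer classification head
  (ablated: pooling + head only).

The residual spatial axes of the three branches (1/19/8) are mean-pooled
away before concatenation so the attention stage sees three feature maps
of identical layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Tensor
from .eegprep import EEGEpoch, RegionPartition, build_partition

__all__ = [
    "TriSdanetConfig",
    "TrainConfig",
    "DecodeOutput",
    "TriSdanet",
    "nsp_split",
    "train",
    "evaluate",
    "metrics_from_counts",
    "stratified_split",
    "save_checkpoint",
    "load_checkpoint",
]

_LABEL_TO_CLASS = {"nontarget": 0, "target": 1}
REGIONS = ("T", "F", "P")


@dataclass(frozen=True)
class TriSdanetConfig:
    spatial_filters: int = 16
    temporal_filters: int = 16
    temporal_kernels: dict = field(default_factory=lambda: {"T": 15, "F": 25, "P": 35})
    attention_kernels: dict = field(default_factory=lambda: {"E": 15, "M": 35, "L": 55})
    dropout_p: float = 0.5
    gate_window_ms: tuple[float, float] = (100.0, 500.0)
    dstcn_depth_kernel: int = 15
    dstcn_point_filters: int = 32
    hidden_units: int = 64
    n_classes: int = 2
    ablation: frozenset = frozenset()

    def __post_init__(self):
        for k in list(self.temporal_kernels.values()) + \
                list(self.attention_kernels.values()) + [self.dstcn_depth_kernel]:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel lengths must be odd and >= 1, got {k}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        bad = set(self.ablation) - {"NSP", "RSF", "DAW", "TG", "DSTCN"}
        if bad:
            raise ValueError(f"unknown ablation switches: {bad}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 200
    learning_rate: float = 1e-3
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class DecodeOutput:
    probs: np.ndarray
    label: int


def nsp_split(epoch: EEGEpoch | np.ndarray, partition: RegionPartition
              ) -> dict[str, np.ndarray]:
    """Split a 60 × T array into three 20 × T region blocks in the
    partition's canonical channel order."""
    data = epoch.data if isinstance(epoch, EEGEpoch) else np.asarray(epoch)
    if data.shape[0] != 60:
        raise ValueError("expected 60 channels")
    return {r: data[partition.region_order[r], :] for r in REGIONS}


# spatial-stage geometry per region: (kernel height, channel pad, stride)
_SPATIAL_GEOM = {"T": (20, 0, 1), "F": (10, 4, 1), "P": (5, 0, 2)}


class TriSdanet(_nn.Module):
    def __init__(self, cfg: TriSdanetConfig | None = None,
                 partition: RegionPartition | None = None,
                 srate: float = 100.0, n_times: int = 100, seed: int = 0):
        self.cfg = cfg or TriSdanetConfig()
        self.partition = partition or build_partition_default()
        self.srate, self.n_times, self.seed = srate, n_times, seed
        rng = np.random.default_rng(seed)
        c = self.cfg
        ab = c.ablation

        if "NSP" in ab:
            # random-but-fixed 20-channel groups, seeded at construction
            perm = rng.permutation(60)
            self._groups = {r: perm[i * 20:(i + 1) * 20] for i, r in enumerate(REGIONS)}
        else:
            self._groups = {r: np.asarray(self.partition.region_order[r])
                            for r in REGIONS}

        if "RSF" not in ab:
            self.spatial = {}
            self.temporal = {}
            self.bn_rsf = {}
            for r in REGIONS:
                kh, ph, sh = _SPATIAL_GEOM[r]
                self.spatial[r] = _nn.Conv2d(1, c.spatial_filters, kh, 1, rng,
                                             stride=(sh, 1), pad=(ph, 0))
                kt = c.temporal_kernels[r]
                self.temporal[r] = _nn.Conv2d(c.spatial_filters, c.temporal_filters,
                                              1, kt, rng, pad=(0, kt // 2))
                self.bn_rsf[r] = _nn.BatchNorm(c.temporal_filters)
            branch_c = c.temporal_filters
        else:
            # fallback: a single shared spatial projection per region (mean
            # over channels), no learned filtering
            branch_c = 1
        self._branch_c = branch_c
        concat_c = 3 * branch_c

        d = c.temporal_filters
        self._daw_c = d
        self.daw_convs = []
        for s in ("E", "M", "L"):
            ks = c.attention_kernels[s]
            self.daw_convs.append(_nn.Conv2d(concat_c, d, 1, ks, rng,
                                             pad=(0, ks // 2)))
        self.daw_wa = _nn.Linear(3 * d, 3, rng)

        # temporal gate mask, learnable inside the gate window only
        lo = int(round(c.gate_window_ms[0] / 1000.0 * srate))
        hi = int(round(c.gate_window_ms[1] / 1000.0 * srate))
        lo, hi = max(lo, 0), min(hi, n_times)
        if hi <= lo:
            raise ValueError("empty gate window")
        wmask = np.zeros((1, 1, 1, n_times))
        wmask[..., lo:hi] = 1.0
        self._gate_mask = wmask
        self.gate_m = Tensor(np.zeros((1, 1, 1, n_times)), requires_grad=True)

        if "DSTCN" not in ab:
            self.depthwise = _nn.DepthwiseConv1d(d, c.dstcn_depth_kernel, rng)
            self.bn_d = _nn.BatchNorm(d)
            self.pointwise = _nn.Conv2d(d, c.dstcn_point_filters, 1, 1, rng)
            self.bn_p = _nn.BatchNorm(c.dstcn_point_filters)
            head_in = c.dstcn_point_filters
        else:
            head_in = d
        self.fc1 = _nn.Linear(head_in, c.hidden_units, rng)
        self.fc2 = _nn.Linear(c.hidden_units, c.n_classes, rng)

    # -- stages ------------------------------------------------------------
    def split_blocks(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """(N, 60, T) -> region blocks (N, 1, 20, T)."""
        return {r: x[:, self._groups[r], :][:, None, :, :] for r in REGIONS}

    def rsf_forward(self, blocks: dict[str, np.ndarray], train: bool,
                    rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        c = self.cfg
        out = {}
        for r in REGIONS:
            xb = Tensor(blocks[r])
            if xb.data.shape[-1] < max(c.temporal_kernels.values()):
                raise ValueError("epoch shorter than the largest temporal kernel")
            if "RSF" in c.ablation:
                out[r] = xb.mean(axis=2, keepdims=True)
                continue
            f = self.spatial[r](xb).elu()
            t = self.bn_rsf[r](self.temporal[r](f), train).elu()
            if train and c.dropout_p > 0:
                mask = (rng.random(t.data.shape) >= c.dropout_p) / (1 - c.dropout_p)
                t = t * Tensor(mask)
            out[r] = t
        return out

    def daw_forward(self, branch: dict[str, Tensor], train: bool
                    ) -> tuple[Tensor, np.ndarray]:
        # pool the residual spatial axis, concatenate on the feature axis
        pooled = [branch[r].mean(axis=2, keepdims=True) for r in REGIONS]
        fcat = _nn.concat(pooled, axis=1)            # (N, 3D or 3, 1, T)
        scales = [conv(fcat) for conv in self.daw_convs]
        if "DAW" in self.cfg.ablation:
            a = scales[0] + scales[1] + scales[2]
            n = fcat.data.shape[0]
            return a, np.full((n, 3), np.nan)
        summaries = _nn.concat([s.mean(axis=(2, 3)) for s in scales], axis=1)
        logits = self.daw_wa(summaries)              # (N, 3)
        alpha = _nn.softmax(logits, axis=1)
        parts = []
        for i, s in enumerate(scales):
            a_i = alpha.slice((slice(None), slice(i, i + 1))).reshape(-1, 1, 1, 1)
            parts.append(a_i * s)
        a = parts[0] + parts[1] + parts[2]
        return a, alpha.data.copy()

    def tg_forward(self, a: Tensor) -> Tensor:
        if "TG" in self.cfg.ablation:
            return a
        m_eff = self.gate_m * Tensor(self._gate_mask) + Tensor(1.0 - self._gate_mask)
        gate = (m_eff * a).sigmoid()
        return gate * a

    def dstcn_head(self, g: Tensor, train: bool) -> Tensor:
        if "DSTCN" not in self.cfg.ablation:
            h = self.bn_d(self.depthwise(g), train).elu()
            h = self.bn_p(self.pointwise(h), train).elu()
        else:
            h = g
        z = h.mean(axis=(2, 3))                      # global average pooling
        h1 = self.fc1(z).elu()
        return self.fc2(h1)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, np.ndarray]:
        """(N, 60, T) -> (logits (N, n_classes), attention weights (N, 3))."""
        blocks = self.split_blocks(np.asarray(x, dtype=np.float64))
        branch = self.rsf_forward(blocks, train, rng)
        a, alpha = self.daw_forward(branch, train)
        g = self.tg_forward(a)
        return self.dstcn_head(g, train), alpha

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch):
            logits, _ = self.forward(x[i:i + batch], train=False)
            outs.append(_nn.softmax(logits, axis=1).data)
        return np.concatenate(outs, axis=0)

    def decode(self, epoch: EEGEpoch) -> DecodeOutput:
        probs = self.predict_proba(epoch.data[None])[0]
        return DecodeOutput(probs=probs, label=int(np.argmax(probs)))


def build_partition_default() -> RegionPartition:
    from .eegprep import STANDARD_60
    return build_partition(list(STANDARD_60))


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, fractions: tuple[float, float, float],
                     seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded per-class split into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr:n_tr + n_va])
        te.extend(idx[n_tr + n_va:])
    return (np.sort(np.asarray(tr, dtype=int)), np.sort(np.asarray(va, dtype=int)),
            np.sort(np.asarray(te, dtype=int)))


def _to_arrays(dataset: list[EEGEpoch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([e.data for e in dataset])
    y = np.asarray([_LABEL_TO_CLASS[e.label] for e in dataset], dtype=int)
    return x, y


def train(dataset: list[EEGEpoch], cfg: TrainConfig | None = None,
          model_cfg: TriSdanetConfig | None = None,
          partition: RegionPartition | None = None
          ) -> tuple[TriSdanet, dict]:
    """Train with cross-entropy + Adam on a stratified 70/10/20 split and
    return the best-validation-accuracy checkpoint plus the history."""
    cfg = cfg or TrainConfig()
    if len(dataset) < 10:
        raise ValueError("dataset too small to split")
    x, y = _to_arrays(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    itr, iva, ite = stratified_split(y, cfg.split, cfg.seed)
    model = TriSdanet(model_cfg, partition, srate=dataset[0].srate,
                      n_times=x.shape[-1], seed=cfg.seed)
    opt = _nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_loss": [], "train_acc": [], "val_acc": [],
               "split_sizes": (len(itr), len(iva), len(ite))}
    best_acc, best_state = -1.0, None
    for _epoch in range(cfg.epochs):
        order = rng.permutation(itr)
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            bidx = order[i:i + cfg.batch_size]
            logits, _ = model.forward(x[bidx], train=True, rng=rng)
            loss = _nn.softmax_cross_entropy(logits, y[bidx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[bidx]).sum())
        val_pred = model.predict_proba(x[iva]).argmax(axis=1)
        val_acc = float((val_pred == y[iva]).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(order))
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state()
    if best_state is not None:
        model.load_state(best_state)
    history["best_val_acc"] = best_acc
    history["test_idx"] = ite
    return model, history


def metrics_from_counts(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    total = tp + fn + fp + tn
    acc = (tp + tn) / total if total else 0.0
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * tpr / (prec + tpr) if prec + tpr else 0.0
    return {"accuracy": acc, "TPR": tpr, "FPR": fpr, "F1": f1}


def evaluate(model: TriSdanet, epochs: list[EEGEpoch]) -> dict[str, float]:
    x, y = _to_arrays(epochs)
    pred = model.predict_proba(x).argmax(axis=1)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return metrics_from_counts(tp, fn, fp, tn)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, model: TriSdanet, history: dict | None = None) -> None:
    cfg = model.cfg
    meta = {
        "config": {
            "spatial_filters": cfg.spatial_filters,
            "temporal_filters": cfg.temporal_filters,
            "temporal_kernels": cfg.temporal_kernels,
            "attention_kernels": cfg.attention_kernels,
            "dropout_p": cfg.dropout_p,
            "gate_window_ms": list(cfg.gate_window_ms),
            "dstcn_depth_kernel": cfg.dstcn_depth_kernel,
            "dstcn_point_filters": cfg.dstcn_point_filters,
            "hidden_units": cfg.hidden_units,
            "n_classes": cfg.n_classes,
            "ablation": sorted(cfg.ablation),
        },
        "srate": model.srate,
        "n_times": model.n_times,
        "seed": model.seed,
        "history": {k: v for k, v in (history or {}).items()
                    if k in ("train_loss", "train_acc", "val_acc", "best_val_acc")},
    }
    arrays = {f"arr{i}": a for i, a in enumerate(model.state())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> TriSdanet:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    c = meta["config"]
    cfg = TriSdanetConfig(
        spatial_filters=c["spatial_filters"],
        temporal_filters=c["temporal_filters"],
        temporal_kernels=c["temporal_kernels"],
        attention_kernels=c["attention_kernels"],
        dropout_p=c["dropout_p"],
        gate_window_ms=tuple(c["gate_window_ms"]),
        dstcn_depth_kernel=c["dstcn_depth_kernel"],
        dstcn_point_filters=c["dstcn_point_filters"],
        hidden_units=c["hidden_units"],
        n_classes=c["n_classes"],
        ablation=frozenset(c["ablation"]),
    )
    model = TriSdanet(cfg, srate=meta["srate"], n_times=meta["n_times"],
                      seed=meta["seed"])
    n = len([k for k in z.files if k.startswith("arr")])
    model.load_state([z[f"arr{i}"] for i in range(n)])
    return model
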