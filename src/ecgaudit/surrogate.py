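"""Trainable 1-D residual-network surrogate with a 0-100 risk score.

Architecture: a stem block (conv / norm / nonlinearity / pooling), four
feature blocks of exactly three pre-activation residual blocks each
(spatial downsampling x2 at each feature-block entry), and a fully
connected head whose sigmoid output is scaled to a 0-100 score.  Scores at
or above the operating threshold (default 9.7) are called high risk.

Per-block pooled activations (global average over time) are the feature
spaces used by the attribution and clustering stages.
"""

from __future__ import annotations

import json
import zipfile
import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .records import ECGRecord

__all__ = [
    "DEFAULT_THRESHOLD",
    "SurrogateConfig",
    "TrainConfig",
    "ScoreOutput",
    "ActivationVector",
    "Surrogate",
    "build_surrogate",
    "train_surrogate",
    "predict_scores",
    "classify_risk",
    "extract_activations",
    "save_checkpoint",
    "load_checkpoint",
]

#: Operating threshold on the 0-100 score; scores >= threshold are high risk.
DEFAULT_THRESHOLD = 9.7

N_FEATURE_BLOCKS = 4
RESIDUAL_BLOCKS_PER_FEATURE_BLOCK = 3


@dataclass(frozen=True)
class SurrogateConfig:
    """Desk-scale defaults: channels doubling over four blocks, 12x2500 input."""

    channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel: int = 7
    n_leads: int = 12
    n_samples: int = 2500
    sampling_rate: float = 250.0
    stem_channels: int = 16
    score_scale: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != N_FEATURE_BLOCKS:
            raise ValueError("exactly four feature blocks are required")
        if self.n_leads != 12:
            raise ValueError("the surrogate is a 12-lead model")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.25
    early_stop_auroc: float | None = 0.98
    seed: int = 0


@dataclass(frozen=True)
class ScoreOutput:
    record_id: str
    score: float
    risk_class: str  # "high" | "low"
    threshold_used: float


@dataclass(frozen=True)
class ActivationVector:
    record_id: str
    block_index: int  # 1-4
    vector: np.ndarray


class _ResidualBlock(nn.Layer):
    """Pre-activation residual block: BN-ReLU-Conv / BN-ReLU-Conv + shortcut."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 *, rng: np.random.Generator):
        self.path = nn.Sequential(
            nn.BatchNorm1d(c_in),
            nn.ReLU(),
            nn.Conv1d(c_in, c_out, kernel, stride=stride, rng=rng),
            nn.BatchNorm1d(c_out),
            nn.ReLU(),
            nn.Conv1d(c_out, c_out, kernel, stride=1, rng=rng),
        )
        if stride != 1 or c_in != c_out:
            self.shortcut = nn.Conv1d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
        else:
            self.shortcut = None

    def params(self):
        ps = self.path.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def set_mode(self, train: bool) -> None:
        self.path.set_mode(train)
        if self.shortcut is not None:
            self.shortcut.set_mode(train)

    def forward(self, x):
        main = self.path.forward(x)
        skip = x if self.shortcut is None else self.shortcut.forward(x)
        return main + skip

    def backward(self, gout):
        gx = self.path.backward(gout)
        if self.shortcut is None:
            gx = gx + gout
        else:
            gx = gx + self.shortcut.backward(gout)
        return gx


class Surrogate:
    """Model handle: stem + four feature blocks + fully connected head."""

    def __init__(self, config: SurrogateConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        self.stem = nn.Sequential(
            nn.Conv1d(config.n_leads, config.stem_channels, k, stride=2, rng=rng),
            nn.BatchNorm1d(config.stem_channels),
            nn.ReLU(),
            nn.MaxPool1d(2),
        )
        self.feature_blocks: list[nn.Sequential] = []
        c_prev = config.stem_channels
        for c in config.channels:
            blocks = [_ResidualBlock(c_prev, c, k, stride=2, rng=rng)]
            for _ in range(RESIDUAL_BLOCKS_PER_FEATURE_BLOCK - 1):
                blocks.append(_ResidualBlock(c, c, k, stride=1, rng=rng))
            self.feature_blocks.append(nn.Sequential(*blocks))
            c_prev = c
        self.head = nn.Sequential(
            nn.BatchNorm1d(c_prev),
            nn.ReLU(),
            nn.GlobalAvgPool1d(),
            nn.Linear(c_prev, 1, rng=rng),
        )
        self.trained = False

    # -- plumbing -----------------------------------------------------------

    def _modules(self):
        return [self.stem, *self.feature_blocks, self.head]

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def set_mode(self, train: bool) -> None:
        for m in self._modules():
            m.set_mode(train)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.n_leads or x.shape[2] != self.config.n_samples:
            raise ValueError(
                f"expected input of shape (batch, {self.config.n_leads}, "
                f"{self.config.n_samples}), got {tuple(x.shape)}"
            )
        return x

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return logits of shape (batch,)."""
        x = self._check_input(x)
        self.set_mode(train)
        h = self.stem.forward(x)
        self._block_outputs = []
        for blk in self.feature_blocks:
            h = blk.forward(h)
            self._block_outputs.append(h)
        return self.head.forward(h)[:, 0]

    def backward_from_logits(self, glogits: np.ndarray) -> list[np.ndarray]:
        """Backprop; returns the gradient at each feature-block output."""
        g = self.head.backward(glogits[:, None])
        block_grads: list[np.ndarray | None] = [None] * N_FEATURE_BLOCKS
        for i in range(N_FEATURE_BLOCKS - 1, -1, -1):
            block_grads[i] = g
            g = self.feature_blocks[i].backward(g)
        self.stem.backward(g)
        return block_grads  # type: ignore[return-value]

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid of the logit scaled to [0, score_scale]; monotone in the logit."""
        z = self.logits(x).astype(np.float64)
        return self.config.score_scale / (1.0 + np.exp(-z))

    def pooled_activations(self, x: np.ndarray, block_index: int) -> np.ndarray:
        """(batch, channels[block]) global-average-pooled block output."""
        _validate_block_index(block_index)
        self.forward(x, train=False)
        return self._block_outputs[block_index - 1].mean(axis=2).astype(np.float64)

    def pooled_activations_all_blocks(self, x: np.ndarray) -> list[np.ndarray]:
        """Pooled activations of all four blocks from a single forward pass."""
        self.forward(x, train=False)
        return [h.mean(axis=2).astype(np.float64) for h in self._block_outputs]

    def pooled_logit_gradients(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Per-record gradient of the logit w.r.t. each block's pooled activation.

        A unit perturbation of pooled channel c corresponds to a uniform
        perturbation of that channel across time, so the pooled gradient is
        the time-sum of the feature-map gradient.
        """
        logits = self.forward(x, train=False)
        block_grads = self.backward_from_logits(np.ones_like(logits, dtype=np.float32))
        pooled = [g.sum(axis=2).astype(np.float64) for g in block_grads]
        return logits, pooled


def _validate_block_index(block_index: int) -> None:
    if block_index not in (1, 2, 3, 4):
        raise ValueError(f"block_index must be one of 1, 2, 3, 4; got {block_index}")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_surrogate(config: SurrogateConfig | None = None) -> Surrogate:
    """Deterministically initialize a surrogate from its config seed."""
    return Surrogate(config or SurrogateConfig())


def _stack_records(model: Surrogate, records: Sequence[ECGRecord]) -> np.ndarray:
    cfg = model.config
    sigs = []
    for rec in records:
        if abs(rec.sampling_rate - cfg.sampling_rate) > 1e-9:
            raise ValueError(
                f"record {rec.record_id} sampled at {rec.sampling_rate} Hz but "
                f"the model expects {cfg.sampling_rate} Hz; apply "
                "records.resample_record first"
            )
        if rec.signal.shape != (cfg.n_leads, cfg.n_samples):
            raise ValueError(
                f"record {rec.record_id} has shape {rec.signal.shape}; the model "
                f"expects ({cfg.n_leads}, {cfg.n_samples})"
            )
        sigs.append(rec.signal)
    return np.asarray(sigs, dtype=np.float32)


def train_surrogate(
    model: Surrogate,
    cohort: Sequence[tuple[ECGRecord, object]],
    train_config: TrainConfig | None = None,
) -> tuple[Surrogate, dict]:
    """Train on a labeled cohort; returns the model and a history dict.

    ``cohort`` items are ``(record, metadata)`` where metadata exposes a
    binary ``label`` attribute (or is itself 0/1).  Fully seeded: identical
    (model seed, cohort, train seed) reproduce the history bitwise.
    """
    tc = train_config or TrainConfig()
    records = [rec for rec, _ in cohort]
    labels = np.array([_binary_label(meta) for _, meta in cohort], dtype=np.float32)
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort contains a single class; nothing to learn")

    x = _stack_records(model, records)
    rng = np.random.default_rng(tc.seed)
    n = len(records)
    perm = rng.permutation(n)
    n_hold = max(2, int(round(tc.holdout_fraction * n)))
    hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    # guarantee both classes on each side
    if len(np.unique(labels[hold_idx])) < 2 or len(np.unique(labels[fit_idx])) < 2:
        order = np.argsort(labels, kind="stable")
        interleaved = np.concatenate([order[::2], order[1::2]])
        hold_idx, fit_idx = interleaved[:n_hold], interleaved[n_hold:]

    opt = nn.Adam(model.params(), lr=tc.learning_rate)
    history = {"loss": [], "holdout_auroc": []}
    for epoch in range(tc.epochs):
        batch_order = rng.permutation(len(fit_idx))
        losses = []
        for start in range(0, len(fit_idx), tc.batch_size):
            idx = fit_idx[batch_order[start:start + tc.batch_size]]
            logits = model.forward(x[idx], train=True)
            loss, glog = nn.bce_with_logits(logits, labels[idx])
            opt.zero_grad()
            model.backward_from_logits(glog)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        val_auroc = _auroc(model.logits(x[hold_idx]), labels[hold_idx])
        history["holdout_auroc"].append(val_auroc)
        if tc.early_stop_auroc is not None and val_auroc >= tc.early_stop_auroc:
            break
    model.trained = True
    return model, history


def _binary_label(meta) -> float:
    if hasattr(meta, "label"):
        lab = meta.label
        if isinstance(lab, str):
            return 1.0 if lab.upper() == "LVSD" else 0.0
        return float(lab)
    return float(meta)


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = labels > 0.5
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def predict_scores(
    model: Surrogate,
    records: Sequence[ECGRecord],
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 64,
) -> list[ScoreOutput]:
    """Score records in input order; every score lies in [0, 100]."""
    x = _stack_records(model, records)
    outputs: list[ScoreOutput] = []
    for start in range(0, len(records), batch_size):
        scores = model.scores(x[start:start + batch_size])
        for rec, s in zip(records[start:start + batch_size], scores):
            outputs.append(
                ScoreOutput(
                    record_id=rec.record_id,
                    score=float(s),
                    risk_class=classify_risk(float(s), threshold),
                    threshold_used=threshold,
                )
            )
    return outputs


def classify_risk(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'high' iff score >= threshold (boundary inclusive)."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must be in [0, 100], got {score}")
    return "high" if score >= threshold else "low"


def extract_activations(
    model: Surrogate,
    records: Sequence[ECGRecord],
    block_index: int,
    batch_size: int = 64,
) -> list[ActivationVector]:
    """Global-average-pooled activations of one feature block per record."""
    _validate_block_index(block_index)
    x = _stack_records(model, records)
    out: list[ActivationVector] = []
    for start in range(0, len(records), batch_size):
        acts = model.pooled_activations(x[start:start + batch_size], block_index)
        for rec, a in zip(records[start:start + batch_size], acts):
            out.append(ActivationVector(rec.record_id, block_index, a))
    return out


def extract_activations_all_blocks(
    model: Surrogate,
    records: Sequence[ECGRecord],
    batch_size: int = 64,
) -> list[np.ndarray]:
    """Pooled activations for all four blocks in one forward pass per batch.

    Returns four ``(n_records, channels[b])`` arrays; a cheaper bulk variant
    of :func:`extract_activations` for the attribution pipeline.
    """
    x = _stack_records(model, records)
    chunks: list[list[np.ndarray]] = [[] for _ in range(N_FEATURE_BLOCKS)]
    for start in range(0, len(records), batch_size):
        acts = model.pooled_activations_all_blocks(x[start:start + batch_size])
        for b in range(N_FEATURE_BLOCKS):
            chunks[b].append(acts[b])
    return [np.vstack(c) for c in chunks]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: Surrogate, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for i, bn in enumerate(_iter_batchnorms(model)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    meta = {
        "version": _CKPT_VERSION,
        "trained": model.trained,
        "config": asdict(model.config),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = _io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())
    return path


def load_checkpoint(path: str | Path) -> Surrogate:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(_io.BytesIO(zf.read("arrays.npz")))
        if meta.get("version") != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg_dict = meta["config"]
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        model = Surrogate(SurrogateConfig(**cfg_dict))
        for i, p in enumerate(model.params()):
            p.value = arrays[f"param_{i}"].copy()
        for i, bn in enumerate(_iter_batchnorms(model)):
            bn.running_mean = arrays[f"bn_mean_{i}"].copy()
            bn.running_var = arrays[f"bn_var_{i}"].copy()
        model.trained = bool(meta["trained"])
    return model


def _iter_batchnorms(model: Surrogate):
    def walk(layer):
        if isinstance(layer, nn.BatchNorm1d):
            yield layer
        elif isinstance(layer, nn.Sequential):
            for sub in layer.layers:
                yield from walk(sub)
        elif isinstance(layer, _ResidualBlock):
            yield from walk(layer.path)
            if layer.shortcut is not None:
                yield from walk(layer.shortcut)

    for m in model._modules():
        yield from walk(m)
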