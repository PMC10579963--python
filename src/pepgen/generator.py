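"""Character-level LSTM peptide language model.

A stacked unidirectional LSTM with a 22-way dense softmax head is trained by
next-token prediction on padded peptide windows: the input at step ``t`` is
the token at position ``t`` and the target is the token at ``t + 1``, with
the initial pad token ``X`` acting as the start-of-sequence primer.  The
loss is masked categorical cross-entropy (padding targets excluded by
default).  Sampling is autoregressive with temperature-scaled softmax and
terminates at the end token ``$``.

Everything is deterministic given (corpus, config, seed).
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .corpus import Corpus, EncodedBatch, Peptide, Vocabulary

logger = logging.getLogger(__name__)

_CKPT_MAGIC = b"PEPGENC1"


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


class CheckpointError(ValueError):
    """Raised on malformed or shape-incompatible checkpoint files."""


@dataclass
class ModelConfig:
    """Hyperparameters of the LSTM generator.

    Defaults are the production settings: two 256-unit layers with 30% and
    45% dropout, Adam at learning rate 0.02, a fixed forget-gate bias of 1,
    and a 200-epoch budget.
    """

    layers: int = 2
    units_per_layer: int = 256
    dropout_per_layer: tuple[float, ...] = (0.30, 0.45)
    learning_rate: float = 0.02
    forget_gate_bias: float = 1.0
    epochs: int = 200
    batch_size: int = 0  # 0 = full batch
    seed: int = 0
    include_pad_loss: bool = False
    loss_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.units_per_layer < 1:
            raise ValueError("units_per_layer must be >= 1")
        if len(self.dropout_per_layer) != self.layers:
            # pad or trim the dropout schedule to the layer count
            d = tuple(self.dropout_per_layer) + (0.0,) * self.layers
            self.dropout_per_layer = d[: self.layers]
        if any(not (0.0 <= d < 1.0) for d in self.dropout_per_layer):
            raise ValueError("dropout fractions must lie in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ModelState:
    """Vocabulary, config and all trainable weights of a model."""

    vocabulary: Vocabulary
    config: ModelConfig
    lstm: list[nn.LSTMParams]
    dense: nn.DenseParams

    def parameter_dict(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for k, layer in enumerate(self.lstm):
            params[f"lstm{k}.Wx"] = layer.Wx
            params[f"lstm{k}.Wh"] = layer.Wh
            params[f"lstm{k}.b"] = layer.b
        params["dense.W"] = self.dense.W
        params["dense.b"] = self.dense.b
        return params


@dataclass
class LossTrace:
    """Per-epoch training (and optionally validation) loss in nats."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def best_val_epoch(self) -> int:
        if not self.val_loss:
            raise ValueError("trace has no validation losses")
        return int(np.argmin(self.val_loss))


@dataclass
class CVReport:
    """Cross-validation traces per (architecture index, fold)."""

    traces: dict[tuple[int, int], LossTrace]
    fold_seeds: dict[tuple[int, int], int]
    mean_best_val: list[float]
    selected: int  # index into the architecture grid


def cross_entropy(
    targets: np.ndarray,
    predictions: np.ndarray,
    mask: np.ndarray | None = None,
    epsilon: float = 0.0,
) -> float:
    """Masked mean categorical cross-entropy in nats (see :mod:`pepgen.nn`)."""
    return nn.masked_cross_entropy(targets, predictions, mask, epsilon)


# ---------------------------------------------------------------------------
# Initialisation, forward pass


def init_model(
    config: ModelConfig, vocabulary: Vocabulary | None = None
) -> ModelState:
    vocabulary = vocabulary or Vocabulary()
    rng = np.random.default_rng(config.seed)
    layers = []
    input_dim = vocabulary.size
    for _ in range(config.layers):
        layers.append(
            nn.init_lstm_layer(rng, input_dim, config.units_per_layer,
                               config.forget_gate_bias)
        )
        input_dim = config.units_per_layer
    dense = nn.init_dense(rng, config.units_per_layer, vocabulary.size)
    return ModelState(vocabulary=vocabulary, config=config, lstm=layers,
                      dense=dense)


def _one_hot(tokens: np.ndarray, size: int) -> np.ndarray:
    return np.eye(size)[tokens]


def _forward(
    state: ModelState,
    inputs: np.ndarray,  # (N, T) token indices
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list]:
    """Return softmax probabilities of shape (N, T, K) and layer caches."""
    x = _one_hot(inputs, state.vocabulary.size).transpose(1, 0, 2)  # (T, N, K)
    caches = []
    for layer, dropout in zip(state.lstm, state.config.dropout_per_layer):
        x, cache = nn.lstm_forward(layer, x, dropout=dropout, rng=rng)
        caches.append(cache)
    logits = x @ state.dense.W + state.dense.b  # (T, N, K)
    probs = nn.softmax(logits).transpose(1, 0, 2)
    caches.append(x)  # top-layer (possibly dropped-out) activations
    return probs, caches


def predict_probs(state: ModelState, inputs: np.ndarray) -> np.ndarray:
    """Inference-mode next-token probabilities, shape (N, T, 22)."""
    probs, _ = _forward(state, np.asarray(inputs, dtype=np.int64), rng=None)
    return probs


def evaluate_loss(state: ModelState, batch: EncodedBatch) -> float:
    inputs = batch.token_matrix[:, :-1]
    targets = batch.token_matrix[:, 1:]
    mask = batch.loss_mask[:, 1:]
    probs = predict_probs(state, inputs)
    t_onehot = _one_hot(targets, state.vocabulary.size)
    return cross_entropy(t_onehot, probs, mask,
                         epsilon=state.config.loss_epsilon)


# ---------------------------------------------------------------------------
# Training


def _train_step(
    state: ModelState,
    inputs: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    adam: nn.AdamState,
    rng: np.random.Generator,
) -> float:
    K = state.vocabulary.size
    probs, caches = _forward(state, inputs, rng=rng)
    top = caches.pop()  # (T, N, H)
    t_onehot = _one_hot(targets, K)
    loss = cross_entropy(t_onehot, probs, mask,
                         epsilon=state.config.loss_epsilon)
    n_active = max(int(mask.sum()), 1)
    dlogits = (probs - t_onehot) * mask[:, :, None] / n_active  # (N, T, K)
    dlogits = dlogits.transpose(1, 0, 2)  # (T, N, K)
    T = dlogits.shape[0]
    dW = top.reshape(-1, top.shape[-1]).T @ dlogits.reshape(-1, K)
    db = dlogits.sum(axis=(0, 1))
    dx = dlogits @ state.dense.W.T  # (T, N, H)
    grads: dict[str, np.ndarray] = {"dense.W": dW, "dense.b": db}
    for k in range(len(state.lstm) - 1, -1, -1):
        layer_grads, dx = nn.lstm_backward(state.lstm[k], caches[k], dx)
        grads[f"lstm{k}.Wx"] = layer_grads.Wx
        grads[f"lstm{k}.Wh"] = layer_grads.Wh
        grads[f"lstm{k}.b"] = layer_grads.b
    nn.adam_step(state.parameter_dict(), grads, adam,
                 lr=state.config.learning_rate)
    return loss


def train(
    batch: EncodedBatch,
    config: ModelConfig,
    val_batch: EncodedBatch | None = None,
) -> tuple[ModelState, LossTrace]:
    """Train a model on an encoded batch; reproducible from ``config.seed``.

    Returns the final state and the per-epoch loss trace.  ``epochs == 0``
    returns the freshly initialised state with an empty trace.  Divergence
    (non-finite loss) aborts with :class:`TrainingError` naming the epoch.
    """
    if len(batch) == 0:
        raise ValueError("cannot train on an empty batch")
    state = init_model(config, batch.vocabulary)
    trace = LossTrace()
    if config.epochs == 0:
        return state, trace
    rng = np.random.default_rng(config.seed + 1)
    adam = nn.AdamState()
    inputs_all = batch.token_matrix[:, :-1]
    targets_all = batch.token_matrix[:, 1:]
    mask_all = batch.loss_mask[:, 1:]
    n = len(batch)
    bs = config.batch_size if config.batch_size > 0 else n
    for epoch in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        losses, weights = [], []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            loss = _train_step(
                state, inputs_all[idx], targets_all[idx], mask_all[idx],
                adam, rng,
            )
            losses.append(loss)
            weights.append(mask_all[idx].sum())
        epoch_loss = float(np.average(losses, weights=weights))
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"training diverged at epoch {epoch}")
        trace.train_loss.append(epoch_loss)
        if val_batch is not None and len(val_batch):
            trace.val_loss.append(evaluate_loss(state, val_batch))
    return state, trace


def cross_validate(
    batch: EncodedBatch,
    grid: list[ModelConfig],
    k: int = 5,
    base_seed: int = 0,
) -> CVReport:
    """k-fold cross-validation over an architecture grid.

    Sequences are shuffled once with ``base_seed`` and split into k
    contiguous folds.  For each architecture and fold the model weights are
    re-initialised with ``base_seed + fold`` so no fold inherits residual
    knowledge.  The selected architecture minimises the mean validation loss
    at each trace's best epoch.
    """
    if not grid:
        raise ValueError("architecture grid is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(batch)
    if n < k:
        raise ValueError(f"batch of {n} sequences cannot be split into {k} folds")
    rng = np.random.default_rng(base_seed)
    order = rng.permutation(n)
    bounds = np.linspace(0, n, k + 1).astype(int)
    traces: dict[tuple[int, int], LossTrace] = {}
    fold_seeds: dict[tuple[int, int], int] = {}
    mean_best_val = []
    for a, arch in enumerate(grid):
        best_vals = []
        for fold in range(k):
            val_idx = order[bounds[fold] : bounds[fold + 1]]
            train_idx = np.concatenate([order[: bounds[fold]], order[bounds[fold + 1] :]])
            seed = base_seed + fold
            cfg = ModelConfig(**{**asdict(arch), "seed": seed})
            sub = EncodedBatch(
                token_matrix=batch.token_matrix[train_idx],
                loss_mask=batch.loss_mask[train_idx],
                vocabulary=batch.vocabulary,
            )
            val = EncodedBatch(
                token_matrix=batch.token_matrix[val_idx],
                loss_mask=batch.loss_mask[val_idx],
                vocabulary=batch.vocabulary,
            )
            _, trace = train(sub, cfg, val_batch=val)
            traces[(a, fold)] = trace
            fold_seeds[(a, fold)] = seed
            best_vals.append(min(trace.val_loss))
        mean_best_val.append(float(np.mean(best_vals)))
    selected = int(np.argmin(mean_best_val))
    logger.info("cross_validate: selected architecture %d (mean best val loss %.4f)",
                selected, mean_best_val[selected])
    return CVReport(traces=traces, fold_seeds=fold_seeds,
                    mean_best_val=mean_best_val, selected=selected)


# ---------------------------------------------------------------------------
# Sampling


def _next_token(
    state: ModelState, probs: np.ndarray, temperature: float,
    rng: np.random.Generator,
) -> int:
    if temperature <= 1e-8:
        return int(np.argmax(probs))
    logits = np.log(np.clip(probs, 1e-300, None)) / temperature
    p = nn.softmax(logits)
    return int(rng.choice(len(p), p=p))


def _step(
    state: ModelState,
    token: int,
    hs: list[np.ndarray],
    cs: list[np.ndarray],
) -> np.ndarray:
    """Advance the recurrence one token; updates hs/cs in place.

    Returns the next-token probability vector (inference mode, no dropout).
    """
    x = np.zeros(state.vocabulary.size)
    x[token] = 1.0
    for k, layer in enumerate(state.lstm):
        H = layer.hidden
        z = x @ layer.Wx + hs[k] @ layer.Wh + layer.b
        i = nn.sigmoid(z[:H])
        f = nn.sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = nn.sigmoid(z[3 * H :])
        cs[k] = f * cs[k] + i * g
        hs[k] = o * np.tanh(cs[k])
        x = hs[k]
    return nn.softmax(x @ state.dense.W + state.dense.b)


def _draw_sequence(
    state: ModelState, temperature: float, max_len: int,
    rng: np.random.Generator, prefix: str = "",
) -> str:
    """One autoregressive draw primed with start token (+ optional prefix)."""
    vocab = state.vocabulary
    H = state.config.units_per_layer
    hs = [np.zeros(H) for _ in state.lstm]
    cs = [np.zeros(H) for _ in state.lstm]
    probs = _step(state, vocab.pad_index, hs, cs)
    for ch in prefix:
        probs = _step(state, vocab.index_of(ch), hs, cs)
    out = list(prefix)
    while len(out) < max_len:
        idx = _next_token(state, probs, temperature, rng)
        if idx == vocab.end_index:
            break
        sym = vocab.symbols[idx]
        if sym == "X":
            break  # pad emitted mid-sequence: treat as termination
        out.append(sym)
        probs = _step(state, idx, hs, cs)
    return "".join(out)


def sample(
    state: ModelState,
    n: int,
    temperature: float = 1.0,
    max_len: int = 15,
    seed: int = 0,
) -> Corpus:
    """Draw ``n`` sequences; raw draws, deduplication happens downstream.

    Draws that terminate before emitting any residue are discarded (they
    carry no sequence), so the returned corpus may be smaller than ``n``.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rng = np.random.default_rng(seed)
    peptides = []
    for j in range(n):
        seq = _draw_sequence(state, temperature, max_len, rng)
        if seq:
            peptides.append(Peptide(id=f"gen_{j:05d}", sequence=seq,
                                    provenance="generated"))
    return Corpus(peptides)


def greedy_complete(state: ModelState, prefix: str, max_len: int = 30) -> str:
    """Deterministic greedy completion of ``prefix`` (temperature -> 0)."""
    rng = np.random.default_rng(0)  # unused at temperature 0
    return _draw_sequence(state, 0.0, max_len, rng, prefix=prefix)


def dedupe_against(generated: Corpus, reference: Corpus) -> Corpus:
    """Drop internal duplicates (keep first) and exact reference matches."""
    ref = set(reference.sequences)
    seen: set[str] = set()
    kept = []
    for p in generated:
        if p.sequence in ref or p.sequence in seen:
            continue
        seen.add(p.sequence)
        kept.append(p)
    logger.info("dedupe_against: %d -> %d unique novel sequences",
                len(generated), len(kept))
    return Corpus(kept)


# ---------------------------------------------------------------------------
# Checkpoints: JSON header + little-endian float64 payload


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    params = state.parameter_dict()
    header = {
        "format": 1,
        "symbols": list(state.vocabulary.symbols),
        "config": asdict(state.config),
        "arrays": [
            {"name": name, "shape": list(arr.shape)} for name, arr in params.items()
        ],
    }
    header_bytes = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_CKPT_MAGIC)
        fh.write(struct.pack("<I", len(header_bytes)))
        fh.write(header_bytes)
        for arr in params.values():
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def load_checkpoint(path: str | Path, expect_layers: int | None = None) -> ModelState:
    with open(path, "rb") as fh:
        magic = fh.read(len(_CKPT_MAGIC))
        if magic != _CKPT_MAGIC:
            raise CheckpointError(f"{path}: not a pepgen checkpoint")
        raw_len = fh.read(4)
        if len(raw_len) < 4:
            raise CheckpointError(f"{path}: truncated header length")
        (header_len,) = struct.unpack("<I", raw_len)
        header_bytes = fh.read(header_len)
        if len(header_bytes) < header_len:
            raise CheckpointError(f"{path}: truncated header")
        header = json.loads(header_bytes)
        cfg_dict = dict(header["config"])
        cfg_dict["dropout_per_layer"] = tuple(cfg_dict["dropout_per_layer"])
        config = ModelConfig(**cfg_dict)
        if expect_layers is not None and config.layers != expect_layers:
            raise CheckpointError(
                f"{path}: checkpoint has {config.layers} LSTM layer(s), "
                f"expected {expect_layers}"
            )
        vocabulary = Vocabulary(symbols=tuple(header["symbols"]))
        arrays: dict[str, np.ndarray] = {}
        for spec in header["arrays"]:
            shape = tuple(spec["shape"])
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(count * 8)
            if len(buf) < count * 8:
                raise CheckpointError(
                    f"{path}: truncated payload at array {spec['name']!r}"
                )
            arrays[spec["name"]] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    lstm = []
    for k in range(config.layers):
        try:
            lstm.append(nn.LSTMParams(
                Wx=arrays[f"lstm{k}.Wx"], Wh=arrays[f"lstm{k}.Wh"],
                b=arrays[f"lstm{k}.b"],
            ))
        except KeyError as exc:
            raise CheckpointError(f"{path}: missing weights for layer {k}") from exc
    dense = nn.DenseParams(W=arrays["dense.W"], b=arrays["dense.b"])
    return ModelState(vocabulary=vocabulary, config=config, lstm=lstm, dense=dense)
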