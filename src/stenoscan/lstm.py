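"""Recurrent multi-label classifier for per-artery stenosis probabilities.

Architecture: token embedding (dim 128) -> LSTM (64 cells, sequence output)
-> LSTM (32 cells, final state) -> dense sigmoid layer with 11 independent
outputs, one per target artery. Dropout 0.2 is applied after each layer
during training. The loss is mean binary cross-entropy over the 11 outputs
(multi-label: the sigmoid outputs are not coupled by a softmax), optimized
with Adam at learning rate 1e-3.

The network and its backpropagation-through-time are implemented directly
on NumPy arrays, which keeps training fully deterministic under a seed and
dependency-free; the layer sizes above put the model at roughly 1.3M
parameters with the default 10k-type vocabulary cap. Variable-length
reports are padded per batch and masked, so padded positions neither
advance the recurrent state nor contribute gradients.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Vocabulary", "TrainingConfig", "LSTMClassifier", "build_vocabulary"]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*|[%><]")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; keeps %, >, < as tokens (severity signal)."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Token-to-id mapping built from the training split only.

    Id 0 is padding, id 1 is the unknown token; content ids are dense from 2.
    """

    token_to_id: dict[str, int]
    max_sequence_length: int = 256

    PAD = 0
    UNK = 1

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def encode(self, text: str) -> list[int]:
        ids = [self.token_to_id.get(t, self.UNK) for t in tokenize(text)]
        return ids[: self.max_sequence_length]

    def encode_batch(self, texts: list[str], pad_to: int | None = None) -> np.ndarray:
        seqs = [self.encode(t) for t in texts]
        width = max((len(s) for s in seqs), default=1) or 1
        if pad_to is not None:
            width = max(width, pad_to)
        out = np.zeros((len(seqs), width), dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out


def build_vocabulary(
    train_texts: list[str],
    max_size: int = 10_000,
    max_sequence_length: int = 256,
) -> Vocabulary:
    """Frequency-capped vocabulary; ties broken alphabetically."""
    if not train_texts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for t in train_texts:
        for tok in tokenize(t):
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_size]
    mapping = {tok: i + 2 for i, (tok, _) in enumerate(ranked)}
    return Vocabulary(mapping, max_sequence_length)


@dataclass
class TrainingConfig:
    """Hyperparameters of the recurrent model."""

    embedding_dim: int = 128
    lstm_units: tuple[int, int] = (64, 32)
    dropout: float = 0.2
    output_dim: int = 11
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    max_vocab: int = 10_000
    max_sequence_length: int = 256

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.output_dim, *self.lstm_units) <= 0:
            raise ValueError("layer dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMLayer:
    """One LSTM layer with gate order (input, forget, cell, output)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(units)
        self.Wx = rng.uniform(-k, k, (in_dim, 4 * units))
        self.Wh = rng.uniform(-k, k, (units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias init
        self.units = units

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (B, T, D); mask: (B, T) with 1 on real tokens.

        Returns the hidden-state sequence (B, T, H) and caches for BPTT.
        Masked steps carry the previous state through unchanged, so the
        state at the last step equals the state after the last real token.
        """
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        caches = []
        for t in range(T):
            m = mask[:, t : t + 1]
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_raw = f * c + i * g
            tc = np.tanh(c_raw)
            h_raw = o * tc
            caches.append((h, c, i, f, g, o, tc, m))
            h = m * h_raw + (1.0 - m) * h
            c = m * c_raw + (1.0 - m) * c
            hs[:, t, :] = h
        return hs, caches

    def backward(self, x: np.ndarray, dhs: np.ndarray, caches):
        """dhs: gradient w.r.t. the hidden-state sequence (B, T, H)."""
        B, T, D = x.shape
        H = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = caches[t]
            dh = dhs[:, t, :] + dh_next
            dh_raw = m * dh
            dc_raw = m * dc_next + dh_raw * o * (1.0 - tc * tc)
            do = dh_raw * tc
            di = dc_raw * g
            df = dc_raw * c_prev
            dg = dc_raw * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T + (1.0 - m) * dh
            dc_next = dc_raw * f + (1.0 - m) * dc_next
        return dx, [dWx, dWh, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class LSTMClassifier:
    """Multi-label stenosis classifier over tokenized report text."""

    def __init__(self, config: TrainingConfig | None = None,
                 vocab: Vocabulary | None = None):
        self.config = config or TrainingConfig()
        self.vocab = vocab
        self.history: list[float] = []
        self._rng = np.random.default_rng(self.config.seed)
        if vocab is not None:
            self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        V = len(self.vocab)
        self.embedding = rng.normal(0.0, 0.05, (V, cfg.embedding_dim))
        self.embedding[Vocabulary.PAD] = 0.0
        h1, h2 = cfg.lstm_units
        self.lstm1 = _LSTMLayer(cfg.embedding_dim, h1, rng)
        self.lstm2 = _LSTMLayer(h1, h2, rng)
        k = 1.0 / np.sqrt(h2)
        self.Wout = rng.uniform(-k, k, (h2, cfg.output_dim))
        self.bout = np.zeros(cfg.output_dim)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)

    def _all_params(self):
        return ([self.embedding] + self.lstm1.params() + self.lstm2.params()
                + [self.Wout, self.bout])

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._all_params()))

    # -- forward / backward -------------------------------------------------

    def _forward(self, ids: np.ndarray, train: bool):
        cfg = self.config
        mask = (ids != Vocabulary.PAD).astype(float)
        x = self.embedding[ids]  # (B, T, E)
        drops = []
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            d0 = (self._dropout_rng.random(x.shape) < keep) / keep
            x = x * d0
            drops.append(d0)
        h1, cache1 = self.lstm1.forward(x, mask)
        h1d = h1
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            d1 = (self._dropout_rng.random(h1.shape) < keep) / keep
            h1d = h1 * d1
            drops.append(d1)
        h2, cache2 = self.lstm2.forward(h1d, mask)
        last = h2[:, -1, :]
        lastd = last
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            d2 = (self._dropout_rng.random(last.shape) < keep) / keep
            lastd = last * d2
            drops.append(d2)
        logits = lastd @ self.Wout + self.bout
        cache = (ids, mask, x, cache1, h1d, cache2, lastd, drops)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache):
        cfg = self.config
        ids, mask, x, cache1, h1d, cache2, lastd, drops = cache
        dWout = lastd.T @ dlogits
        dbout = dlogits.sum(axis=0)
        dlast = dlogits @ self.Wout.T
        if drops:
            dlast = dlast * drops[2]
        T = ids.shape[1]
        dh2 = np.zeros((ids.shape[0], T, cfg.lstm_units[1]))
        dh2[:, -1, :] = dlast
        dh1d, grads2 = self.lstm2.backward(h1d, dh2, cache2)
        if drops:
            dh1d = dh1d * drops[1]
        dx, grads1 = self.lstm1.backward(x, dh1d, cache1)
        if drops:
            dx = dx * drops[0]
        dE = np.zeros_like(self.embedding)
        np.add.at(dE, ids, dx)
        dE[Vocabulary.PAD] = 0.0
        return [dE] + grads1 + grads2 + [dWout, dbout]

    # -- training -----------------------------------------------------------

    @staticmethod
    def _bce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        # numerically stable BCE-with-logits; gradient is (p - y) / N
        p = _sigmoid(logits)
        z = np.clip(logits, -500, 500)
        loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
        return float(loss), (p - y) / y.size

    def fit(self, texts: list[str], labels: np.ndarray) -> "LSTMClassifier":
        """Train on texts and an (n, output_dim) binary label matrix."""
        cfg = self.config
        labels = np.asarray(labels, dtype=float)
        if len(texts) == 0:
            raise ValueError("empty training set")
        if labels.shape != (len(texts), cfg.output_dim):
            raise ValueError(
                f"labels must have shape ({len(texts)}, {cfg.output_dim})")
        col_sums = labels.sum(axis=0)
        if np.all((col_sums == 0) | (col_sums == len(texts))):
            warnings.warn("all outputs are single-class; model will be constant",
                          stacklevel=2)
        if self.vocab is None:
            self.vocab = build_vocabulary(
                texts, cfg.max_vocab, cfg.max_sequence_length)
            self._init_params()

        # fresh random batch composition every epoch (padded per batch)
        opt = _Adam(self._all_params(), cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 2)
        n = len(texts)
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            total = 0.0
            for i in range(0, n, cfg.batch_size):
                batch = perm[i : i + cfg.batch_size]
                ids = self.vocab.encode_batch([texts[j] for j in batch])
                y = labels[batch]
                logits, cache = self._forward(ids, train=True)
                loss, dlogits = self._bce(logits, y)
                grads = self._backward(dlogits, cache)
                opt.step(grads)
                total += loss * len(batch)
            self.history.append(total / n)
        return self

    def predict_proba(self, texts: list[str], batch_size: int = 64) -> np.ndarray:
        """Per-report vector of output_dim independent probabilities."""
        if self.vocab is None:
            raise RuntimeError("model is not trained")
        out = []
        for i in range(0, len(texts), batch_size):
            ids = self.vocab.encode_batch(list(texts[i : i + batch_size]))
            logits, _ = self._forward(ids, train=False)
            out.append(_sigmoid(logits))
        if not out:
            return np.zeros((0, self.config.output_dim))
        return np.vstack(out)

    # -- persistence ----------------------------------------------------------

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "weights.npz",
            embedding=self.embedding,
            l1_Wx=self.lstm1.Wx, l1_Wh=self.lstm1.Wh, l1_b=self.lstm1.b,
            l2_Wx=self.lstm2.Wx, l2_Wh=self.lstm2.Wh, l2_b=self.lstm2.b,
            Wout=self.Wout, bout=self.bout,
        )
        meta = {
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "embedding_dim", "dropout", "output_dim", "learning_rate",
                    "epochs", "batch_size", "seed", "max_vocab",
                    "max_sequence_length")},
                "lstm_units": list(self.config.lstm_units),
            },
            "vocab": self.vocab.token_to_id,
        }
        (d / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, model_dir) -> "LSTMClassifier":
        d = Path(model_dir)
        meta = json.loads((d / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["lstm_units"] = tuple(cfg_d["lstm_units"])
        cfg = TrainingConfig(**cfg_d)
        vocab = Vocabulary(meta["vocab"], cfg.max_sequence_length)
        model = cls(cfg, vocab)
        w = np.load(d / "weights.npz")
        model.embedding = w["embedding"]
        model.lstm1.Wx, model.lstm1.Wh, model.lstm1.b = w["l1_Wx"], w["l1_Wh"], w["l1_b"]
        model.lstm2.Wx, model.lstm2.Wh, model.lstm2.b = w["l2_Wx"], w["l2_Wh"], w["l2_b"]
        model.Wout, model.bout = w["Wout"], w["bout"]
        return model
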