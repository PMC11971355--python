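"""The triple-encoder methylation classifier.

Architecture: a sequence-feature branch (learned base embedding joined
with the four numeric per-base statistics, projected to ``seq_dim``) and a
signal-feature branch (the k x 15 sampled-signal matrix projected to
``sig_dim``) are encoded independently, concatenated per position, and
passed through a third, collaborative encoder; a feedforward classifier
then emits two-class probabilities for the center cytosine.

Two encoder families implement one contract:

* ``bilstm`` — stacked bidirectional LSTMs; the terminal representation is
  the concatenation of the last forward and last backward hidden states of
  the collaborative encoder.
* ``transformer`` — BERT-style encoder blocks with sinusoidal positional
  encoding added at both branch inputs; the terminal representation is the
  hidden vector at the center (target cytosine) position.

Each of the three encoders can be disabled independently (identity
pass-through) for ablation studies; the dimension contract is preserved so
the rest of the network still type-checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import nn
from .types import BASE_CODES, FeatureRecord, ReadCall

__all__ = [
    "ModelConfig",
    "MethylationClassifier",
    "positional_encoding",
    "positional_encoding_matrix",
    "classify_read",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

# fixed input scalings keeping all network inputs near unit magnitude:
# MAD-standardized signal values span roughly +-8 across contexts, basecall
# quality ~0..50, per-base signal sample count ~1..40.  Constants, not
# fitted statistics, so records featurize identically everywhere.
SIGNAL_SCALE = 0.2
QUALITY_SCALE = 1.0 / 40.0
COUNT_SCALE = 1.0 / 20.0


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``combine_dim`` must equal ``seq_dim + sig_dim``: the collaborative
    encoder consumes the per-position concatenation of the two branches.
    """

    encoder_kind: str = "bilstm"  # "bilstm" | "transformer"
    k: int = 13
    seq_layers: int = 2
    sig_layers: int = 2
    combine_layers: int = 3
    seq_dim: int = 128
    sig_dim: int = 128
    combine_dim: int = 256
    dropout_rate: float = 0.2
    num_classes: int = 2
    n_heads: int = 4
    use_seq_encoder: bool = True
    use_sig_encoder: bool = True
    use_combine_encoder: bool = True

    def __post_init__(self) -> None:
        if self.encoder_kind not in ("bilstm", "transformer"):
            raise ValueError(f"unknown encoder kind {self.encoder_kind!r}")
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.combine_dim != self.seq_dim + self.sig_dim:
            raise ValueError(
                f"combine_dim {self.combine_dim} != seq_dim {self.seq_dim} "
                f"+ sig_dim {self.sig_dim}")
        for name in ("seq_dim", "sig_dim", "combine_dim"):
            if getattr(self, name) % 2:
                raise ValueError(f"{name} must be even (bidirectional halves)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def positional_encoding(pos: int, index: int, d: int = 128) -> float:
    """Sinusoidal positional encoding value at one (position, dimension).

    Even dimension indices 2i carry sin(pos * 10000^(-2i/d)), odd indices
    2i+1 carry cos of the same angle.
    """
    if not 0 <= index < d:
        raise ValueError(f"dimension index {index} outside [0, {d})")
    i = index // 2
    angle = pos * 10000.0 ** (-2.0 * i / d)
    return float(np.sin(angle) if index % 2 == 0 else np.cos(angle))


def positional_encoding_matrix(k: int, d: int) -> np.ndarray:
    """The full k x d sinusoidal positional encoding table."""
    pos = np.arange(k)[:, None]
    i = np.arange(d)[None, :] // 2
    angles = pos * 10000.0 ** (-2.0 * i / d)
    pe = np.empty((k, d))
    pe[:, 0::2] = np.sin(angles[:, 0::2])
    pe[:, 1::2] = np.cos(angles[:, 1::2])
    return pe


def batch_arrays(records: Sequence[FeatureRecord]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack feature records into (base codes, numeric features, signal).

    Shapes: (B, k) int, (B, k, 4), (B, k, 15).  Quality and sample-count
    columns are rescaled by fixed constants to keep all inputs near unit
    magnitude.
    """
    codes = np.array([[BASE_CODES[b] for b in r.kmer] for r in records], dtype=np.intp)
    numeric = np.stack([r.seq_features[:, :4] for r in records]).astype(float)
    numeric[:, :, 0] *= SIGNAL_SCALE
    numeric[:, :, 1] *= SIGNAL_SCALE
    numeric[:, :, 2] *= QUALITY_SCALE
    numeric[:, :, 3] *= COUNT_SCALE
    signal = np.stack([r.signal_features for r in records]).astype(float) * SIGNAL_SCALE
    return codes, numeric, signal


class _BiLSTMStack(nn.Module):
    def __init__(self, d_in: int, d_out: int, layers: int, rng):
        self.layers = [nn.BiLSTM(d_in if i == 0 else d_out, d_out // 2, rng)
                       for i in range(layers)]

    def __call__(self, x, dropout_rate, rng, training):
        finals = None
        for i, layer in enumerate(self.layers):
            if i > 0:
                x = nn.dropout(x, dropout_rate, rng, training)
            x, finals = layer(x)
        return x, finals


class _TransformerStack(nn.Module):
    def __init__(self, dim: int, layers: int, n_heads: int, dropout_rate: float, rng):
        self.layers = [nn.TransformerEncoderLayer(dim, n_heads, 2 * dim, dropout_rate, rng)
                       for _ in range(layers)]

    def __call__(self, x, rng, training):
        for layer in self.layers:
            x = layer(x, rng, training)
        return x


class MethylationClassifier(nn.Module):
    """Triple-encoder 5mC classifier over k-mer feature matrices."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c = config
        self.base_embedding = nn.Embedding(4, c.seq_dim, rng)
        self.seq_proj = nn.Linear(c.seq_dim + 4, c.seq_dim, rng)
        self.sig_proj = nn.Linear(15, c.sig_dim, rng)
        if c.encoder_kind == "bilstm":
            self.seq_encoder = _BiLSTMStack(c.seq_dim, c.seq_dim, c.seq_layers, rng)
            self.sig_encoder = _BiLSTMStack(c.sig_dim, c.sig_dim, c.sig_layers, rng)
            self.combine_encoder = _BiLSTMStack(c.combine_dim, c.combine_dim,
                                                c.combine_layers, rng)
        else:
            self.seq_encoder = _TransformerStack(c.seq_dim, c.seq_layers, c.n_heads,
                                                 c.dropout_rate, rng)
            self.sig_encoder = _TransformerStack(c.sig_dim, c.sig_layers, c.n_heads,
                                                 c.dropout_rate, rng)
            self.combine_encoder = _TransformerStack(c.combine_dim, c.combine_layers,
                                                     c.n_heads, c.dropout_rate, rng)
            self.pe_seq = positional_encoding_matrix(c.k, c.seq_dim)
            self.pe_sig = positional_encoding_matrix(c.k, c.sig_dim)
        self.classifier_hidden = nn.Linear(c.combine_dim, c.combine_dim // 2, rng)
        self.classifier_out = nn.Linear(c.combine_dim // 2, c.num_classes, rng)

    # -- forward ----------------------------------------------------------

    def forward_logits(self, codes: np.ndarray, numeric: np.ndarray, signal: np.ndarray,
                       training: bool = False, rng: np.random.Generator | None = None
                       ) -> nn.Tensor:
        """Unnormalized class logits, shape (B, num_classes)."""
        c = self.config
        if codes.shape[1] != c.k:
            raise ValueError(f"batch k-mer length {codes.shape[1]} != config k {c.k}")
        if rng is None:
            rng = np.random.default_rng(0)
        drop = c.dropout_rate

        emb = self.base_embedding(codes)  # (B, k, seq_dim)
        seq_in = self.seq_proj(nn.concat([emb, nn.Tensor(numeric)], axis=-1))
        sig_in = self.sig_proj(nn.Tensor(signal))
        if c.encoder_kind == "transformer":
            seq_in = seq_in + nn.Tensor(self.pe_seq)
            sig_in = sig_in + nn.Tensor(self.pe_sig)

        if c.encoder_kind == "bilstm":
            if c.use_seq_encoder:
                seq_out, _ = self.seq_encoder(seq_in, drop, rng, training)
            else:
                seq_out = seq_in
            if c.use_sig_encoder:
                sig_out, _ = self.sig_encoder(sig_in, drop, rng, training)
            else:
                sig_out = sig_in
            combined = nn.concat([seq_out, sig_out], axis=-1)
            if c.use_combine_encoder:
                combined = nn.dropout(combined, drop, rng, training)
                _, (last_f, last_b) = self.combine_encoder(combined, drop, rng, training)
                rep = nn.concat([last_f, last_b], axis=-1)
            else:
                rep = combined[:, (c.k - 1) // 2, :]
        else:
            seq_out = (self.seq_encoder(seq_in, rng, training)
                       if c.use_seq_encoder else seq_in)
            sig_out = (self.sig_encoder(sig_in, rng, training)
                       if c.use_sig_encoder else sig_in)
            combined = nn.concat([seq_out, sig_out], axis=-1)
            if c.use_combine_encoder:
                combined = self.combine_encoder(combined, rng, training)
            rep = combined[:, (c.k - 1) // 2, :]

        hidden = nn.dropout(self.classifier_hidden(rep).relu(), drop, rng, training)
        return self.classifier_out(hidden)

    def forward(self, codes, numeric, signal, training=False, rng=None) -> nn.Tensor:
        """Class probabilities, shape (B, num_classes), rows summing to 1."""
        logits = self.forward_logits(codes, numeric, signal, training=training, rng=rng)
        return nn.softmax(logits, axis=-1)

    # -- inference --------------------------------------------------------

    def predict_proba(self, records: Sequence[FeatureRecord],
                      batch_size: int = 512) -> np.ndarray:
        """Methylation probability P_m per record, in evaluation mode."""
        out = np.empty(len(records))
        for lo in range(0, len(records), batch_size):
            chunk = records[lo:lo + batch_size]
            codes, numeric, signal = batch_arrays(chunk)
            probs = self.forward(codes, numeric, signal, training=False)
            out[lo:lo + len(chunk)] = probs.data[:, 1]
        return out

    def call_reads(self, records: Sequence[FeatureRecord],
                   batch_size: int = 512) -> list[ReadCall]:
        pm = self.predict_proba(records, batch_size=batch_size)
        return [ReadCall(r.read_id, r.chrom, r.pos, r.strand, float(np.clip(p, 0, 1)))
                for r, p in zip(records, pm)]


def classify_read(call: ReadCall) -> str:
    """Binary rule: methylated iff P_m exceeds the non-methylation
    probability; the exact tie P_m = 0.5 is called unmethylated."""
    return "methylated" if call.p_meth > 0.5 else "unmethylated"


def count_parameters(model: MethylationClassifier) -> int:
    return sum(p.data.size for p in model.parameters())


def save_checkpoint(model: MethylationClassifier, path, metadata: dict | None = None) -> None:
    """Persist config, weights, and training metadata to an .npz file."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    arrays["metadata_json"] = np.array(json.dumps(metadata or {}))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[MethylationClassifier, dict]:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(data["config_json"])))
    metadata = json.loads(str(data["metadata_json"]))
    model = MethylationClassifier(config, seed=0)
    params = model.parameters()
    for i, p in enumerate(params):
        saved = data[f"param_{i}"]
        if saved.shape != p.data.shape:
            raise ValueError(f"checkpoint parameter {i} shape {saved.shape} "
                             f"does not match model {p.data.shape}")
        p.data = saved.astype(np.float64)
    return model, metadata
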