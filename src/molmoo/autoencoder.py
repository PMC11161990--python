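"""Latent Transformer molecular autoencoders.

Two architectures share an embedding + Transformer encoder front end and a
fixed-length latent bottleneck, and differ in how they get into and out of
it:

* ``relso`` — mean-pools the encoder output, projects to the latent vector,
  and decodes with a position-wise convolutional decoder fed by the latent
  vector broadcast along the sequence (one non-autoregressive pass).
* ``fragnet`` — projects the start-token encoder state to the latent vector
  and decodes autoregressively with a Transformer decoder cross-attending
  to the unprojected latent (teacher forcing in training, greedy argmax at
  inference).

Both carry property-prediction heads (logP, SAS, QED) from the latent
vector and train on a joint loss: token cross-entropy, property MSE, an
optional NT-Xent contrastive term over SMILES-enumeration positive pairs,
and a latent L2 penalty.  Greedy decoding plus the SELFIES grammar make the
genotype→phenotype map total and deterministic, which is what the
latent-space optimizers require.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autograd import Tensor
from . import nn
from .molecules import (MoleculeRecord, Vocabulary, DatasetSplit,
                        enumerate_smiles, smiles_to_selfies, tokenize,
                        PROPERTY_NAMES)
from .molecules import _stable_seed
from .selfies_codec import CodecError
from . import selfies_codec

__all__ = [
    "ModelConfig", "LossWeights", "LossBreakdown", "TrainConfig",
    "MolecularAutoencoder", "AutoencoderService", "nt_xent_loss",
    "joint_loss", "train", "evaluate", "visualize_latent",
    "reconstruction_accuracy", "TrainingError",
]

_NEG = -1e9


class TrainingError(RuntimeError):
    """Raised when the loss diverges to a non-finite value."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: the full-scale preset)."""

    architecture: str = "relso"          # "relso" | "fragnet"
    embedding_dim: int = 256
    latent_dim: int = 512
    encoder_layers: int = 6
    attention_heads: int = 8
    feedforward_dim: int = 1024
    dropout: float = 0.2
    contrastive_enabled: bool = True
    max_len: int = 200                   # includes start/end markers
    conv_blocks: int = 3
    conv_kernel: int = 5

    def __post_init__(self):
        if self.architecture not in ("relso", "fragnet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.embedding_dim % self.attention_heads:
            raise ValueError("embedding_dim must be divisible by heads")

    @classmethod
    def desk(cls, architecture: str = "relso",
             contrastive_enabled: bool = True, max_len: int = 64
             ) -> "ModelConfig":
        """CPU-friendly preset: 32-dim embedding, 2 layers, 64-dim latent."""
        return cls(architecture=architecture, embedding_dim=32, latent_dim=64,
                   encoder_layers=2, attention_heads=2, feedforward_dim=64,
                   dropout=0.0, contrastive_enabled=contrastive_enabled,
                   max_len=max_len)


@dataclass
class LossWeights:
    w_recon: float = 1.0
    w_aux: tuple[float, float, float] = (0.25, 0.25, 0.25)
    w_contrast: float = 1.0
    w_l2: float = 0.1
    temperature: float = 0.1

    def __post_init__(self):
        if min(self.w_recon, *self.w_aux, self.w_contrast, self.w_l2) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LossBreakdown:
    recon_ce: float
    aux_mse: dict[str, float]
    contrastive: float
    latent_l2: float
    total: float
    recon_token_accuracy: float

    def as_row(self) -> dict[str, float]:
        row = {"recon_ce": self.recon_ce, "contrastive": self.contrastive,
               "latent_l2": self.latent_l2, "total": self.total,
               "recon_token_accuracy": self.recon_token_accuracy}
        for k, v in self.aux_mse.items():
            row[f"aux_mse_{k}"] = v
        return row


def nt_xent_loss(z: Tensor | np.ndarray, temperature: float = 0.1) -> Tensor:
    """Normalized temperature-scaled cross entropy over 2N latent vectors.

    Rows are ordered pairwise: (0,1), (2,3), ... are the positive pairs.
    For each anchor i with partner j,
    ``l(i,j) = -log( exp(sim(i,j)/τ) / Σ_{k≠i} exp(sim(i,k)/τ) )``
    with cosine similarity, and the loss is the mean of l over all 2N
    anchors (both directions of every pair).
    """
    if not isinstance(z, Tensor):
        z = Tensor(z)
    two_n = z.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("need an even number (2N) of latent vectors")
    norms = ((z ** 2.0).sum(axis=1, keepdims=True)) ** 0.5
    if np.any(norms.data < 1e-12):
        raise FloatingPointError("zero-norm latent vector: cosine undefined")
    zn = z / norms
    sim = (zn @ zn.swap_last() if zn.ndim == 3 else zn @ zn.transpose(1, 0))
    sim = sim * (1.0 / temperature)
    mask = np.zeros((two_n, two_n))
    np.fill_diagonal(mask, _NEG)          # exclude self-similarity
    log_probs = (sim + Tensor(mask)).log_softmax(axis=-1)
    partner = np.arange(two_n) ^ 1        # 0<->1, 2<->3, ...
    return -log_probs.gather_last(partner).mean()


def latent_l2(z: Tensor) -> Tensor:
    """Batch mean of squared Euclidean latent norms."""
    return (z ** 2.0).sum(axis=-1).mean()


def joint_loss(logits: Tensor, target_ids: np.ndarray, pad_id: int,
               z: Tensor, prop_pred: Tensor, prop_targets: np.ndarray,
               weights: LossWeights, contrastive_enabled: bool
               ) -> tuple[Tensor, LossBreakdown]:
    """Weighted joint objective; returns the differentiable total plus a
    float breakdown whose ``total`` equals the weighted sum of its parts."""
    ce, accuracy = nn.cross_entropy(logits, target_ids, ignore_id=pad_id)
    aux_terms: dict[str, float] = {}
    aux_total: Tensor | None = None
    for k, name in enumerate(PROPERTY_NAMES):
        err = ((prop_pred[:, k] - Tensor(prop_targets[:, k])) ** 2.0).mean()
        aux_terms[name] = err.item()
        weighted = err * weights.w_aux[k]
        aux_total = weighted if aux_total is None else aux_total + weighted
    l2 = latent_l2(z)
    total = ce * weights.w_recon + aux_total + l2 * weights.w_l2
    contrast_value = 0.0
    if contrastive_enabled:
        contrast = nt_xent_loss(z, weights.temperature)
        contrast_value = contrast.item()
        total = total + contrast * weights.w_contrast
    if not np.isfinite(total.data):
        raise TrainingError("non-finite loss")
    return total, LossBreakdown(
        recon_ce=ce.item(), aux_mse=aux_terms, contrastive=contrast_value,
        latent_l2=l2.item(), total=total.item(),
        recon_token_accuracy=accuracy)


class MolecularAutoencoder(nn.Module):
    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        super().__init__()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        E, Z, L = config.embedding_dim, config.latent_dim, config.max_len
        self.token_emb = nn.Embedding(len(vocab), E, rng)
        self.pos_emb = nn.Embedding(L, E, rng)
        self.encoder = [nn.TransformerEncoderLayer(
            E, config.attention_heads, config.feedforward_dim,
            config.dropout, rng) for _ in range(config.encoder_layers)]
        # Projection into the latent space: four linear layers with ReLU.
        self.projection = nn.MLP([E, E, E, E, Z], rng)
        self.property_head = nn.MLP([Z, max(Z // 2, 8), len(PROPERTY_NAMES)], rng)
        if config.architecture == "fragnet":
            self.unprojection = nn.MLP([Z, E, E, E, E], rng)
            self.decoder = [nn.TransformerDecoderLayer(
                E, config.attention_heads, config.feedforward_dim,
                config.dropout, rng) for _ in range(config.encoder_layers)]
        else:
            # Expand the latent vector to one channel vector per target
            # position, then refine locally with the conv stack.
            self.latent_to_seq = nn.Linear(Z, (L - 1) * E, rng, he=True)
            self.decoder_pos = nn.Embedding(L, E, rng)
            self.convs = [nn.Conv1d(E, E, config.conv_kernel, rng)
                          for _ in range(config.conv_blocks)]
        self.out_proj = nn.Linear(E, len(vocab), rng)

    # -- encoding ------------------------------------------------------------
    def _encode_states(self, ids: np.ndarray) -> tuple[Tensor, np.ndarray]:
        B, L = ids.shape
        pad_mask = (ids == self.vocab.pad_id)
        x = self.token_emb(ids) + self.pos_emb(np.arange(L))
        attn_mask = np.where(pad_mask[:, None, None, :], _NEG, 0.0)
        for layer in self.encoder:
            x = layer(x, attn_mask)
        return x, pad_mask

    def encode(self, ids: np.ndarray) -> Tensor:
        states, pad_mask = self._encode_states(np.atleast_2d(ids))
        if self.config.architecture == "fragnet":
            pooled = states[:, 0]                      # start-token state
        else:
            keep = (~pad_mask).astype(float)[:, :, None]
            pooled = (states * Tensor(keep)).sum(axis=1) \
                * Tensor(1.0 / keep.sum(axis=1))
        return self.projection(pooled)

    def predict_properties(self, z: Tensor) -> Tensor:
        return self.property_head(z)

    # -- decoding ------------------------------------------------------------
    def decode_logits(self, z: Tensor, teacher_ids: np.ndarray | None = None
                      ) -> Tensor:
        """Logits over L-1 target positions (the sequence minus its start
        marker).  ``fragnet`` requires ``teacher_ids`` (teacher forcing)."""
        L = self.config.max_len
        if self.config.architecture == "relso":
            base = self.latent_to_seq(z).reshape(
                z.shape[0], L - 1, self.config.embedding_dim)
            x = base + self.decoder_pos(np.arange(L - 1))
            for conv in self.convs:
                x = conv(x).relu()
            return self.out_proj(x)
        if teacher_ids is None:
            raise ValueError("fragnet decoding needs teacher ids")
        memory = self.unprojection(z).reshape(z.shape[0], 1, -1)
        inp = teacher_ids[:, :-1]
        x = self.token_emb(inp) + self.pos_emb(np.arange(inp.shape[1]))
        causal = np.where(np.triu(np.ones((inp.shape[1], inp.shape[1])), 1) > 0,
                          _NEG, 0.0)
        for layer in self.decoder:
            x = layer(x, memory, causal)
        return self.out_proj(x)

    def greedy_decode_ids(self, z: Tensor) -> np.ndarray:
        """Deterministic argmax decode to token ids (no start marker)."""
        L = self.config.max_len
        if self.config.architecture == "relso":
            logits = self.decode_logits(z)
            return logits.data.argmax(axis=-1)
        B = z.shape[0]
        ids = np.full((B, L), self.vocab.pad_id, dtype=np.int64)
        ids[:, 0] = self.vocab.bos_id
        finished = np.zeros(B, dtype=bool)
        for pos in range(1, L):
            logits = self.decode_logits(z, ids)
            nxt = logits.data[:, pos - 1].argmax(axis=-1)
            ids[:, pos] = np.where(finished, self.vocab.pad_id, nxt)
            finished |= (nxt == self.vocab.eos_id)
            if finished.all():
                break
        return ids[:, 1:]

    def forward(self, ids: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """(logits over targets, latent vectors, property predictions)."""
        z = self.encode(ids)
        logits = self.decode_logits(z, teacher_ids=ids)
        return logits, z, self.predict_properties(z)


class _PropertyScaler:
    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        self.std = np.where(std < 1e-9, 1.0, std)

    @classmethod
    def fit(cls, records: Sequence[MoleculeRecord]) -> "_PropertyScaler":
        values = np.stack([r.property_vector for r in records])
        return cls(values.mean(axis=0), values.std(axis=0))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.std + self.mean


class AutoencoderService:
    """Molecule-level facade over a trained model: implements the latent
    codec interface used by the optimizers, plus property prediction."""

    def __init__(self, model: MolecularAutoencoder, scaler: _PropertyScaler):
        self.model = model
        self.scaler = scaler

    @property
    def vocab(self) -> Vocabulary:
        return self.model.vocab

    @property
    def latent_dim(self) -> int:
        return self.model.config.latent_dim

    def ids_for(self, selfies_tokens: Sequence[str]) -> np.ndarray:
        return self.vocab.encode(selfies_tokens, length=self.model.config.max_len)

    def encode_smiles(self, smiles: Sequence[str]) -> np.ndarray:
        self.model.eval()
        ids = np.stack([self.ids_for(tokenize(smiles_to_selfies(s)))
                        for s in smiles])
        return self.model.encode(ids).data.copy()

    def decode_latent(self, z: np.ndarray) -> list[str]:
        self.model.eval()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        ids = self.model.greedy_decode_ids(Tensor(z))
        out = []
        for row in ids:
            symbols = self.vocab.decode(row)
            out.append(selfies_codec.decoder(symbols) if symbols else "")
        return out

    def predict_properties(self, z: np.ndarray) -> np.ndarray:
        """(n, 3) predictions in natural units, ordered (logP, QED, SAS)."""
        self.model.eval()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        pred = self.model.predict_properties(Tensor(z)).data
        return self.scaler.inverse(pred)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        meta = {"config": asdict(self.model.config),
                "vocab": self.vocab.id_to_symbol,
                "scaler_mean": self.scaler.mean.tolist(),
                "scaler_std": self.scaler.std.tolist()}
        arrays = {f"p{i}": a for i, a in enumerate(self.model.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "AutoencoderService":
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["meta"]))
        config = ModelConfig(**meta["config"])
        vocab = Vocabulary(meta["vocab"])
        model = MolecularAutoencoder(config, vocab)
        model.load_arrays([blob[f"p{i}"]
                           for i in range(len(model.parameters()))])
        scaler = _PropertyScaler(np.array(meta["scaler_mean"]),
                                 np.array(meta["scaler_std"]))
        return cls(model, scaler)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 2e-5       # ReLSO full-scale default (FragNet: 1e-5)
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 4                 # consecutive validation increases
    val_fraction_of_epoch: float = 0.2
    augmentation_attempts: int = 10
    lr_decay: str = "none"            # "none" | "cosine"
    lr_floor: float = 0.1             # cosine decays to lr_floor * base
    seed: int = 42


def _views_for(record: MoleculeRecord, n_views: int, attempts: int,
               seed: int, max_tokens: int) -> list[tuple[str, ...]]:
    """Token sequences of ``n_views`` SMILES spellings of one molecule.

    Falls back to the canonical spelling when enumeration yields too few
    distinct variants or a variant tokenizes past the length budget.
    """
    views: list[tuple[str, ...]] = []
    if n_views > 1:
        for variant in enumerate_smiles(record.smiles_canonical, attempts, seed):
            try:
                toks = tuple(tokenize(smiles_to_selfies(variant)))
            except CodecError:
                continue
            if len(toks) <= max_tokens:
                views.append(toks)
            if len(views) == n_views:
                break
    while len(views) < n_views:
        views.append(record.tokens)
    return views


def _batch_arrays(records: Sequence[MoleculeRecord],
                  service: "AutoencoderService",
                  n_views: int, attempts: int, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    model = service.model
    scaler = service.scaler
    max_tokens = model.config.max_len - 2
    ids_rows, target_rows, props = [], [], []
    for rec in records:
        canonical_ids = model.vocab.encode(rec.tokens,
                                           length=model.config.max_len)
        for view in _views_for(rec, n_views, attempts,
                               _stable_seed(seed, rec.smiles_canonical), max_tokens):
            ids_rows.append(model.vocab.encode(view, length=model.config.max_len))
            # Reconstruction targets are always the canonical SELFIES:
            # augmented spellings act as input noise, so the contrastive
            # pull toward a shared latent and the reconstruction task agree.
            target_rows.append(canonical_ids)
            props.append(scaler.transform(rec.property_vector))
    return np.stack(ids_rows), np.stack(target_rows), np.stack(props)


def _run_batch(service: AutoencoderService, records, weights: LossWeights,
               n_views: int, attempts: int, seed: int
               ) -> tuple[Tensor, LossBreakdown]:
    model = service.model
    ids, targets, props = _batch_arrays(records, service, n_views, attempts,
                                        seed)
    z = model.encode(ids)
    logits = model.decode_logits(z, teacher_ids=targets)
    prop_pred = model.predict_properties(z)
    contrastive = model.config.contrastive_enabled and n_views == 2
    return joint_loss(logits, targets[:, 1:], model.vocab.pad_id, z, prop_pred,
                      props, weights, contrastive)


def train(service: AutoencoderService, splits: DatasetSplit,
          weights: LossWeights | None = None,
          config: TrainConfig | None = None,
          ) -> list[dict]:
    """Train with joint loss and early stopping.

    A validation pass runs every 20% of an epoch's steps; training stops
    once validation total loss has increased at ``patience`` consecutive
    checkpoints, or at ``max_epochs``.  Returns the checkpoint history
    (train and validation breakdowns per checkpoint); reproducible per
    seed.
    """
    weights = weights or LossWeights()
    config = config or TrainConfig()
    if not splits.train or not splits.validation:
        raise ValueError("train and validation splits must be nonempty")
    model = service.model
    n_views = 2 if model.config.contrastive_enabled else 1
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    records = list(splits.train)
    steps_per_epoch = max(1, int(np.ceil(len(records) / config.batch_size)))
    val_interval = max(1, int(round(config.val_fraction_of_epoch
                                    * steps_per_epoch)))
    history: list[dict] = []
    previous_val = np.inf
    increases = 0
    step = 0
    stop = False
    total_steps = steps_per_epoch * config.max_epochs
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(records))
        for start in range(0, len(records), config.batch_size):
            batch = [records[i] for i in order[start:start + config.batch_size]]
            if config.lr_decay == "cosine":
                frac = step / max(total_steps - 1, 1)
                floor = config.lr_floor
                optimizer.lr = config.learning_rate * (
                    floor + (1 - floor) * 0.5 * (1.0 + np.cos(np.pi * frac)))
            model.train()
            total, breakdown = _run_batch(
                service, batch, weights, n_views, config.augmentation_attempts,
                seed=config.seed * 977 + epoch)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            step += 1
            if step % val_interval == 0:
                val = evaluate(service, splits.validation, weights,
                               seed=config.seed)
                history.append({"step": step, "epoch": epoch,
                                "train": breakdown, "validation": val})
                if val.total > previous_val:
                    increases += 1
                else:
                    increases = 0
                previous_val = val.total
                if increases >= config.patience:
                    stop = True
                    break
        if stop:
            break
    return history


def evaluate(service: AutoencoderService, records: Sequence[MoleculeRecord],
             weights: LossWeights | None = None, seed: int = 0,
             batch_size: int = 64) -> LossBreakdown:
    """Mean loss breakdown over a split (deterministic per seed)."""
    if not records:
        raise ValueError("cannot evaluate an empty split")
    weights = weights or LossWeights()
    model = service.model
    model.eval()
    n_views = 2 if model.config.contrastive_enabled else 1
    sums: dict[str, float] = {}
    aux_sums = {k: 0.0 for k in PROPERTY_NAMES}
    n_batches = 0
    for start in range(0, len(records), batch_size):
        batch = records[start:start + batch_size]
        if len(batch) < 2 and n_views == 2:
            continue  # contrastive term undefined for a single pair member
        _, breakdown = _run_batch(service, batch, weights, n_views,
                                  attempts=10, seed=seed)
        row = breakdown.as_row()
        for key, value in row.items():
            sums[key] = sums.get(key, 0.0) + value
        for key, value in breakdown.aux_mse.items():
            aux_sums[key] += value
        n_batches += 1
    if n_batches == 0:
        raise ValueError("split too small to evaluate")
    mean = {k: v / n_batches for k, v in sums.items()}
    return LossBreakdown(
        recon_ce=mean["recon_ce"],
        aux_mse={k: aux_sums[k] / n_batches for k in PROPERTY_NAMES},
        contrastive=mean["contrastive"], latent_l2=mean["latent_l2"],
        total=mean["total"],
        recon_token_accuracy=mean["recon_token_accuracy"])


def reconstruction_accuracy(service: AutoencoderService,
                            records: Sequence[MoleculeRecord]) -> float:
    """End-to-end token accuracy of greedy decode(encode(x)) against the
    canonical SELFIES token sequence (end marker included)."""
    model = service.model
    model.eval()
    ids = np.stack([service.ids_for(r.tokens) for r in records])
    z = model.encode(ids)
    decoded = model.greedy_decode_ids(z)
    targets = ids[:, 1:]
    mask = targets != model.vocab.pad_id
    width = min(decoded.shape[1], targets.shape[1])
    hits = (decoded[:, :width] == targets[:, :width]) & mask[:, :width]
    return float(hits.sum() / mask.sum())


# ---------------------------------------------------------------------------
# Latent-space visualization
# ---------------------------------------------------------------------------

def visualize_latent(service: AutoencoderService,
                     records: Sequence[MoleculeRecord], out_dir: str,
                     seed: int = 0) -> dict[str, np.ndarray]:
    """2D (PCA→t-SNE) and 3D (PCA→UMAP) latent maps colored by property.

    With at least 51 samples the latent vectors are first reduced to 50
    principal components; below that the PCA stage is skipped with a
    warning.  logP boxplot outliers (1.5 IQR rule) are drawn in cyan.
    Writes ``embedding_2d.csv``, ``embedding_3d.csv`` and one PNG per
    property; returns the embeddings.
    """
    import warnings
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE
    import umap

    os.makedirs(out_dir, exist_ok=True)
    Z = service.encode_smiles([r.smiles_canonical for r in records])
    n = Z.shape[0]
    if n >= 51 and Z.shape[1] > 50:
        Z50 = PCA(n_components=50, random_state=seed).fit_transform(Z)
    else:
        if Z.shape[1] > 50:
            warnings.warn("fewer than 51 samples: skipping the PCA stage")
        Z50 = Z
    perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    emb2 = TSNE(n_components=2, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(Z50)
    emb3 = umap.UMAP(n_components=3, random_state=seed,
                     n_neighbors=max(2, min(15, n - 1))).fit_transform(Z50)
    props = np.stack([r.property_vector for r in records])  # logP, QED, SAS
    logp = props[:, 0]
    q1, q3 = np.percentile(logp, [25, 75])
    iqr = q3 - q1
    outliers = (logp < q1 - 1.5 * iqr) | (logp > q3 + 1.5 * iqr)

    frames = {"pca": Z50}
    for name, emb in (("embedding_2d", emb2), ("embedding_3d", emb3)):
        cols = {f"dim{k}": emb[:, k] for k in range(emb.shape[1])}
        cols.update({"smiles": [r.smiles_canonical for r in records],
                     "logP": props[:, 0], "QED": props[:, 1],
                     "SAS": props[:, 2]})
        frame = pd.DataFrame(cols)
        frame.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        frames[name] = emb
    for k, prop in enumerate(("logP", "QED", "SAS")):
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(emb2[:, 0], emb2[:, 1], c=props[:, k], s=12,
                        cmap="viridis")
        if prop == "logP" and outliers.any():
            ax.scatter(emb2[outliers, 0], emb2[outliers, 1], c="cyan", s=14,
                       label="logP outliers")
            ax.legend(loc="best", fontsize=7)
        fig.colorbar(sc, ax=ax, label=prop)
        ax.set_title(f"latent 2D map — {prop}")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"latent_2d_{prop}.png"), dpi=120)
        plt.close(fig)
    return frames
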