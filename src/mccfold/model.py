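"""The scoring network: token embedding + Transformer encoder over
positions, pairwise feature grid, and a U-Net convolutional trunk producing
the L x L score matrix M.

Per-position encoder states ``h_i`` are combined into a pairwise grid by
concatenating ``h_i``, ``h_j`` and ``h_i * h_j`` — the construction used by
the E2Efold/UFold model lineage. The published architecture of the original
scoring model is not specified in full detail anywhere public, so this is a
configurable network of the same family, not an exact reproduction; the
validity of decoded predictions does not depend on the architecture (or on
training at all), only on the decoder.

Positional information is two-sided: sinusoidal features of the distance
from the 5' end and of the distance from the 3' end. Pair formation in real
and synthetic stems depends on positions relative to both ends, and product
features of two-sided sinusoids expose such relations to the U-Net directly.

Everything is seed-controlled: construction, batch order, and dropout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigError, ContractError
from .formats import ALPHABET, RnaSequence
from .nn import Adam, Tensor, concatenate, constant
from .nn.layers import DTYPE, Linear, Module, TransformerEncoderLayer, UNet
from .structcore import decode, symmetrize

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: k for k, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class ModelConfig:
    """Scoring-network hyper-parameters.

    ``max_len`` must be a multiple of ``2 ** unet_depth`` so pooling halves
    cleanly; the default 512 covers sequences up to 500 bases, while tests
    and desk-scale runs use much smaller lengths.
    """

    embed_dim: int = 24
    n_layers: int = 2
    n_heads: int = 4
    ff_dim: int = 48
    unet_depth: int = 2
    base_channels: int = 8
    max_len: int = 512
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embed_dim", "n_layers", "n_heads", "ff_dim", "unet_depth",
                     "base_channels", "max_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.embed_dim % self.n_heads:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if self.embed_dim % 4:
            raise ConfigError("embed_dim must be a multiple of 4 (two-sided sin/cos)")
        if self.max_len % 2 ** self.unet_depth:
            raise ConfigError(
                f"max_len={self.max_len} must be a multiple of 2^depth={2 ** self.unet_depth}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")


@dataclass
class SequenceBatch:
    """One-hot encoded, right-padded sequences with their true lengths."""

    onehot: np.ndarray    # (B, Lp, 4)
    lengths: np.ndarray   # (B,)
    pad_mask: np.ndarray  # (B, Lp) True at real positions

    @classmethod
    def from_sequences(cls, seqs: list[RnaSequence], depth: int, max_len: int) -> "SequenceBatch":
        if not seqs:
            raise ContractError("empty batch")
        for s in seqs:
            if s.length > max_len:
                raise ContractError(
                    f"sequence {s.identifier!r} has length {s.length} > max_len {max_len}"
                )
        lengths = np.array([s.length for s in seqs])
        block = 2 ** depth
        Lp = int(-(-lengths.max() // block) * block)
        onehot = np.zeros((len(seqs), Lp, 4), dtype=DTYPE)
        for b, s in enumerate(seqs):
            onehot[b, np.arange(s.length), [_BASE_INDEX[c] for c in s.bases]] = 1.0
        pad_mask = np.arange(Lp)[None, :] < lengths[:, None]
        return cls(onehot, lengths, pad_mask)


def _two_sided_positional(lengths: np.ndarray, Lp: int, d: int) -> np.ndarray:
    """Sinusoidal features of position-from-start and position-from-end."""
    B = len(lengths)
    out = np.zeros((B, Lp, d), dtype=DTYPE)
    half = d // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half // 2) / max(1, half // 2)))
    pos = np.arange(Lp, dtype=np.float64)
    for b, L in enumerate(lengths):
        for base, p in ((0, pos), (half, (L - 1) - pos)):
            ang = p[:, None] * freqs[None, :]
            out[b, :, base:base + half // 2] = np.sin(ang)
            out[b, :, base + half // 2:base + half] = np.cos(ang)
    return out


class ScoringNetwork(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embed_dim
        self.embed = Linear(rng, 4, d)
        self.encoder = [TransformerEncoderLayer(rng, d, cfg.n_heads, cfg.ff_dim)
                        for _ in range(cfg.n_layers)]
        self.unet = UNet(rng, 3 * d, cfg.base_channels, cfg.unet_depth)

    def forward_batch(self, batch: SequenceBatch,
                      train_rng: np.random.Generator | None = None) -> Tensor:
        """Raw (asymmetric) score matrices, shape (B, Lp, Lp)."""
        cfg = self.cfg
        B, Lp, _ = batch.onehot.shape
        mask = batch.pad_mask
        mask_f = mask.astype(DTYPE)[:, :, None]

        x = self.embed(Tensor(batch.onehot))
        x = x + constant(_two_sided_positional(batch.lengths, Lp, cfg.embed_dim))
        x = x * constant(mask_f)
        for layer in self.encoder:
            x = layer(x, mask)
        if train_rng is not None and cfg.dropout > 0:
            keep = (train_rng.random(x.shape) >= cfg.dropout).astype(DTYPE)
            x = x * constant(keep / (1.0 - cfg.dropout))
        x = x * constant(mask_f)

        d = cfg.embed_dim
        hi = x.reshape(B, Lp, 1, d).broadcast_to((B, Lp, Lp, d))
        hj = x.reshape(B, 1, Lp, d).broadcast_to((B, Lp, Lp, d))
        grid = concatenate([hi, hj, hi * hj], axis=-1)       # (B, Lp, Lp, 3d)
        grid = grid.transpose(0, 3, 1, 2)                    # NCHW
        grid_mask = mask[:, :, None] & mask[:, None, :]
        return self.unet(grid, grid_mask).reshape(B, Lp, Lp)


def build_model(cfg: ModelConfig) -> ScoringNetwork:
    """Construct the network deterministically from ``cfg.seed``."""
    net = ScoringNetwork(cfg)
    logger.info("built scoring network: %d parameters", net.n_params())
    return net


def forward(net: ScoringNetwork, batch: SequenceBatch) -> np.ndarray:
    """Raw score matrices as a numpy array (B, Lp, Lp); symmetrization is
    the caller's step, matching the training/evaluation flow."""
    return net.forward_batch(batch).data


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 16
    lr: float = 3e-3
    seed: int = 0
    log_every: int = 0          # batches; 0 = epoch-level logging only
    checkpoint_path: str | None = None


def _batch_loss(net: ScoringNetwork, seqs: list[RnaSequence],
                labels: list[np.ndarray],
                train_rng: np.random.Generator | None = None) -> Tensor:
    """Weighted average cross-entropy of one batch, as an autodiff scalar.

    Mirrors :func:`mccfold.loss.weighted_cross_entropy`: each non-padded row
    is one sub-sample, softmax runs over real columns only, and unpaired
    sub-samples (diagonal-labeled) are down-weighted by (n - |D|)/|D|.
    """
    from .structcore import modify_label

    cfg = net.cfg
    batch = SequenceBatch.from_sequences(seqs, cfg.unet_depth, cfg.max_len)
    B, Lp, _ = batch.onehot.shape
    lab = np.zeros((B, Lp, Lp), dtype=DTYPE)
    for b, S in enumerate(labels):
        L = S.shape[0]
        lab[b, :L, :L] = modify_label(S)

    M = net.forward_batch(batch, train_rng)
    Mhat = (M + M.transpose(0, 2, 1)) / 2.0
    logp = Mhat.log_softmax(mask=np.broadcast_to(batch.pad_mask[:, None, :], (B, Lp, Lp)))
    row_ce = -(logp * constant(lab)).sum(axis=-1)            # (B, Lp)

    diag = np.arange(Lp)
    unpaired = (lab[:, diag, diag] == 1) & batch.pad_mask
    n = int(batch.pad_mask.sum())
    ndu = int(unpaired.sum())
    w = np.zeros((B, Lp), dtype=np.float64)
    w[batch.pad_mask & ~unpaired] = 1.0
    if ndu == 0:
        logger.info("batch has no unpaired sub-samples; plain mean of paired terms")
    elif ndu == n:
        logger.info("batch is all-unpaired; unweighted mean")
        w[unpaired] = 1.0
    else:
        w[unpaired] = (n - ndu) / ndu
    return (row_ce * constant(w)).sum() / n


def _make_batches(order: np.ndarray, lengths: np.ndarray, batch_size: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Length-sorted batching (less padding), batch order shuffled."""
    by_len = order[np.argsort(lengths[order], kind="stable")]
    batches = [by_len[k:k + batch_size] for k in range(0, len(by_len), batch_size)]
    rng.shuffle(batches)
    return batches


def train(net: ScoringNetwork, dataset: list[tuple[RnaSequence, np.ndarray]],
          cfg: TrainConfig | None = None) -> list[float]:
    """Minimize the weighted cross-entropy over the dataset.

    Returns the per-epoch mean training loss trace. Batches are formed from
    length-sorted sample groups; batch order and dropout are driven by
    ``cfg.seed``. If ``checkpoint_path`` is set, a checkpoint (weights +
    config + optimizer state + seed) is written after every epoch.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ContractError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.lr)
    if getattr(net, "_opt_state", None) is not None:
        opt.load_state_dict(net._opt_state)
    lengths = np.array([s.length for s, _ in dataset])
    trace = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for bi, idx in enumerate(_make_batches(order, lengths, cfg.batch_size, rng)):
            seqs = [dataset[i][0] for i in idx]
            labels = [dataset[i][1] for i in idx]
            loss = _batch_loss(net, seqs, labels,
                               train_rng=rng if net.cfg.dropout > 0 else None)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            if cfg.log_every and (bi + 1) % cfg.log_every == 0:
                logger.info("epoch %d batch %d loss %.4f", epoch, bi + 1, epoch_losses[-1])
        trace.append(float(np.mean(epoch_losses)))
        logger.info("epoch %d mean loss %.4f", epoch, trace[-1])
        if cfg.checkpoint_path:
            save_checkpoint(net, cfg.checkpoint_path, optimizer=opt,
                            extra={"epoch": epoch, "train_seed": cfg.seed})
    # carry optimizer state so continuing in-process matches resuming from
    # the checkpoint of this run
    net._opt_state = opt.state_dict()
    return trace


def predict(net: ScoringNetwork, seqs: list[RnaSequence],
            batch_size: int = 32) -> list[np.ndarray]:
    """Decoded, guaranteed-valid predictions for each sequence.

    Validity holds for trained and untrained networks alike: it is a
    property of the decoder, not of the weights.
    """
    if not seqs:
        return []
    order = np.argsort([s.length for s in seqs], kind="stable")
    out: list[np.ndarray | None] = [None] * len(seqs)
    for k in range(0, len(seqs), batch_size):
        idx = order[k:k + batch_size]
        batch = SequenceBatch.from_sequences([seqs[i] for i in idx],
                                             net.cfg.unet_depth, net.cfg.max_len)
        M = net.forward_batch(batch).data
        for row, i in enumerate(idx):
            L = seqs[i].length
            out[i] = decode(symmetrize(M[row, :L, :L]))
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: ScoringNetwork, path, optimizer: Adam | None = None,
                    extra: dict | None = None) -> None:
    arrays = {f"param_{k}": p.data for k, p in enumerate(net.params())}
    if optimizer is not None:
        st = optimizer.state_dict()
        arrays.update({f"adam_m_{k}": m for k, m in enumerate(st["m"])})
        arrays.update({f"adam_v_{k}": v for k, v in enumerate(st["v"])})
        arrays["adam_t"] = np.array(st["t"])
    meta = {"config": asdict(net.cfg), "extra": extra or {}}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ScoringNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        net = build_model(ModelConfig(**meta["config"]))
        for k, p in enumerate(net.params()):
            p.data = data[f"param_{k}"].astype(p.data.dtype)
        if "adam_t" in data:
            n = len(net.params())
            net._opt_state = {
                "t": int(data["adam_t"]),
                "m": [data[f"adam_m_{k}"] for k in range(n)],
                "v": [data[f"adam_v_{k}"] for k in range(n)],
            }
    return net
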