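"""The contact-map prediction network.

Three units built on the package's numpy autodiff core:

* **Chromatin feature encoder** — three stride-1 convolutions (7 -> 16 -> 32
  -> 64 channels by default) interleaved with fixed-factor mean pooling, two
  top-k pooling layers that adapt the feature resolution to the output bin
  grid, and a bidirectional LSTM whose per-bin states are projected to the
  sequence dimension; per-channel outer products of the projected features
  give a symmetric pairwise interaction stack.
* **Chromatin interaction reconstructor** — a U-Net-style 2D decoder over
  the pairwise stack: an initial 3x3 convolution, groups of dilated residual
  blocks with x2 spatial downsampling between groups, skip connections on
  the upsampling path, and a final single-channel head whose output is
  symmetrised as (P + P^T) / 2.
* **Cell-type classifier** — two 1D convolutions over the LSTM states,
  global mean pooling, and two fully connected layers to the class logits.

The total resolution reduction of the encoder (conv pools times the two
top-k patches) must equal the bin size exactly; this is validated at
configuration time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .genomic_io import ContactMap, GenomicWindow
from .nn import autograd as ag
from .nn.autograd import Tensor

DILATION_CYCLE = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and geometry of the network.

    ``prod(pool_factors) * topk_patch**2`` must equal ``bin_size`` (the
    encoder's only hard constraint: one feature vector per output bin), and
    ``window_length == n_bins * bin_size``.
    """

    input_channels: int = 7
    encoder_conv_channels: tuple = (16, 32, 64)
    kernel: int = 3
    stride: int = 1
    pool_factors: tuple = (8, 8, 8)
    topk_patch: int = 4
    topk_k: int = 10
    lstm_seq_dim: int = 128
    lstm_hidden: int = 256
    recon_initial_channels: int = 256
    recon_group_channels: tuple = (256, 128, 64, 32, 16)
    blocks_per_group: int = 5
    classifier_conv_channels: tuple = (128, 64)
    classifier_fc_dim: int = 256
    n_cell_types: int = 2
    n_bins: int = 256
    bin_size: int = 8192
    window_length: int = 2_097_152

    def __post_init__(self):
        if self.window_length != self.n_bins * self.bin_size:
            raise ValueError(
                f"window_length {self.window_length} != n_bins * bin_size "
                f"({self.n_bins} * {self.bin_size})"
            )
        total = int(np.prod(self.pool_factors)) * self.topk_patch**2
        if total != self.bin_size:
            raise ValueError(
                f"total encoder downsampling {total} must equal bin_size "
                f"{self.bin_size} (pool_factors {self.pool_factors}, two "
                f"top-k pools of patch {self.topk_patch})"
            )
        if len(self.pool_factors) != len(self.encoder_conv_channels):
            raise ValueError("one pool factor per encoder convolution")
        if self.topk_k <= 0:
            raise ValueError("topk_k must be positive")
        divisor = 2 ** (len(self.recon_group_channels) - 1)
        if self.n_bins % divisor != 0:
            raise ValueError(
                f"n_bins {self.n_bins} must be divisible by 2**(groups-1) = "
                f"{divisor} for the reconstructor's downsampling path"
            )
        if self.lstm_hidden % 2 != 0:
            raise ValueError("lstm_hidden (total over directions) must be even")
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be at least 2")

    @classmethod
    def toy(cls, n_cell_types: int = 2) -> "ModelConfig":
        """Desk-scale geometry: 64 bins of 1,024 bp with slim channels.

        The wide-ish contextual stage (seq dim 32 over 48 hidden units) is
        what lets the small model place TAD boundaries sharply; narrower
        settings reconstruct the distance decay but blur boundaries.
        """
        return cls(
            encoder_conv_channels=(8, 12, 16),
            pool_factors=(4, 4, 4),
            topk_patch=4,
            topk_k=10,
            lstm_seq_dim=32,
            lstm_hidden=48,
            recon_initial_channels=24,
            recon_group_channels=(24, 12),
            blocks_per_group=2,
            classifier_conv_channels=(16, 8),
            classifier_fc_dim=32,
            n_cell_types=n_cell_types,
            n_bins=64,
            bin_size=1024,
            window_length=65_536,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in (
            "encoder_conv_channels",
            "pool_factors",
            "recon_group_channels",
            "classifier_conv_channels",
        ):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ModelOutput:
    contact_pred: ContactMap  # log-scale prediction
    cell_type_logits: np.ndarray


def pairwise_from_features(feats: Tensor) -> Tensor:
    """Per-channel outer product: pairwise[c, i, j] = f[i, c] * f[j, c].

    Symmetric in (i, j) by construction; one 2D channel per feature dim.
    """
    n, c = feats.shape
    ft = ag.transpose(feats)
    left = ag.reshape(ft, (c, n, 1))
    right = ag.reshape(ft, (c, 1, n))
    return ag.mul(left, right)


class _ResidualBlock(nn.Module):
    """Pre-activation residual block of two dilated 3x3 convolutions."""

    def __init__(self, channels, dilation, rng):
        self.conv1 = nn.Conv2d3x3(channels, channels, rng, dilation=dilation)
        self.conv2 = nn.Conv2d3x3(channels, channels, rng, dilation=dilation)

    def forward(self, x):
        h = self.conv1(ag.relu(x))
        h = self.conv2(ag.relu(h))
        return ag.add(x, h)


class ChromNet(nn.Module):
    """Multi-task network: contact-map reconstruction + cell-type logits."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config

        # --- hierarchical feature reduction: convs + fixed-factor pooling
        self.enc_convs = []
        prev = c.input_channels
        for ch in c.encoder_conv_channels:
            self.enc_convs.append(nn.Conv1d(prev, ch, c.kernel, rng))
            prev = ch

        # --- contextual encoding
        self.lstm = nn.LSTM(prev, c.lstm_hidden // 2, rng)
        self.proj = nn.Linear(c.lstm_hidden, c.lstm_seq_dim, rng)

        # --- reconstructor
        groups = c.recon_group_channels
        self.init_conv = nn.Conv2d3x3(c.lstm_seq_dim, groups[0], rng)
        self.enc_groups = []
        self.downsamples = []
        for gi, ch in enumerate(groups):
            blocks = [
                _ResidualBlock(ch, DILATION_CYCLE[b % len(DILATION_CYCLE)], rng)
                for b in range(c.blocks_per_group)
            ]
            self.enc_groups.append(blocks)
            if gi < len(groups) - 1:
                self.downsamples.append(nn.Conv2d1x1(ch, groups[gi + 1], rng))
        self.upsamples = []
        self.dec_convs = []
        for gi in range(len(groups) - 2, -1, -1):
            self.upsamples.append(nn.Conv2d1x1(groups[gi + 1], groups[gi], rng))
            self.dec_convs.append(nn.Conv2d3x3(groups[gi], groups[gi], rng))
        self.restore_conv = nn.Conv2d1x1(groups[0], c.recon_initial_channels, rng)
        self.head_conv = nn.Conv2d1x1(c.recon_initial_channels, 1, rng)

        # --- classifier
        cls_in = c.lstm_hidden
        self.cls_convs = []
        for ch in c.classifier_conv_channels:
            self.cls_convs.append(nn.Conv1d(cls_in, ch, c.kernel, rng))
            cls_in = ch
        self.cls_fc1 = nn.Linear(cls_in, c.classifier_fc_dim, rng)
        self.cls_fc2 = nn.Linear(c.classifier_fc_dim, c.n_cell_types, rng)

    # ------------------------------------------------------------------
    # forward pieces (each returns autodiff tensors)
    # ------------------------------------------------------------------

    def hierarchical_reduce(self, x: Tensor) -> Tensor:
        """Convs with same padding, each followed by mean pooling."""
        h = x
        for conv, factor in zip(self.enc_convs, self.config.pool_factors):
            h = nn.avg_pool1d(ag.relu(conv(h)), factor)
        return h

    def resolution_adapt(self, h: Tensor) -> Tensor:
        """Two top-k pooling layers bring the length down to n_bins."""
        c = self.config
        h = ag.topk_pool1d(h, c.topk_patch, c.topk_k)
        h = ag.topk_pool1d(h, c.topk_patch, c.topk_k)
        if h.shape[1] != c.n_bins:
            raise ValueError(
                f"reduced length {h.shape[1]} does not match n_bins {c.n_bins}"
            )
        return h

    def contextual_encode(self, reduced: Tensor):
        """LSTM over bins; returns (seq_features, pairwise stack, lstm states)."""
        c = self.config
        if reduced.shape[1] != c.n_bins:
            raise ValueError(
                f"sequence length {reduced.shape[1]} != n_bins {c.n_bins}"
            )
        seq_in = ag.transpose(reduced)          # (n_bins, channels)
        hidden = self.lstm(seq_in)              # (n_bins, lstm_hidden)
        feats = self.proj(hidden)               # (n_bins, lstm_seq_dim)
        return feats, pairwise_from_features(feats), hidden

    def reconstruct_contacts(self, pairwise: Tensor) -> Tensor:
        """U-Net-style decode of the pairwise stack to a symmetric map."""
        c = self.config
        h = self.init_conv(pairwise)
        skips = []
        for gi, blocks in enumerate(self.enc_groups):
            for block in blocks:
                h = block(h)
            if gi < len(self.enc_groups) - 1:
                skips.append(h)
                h = self.downsamples[gi](nn.avg_pool2d(h, 2))
        for up, dec, skip in zip(self.upsamples, self.dec_convs, reversed(skips)):
            h = up(nn.upsample2d(h, 2))
            h = ag.add(h, skip)
            h = dec(ag.relu(h))
        h = ag.relu(self.restore_conv(ag.relu(h)))
        h = self.head_conv(h)
        flat = ag.reshape(h, (c.n_bins, c.n_bins))
        sym = ag.scale(ag.add(flat, ag.transpose(flat)), 0.5)
        return sym

    def classify_cell_type(self, hidden: Tensor) -> Tensor:
        h = ag.transpose(hidden)  # (lstm_hidden, n_bins)
        for conv in self.cls_convs:
            h = ag.relu(conv(h))
        pooled = ag.mean(h, axis=1)             # global mean over bins
        pooled = ag.reshape(pooled, (1, h.shape[0]))
        fc = ag.relu(self.cls_fc1(pooled))
        logits = self.cls_fc2(fc)
        return ag.reshape(logits, (self.config.n_cell_types,))

    def forward_tensors(self, x: Tensor):
        """Full forward pass; returns (contact map tensor, logits tensor)."""
        c = self.config
        if x.shape != (c.input_channels, c.window_length):
            raise ValueError(
                f"input shape {x.shape} != ({c.input_channels}, {c.window_length})"
            )
        if not np.all(np.isfinite(x.data)):
            raise ValueError("NaN or inf in model input")
        reduced = self.resolution_adapt(self.hierarchical_reduce(x))
        _, pairwise, hidden = self.contextual_encode(reduced)
        contact = self.reconstruct_contacts(pairwise)
        logits = self.classify_cell_type(hidden)
        return contact, logits

    def forward(self, x, window: GenomicWindow | None = None) -> ModelOutput:
        """Inference entry point on a numpy (7, window_length) stack.

        Runs without graph recording, so memory stays flat even at the
        full-scale geometry.
        """
        with ag.no_grad():
            contact, logits = self.forward_tensors(Tensor(np.asarray(x)))
        c = self.config
        if window is None:
            window = GenomicWindow("window", 0, c.window_length, c.bin_size)
        cmap = ContactMap(window, contact.data, "log")
        return ModelOutput(contact_pred=cmap, cell_type_logits=logits.data.copy())

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, config=self.config.to_json(), **arrays)

    @classmethod
    def load(cls, path) -> "ChromNet":
        with np.load(path, allow_pickle=False) as archive:
            config = ModelConfig.from_json(str(archive["config"]))
            model = cls(config, seed=0)
            params = model.parameters()
            for i, p in enumerate(params):
                stored = archive[f"p{i}"]
                if stored.shape != p.data.shape:
                    raise ValueError("checkpoint does not match configuration")
                p.data = stored.astype(np.float64)
        return model
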