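"""Multi-task training: noise injection, batch composition, joint loss,
Adam with warm-up + cosine annealing, checkpointing and ablation switches.

Per training window the batch holds three kinds of items:

* the target cell's clean tracks with the clean log-scale Hi-C label;
* the target cell's noise-perturbed tracks paired with a noise-perturbed
  Hi-C label (Gaussian sd 0.1 on log-transformed signals and on the valid,
  i.e. nonzero-in-raw, contact entries);
* each auxiliary cell's clean tracks with no Hi-C label (classification
  supervision only — ground truth exists only for the target cell).

The joint loss is an unweighted sum: mean-squared error on log-scale contact
maps over labelled items plus cross-entropy over all items.  Validation and
inference use clean target-cell inputs only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .architecture import ChromNet, ModelConfig
from .genomic_io import ContactMap, GenomicWindow, SignalTrack, one_hot_encode
from .nn import autograd as ag
from .nn.autograd import Tensor
from .synthetic import SyntheticDatasetBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian perturbation applied during training (never at inference)."""

    mean: float = 0.0
    sd: float = 0.1
    apply_to: tuple = ("ctcf", "atac", "hic_labels")

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class BatchItem:
    """One training sample: input stack, class label, optional Hi-C label."""

    x: np.ndarray                 # (7, window_length)
    cell_label: int
    cell_type: str
    noisy: bool = False
    hic_label: np.ndarray | None = None  # (n_bins, n_bins), log scale

    def __post_init__(self):
        if self.noisy and self.hic_label is None:
            raise ValueError("noisy items are target-cell items and need a label")


@dataclass
class LossBreakdown:
    recon: float
    cls: float

    @property
    def total(self) -> float:
        return self.recon + self.cls


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation knobs (the loss weights themselves are fixed at 1:1)."""

    epochs: int = 20
    base_lr: float = 2e-3
    warmup_fraction: float = 0.05
    no_noise: bool = False
    no_aux: bool = False
    only_ctcf: bool = False
    only_atac: bool = False
    patience: int | None = None   # early stop on val total loss; None = off


def inject_noise(signal: SignalTrack, cfg: NoiseConfig, rng) -> SignalTrack:
    """Add elementwise Gaussian noise to a log-state signal track."""
    if signal.transform_state != "log":
        raise ValueError("noise requires log-transformed signal")
    eps = rng.normal(cfg.mean, cfg.sd, size=signal.values.shape)
    return SignalTrack(
        chrom=signal.chrom,
        values=signal.values + eps,
        bin_size=signal.bin_size,
        transform_state="log",
        start=signal.start,
    )


def noise_hic_label(cmap: ContactMap, raw_matrix: np.ndarray, cfg: NoiseConfig, rng) -> ContactMap:
    """Perturb only the valid (nonzero-in-raw) entries of a log-scale map.

    The upper triangle is noised and mirrored so the result stays exactly
    symmetric; raw zeros (unobserved/filtered pairs) stay exactly zero.
    """
    if cmap.scale_state != "log":
        raise ValueError("label noise requires a log-state map")
    n = cmap.matrix.shape[0]
    eps = rng.normal(cfg.mean, cfg.sd, size=(n, n))
    upper = np.triu(eps)
    eps = upper + np.triu(eps, 1).T
    valid = raw_matrix != 0
    out = cmap.matrix + eps * valid
    return ContactMap(cmap.window, out, "log")


def lr_schedule(step: int, warmup_steps: int, total_steps: int, base_lr: float) -> float:
    """Linear warm-up to base_lr, then cosine annealing to zero."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if warmup_steps >= total_steps:
        raise ValueError("warmup_steps must be smaller than total_steps")
    if step < warmup_steps:
        return base_lr * step / warmup_steps
    progress = (step - warmup_steps) / (total_steps - warmup_steps)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


def build_input(
    onehot: np.ndarray, ctcf_log: np.ndarray, atac_log: np.ndarray
) -> np.ndarray:
    """Stack one-hot DNA (5 rows) with log CTCF and log ATAC per-bp tracks."""
    if onehot.shape[0] != 5:
        raise ValueError("expected 5 sequence channels")
    if not (onehot.shape[1] == len(ctcf_log) == len(atac_log)):
        raise ValueError("sequence and track lengths disagree")
    return np.vstack([onehot, ctcf_log[None, :], atac_log[None, :]])


@dataclass
class WindowData:
    """Everything needed to compose one window's training batch."""

    window: GenomicWindow
    onehot: np.ndarray                  # (5, L)
    ctcf_log: dict                      # cell type -> per-bp log values (L,)
    atac_log: dict
    hic_log: np.ndarray                 # (n, n) target-cell log label
    hic_raw: np.ndarray                 # (n, n) target-cell raw (for validity)


def compose_batch(
    wd: WindowData,
    target: str,
    cell_order: tuple,
    noise_cfg: NoiseConfig,
    train_cfg: TrainConfig,
    rng,
) -> list[BatchItem]:
    """Emit (target clean, target noisy, aux clean...) items for one window."""
    if target not in wd.ctcf_log:
        raise ValueError(f"missing target tracks for {target!r}")
    if wd.hic_log is None:
        raise ValueError(f"missing target Hi-C label for window {wd.window}")
    labels = {c: i for i, c in enumerate(cell_order)}

    def tracks(cell, noisy):
        ctcf = wd.ctcf_log[cell]
        atac = wd.atac_log[cell]
        if noisy:
            if "ctcf" in noise_cfg.apply_to:
                ctcf = ctcf + rng.normal(noise_cfg.mean, noise_cfg.sd, ctcf.shape)
            if "atac" in noise_cfg.apply_to:
                atac = atac + rng.normal(noise_cfg.mean, noise_cfg.sd, atac.shape)
        if train_cfg.only_ctcf:
            atac = np.zeros_like(atac)
        if train_cfg.only_atac:
            ctcf = np.zeros_like(ctcf)
        return build_input(wd.onehot, ctcf, atac)

    items = [
        BatchItem(
            x=tracks(target, False),
            cell_label=labels[target],
            cell_type=target,
            hic_label=wd.hic_log,
        )
    ]
    if not train_cfg.no_noise and noise_cfg.sd > 0:
        window = wd.window
        noised = wd.hic_log
        if "hic_labels" in noise_cfg.apply_to:
            noised = noise_hic_label(
                ContactMap(window, wd.hic_log, "log"), wd.hic_raw, noise_cfg, rng
            ).matrix
        items.append(
            BatchItem(
                x=tracks(target, True),
                cell_label=labels[target],
                cell_type=target,
                noisy=True,
                hic_label=noised,
            )
        )
    if not train_cfg.no_aux:
        for cell in cell_order:
            if cell == target or cell not in wd.ctcf_log:
                continue
            items.append(
                BatchItem(
                    x=tracks(cell, False),
                    cell_label=labels[cell],
                    cell_type=cell,
                )
            )
    return items


def compute_loss(model: ChromNet, items: list[BatchItem]):
    """Joint loss over a batch; returns (LossBreakdown, total loss tensor)."""
    recon_terms = []
    cls_terms = []
    for item in items:
        contact, logits = model.forward_tensors(Tensor(item.x))
        if item.hic_label is not None:
            diff = ag.sub(contact, Tensor(item.hic_label))
            recon_terms.append(ag.mean(ag.square(diff)))
        cls_terms.append(ag.softmax_cross_entropy(logits, item.cell_label))
    if recon_terms:
        recon = ag.scale(_sum_tensors(recon_terms), 1.0 / len(recon_terms))
    else:
        logger.warning("batch has no labelled items; classification-only step")
        recon = Tensor(0.0)
    cls = ag.scale(_sum_tensors(cls_terms), 1.0 / len(cls_terms))
    total = ag.add(recon, cls)
    return LossBreakdown(recon=recon.item(), cls=cls.item()), total


def _sum_tensors(tensors):
    out = tensors[0]
    for t in tensors[1:]:
        out = ag.add(out, t)
    return out


# ---------------------------------------------------------------------------
# dataset preparation from a synthetic bundle
# ---------------------------------------------------------------------------


def prepare_windows(
    bundle: SyntheticDatasetBundle,
    model_cfg: ModelConfig,
    target: str,
    step: int,
    chroms: list | None = None,
) -> list[WindowData]:
    """Scan each chromosome of a bundle into model windows with labels.

    Tracks are log-transformed here (noise is added later, on log signals);
    the target cell's contact map is cut to the window, log-transformed, and
    kept alongside its raw version so label noising can see which entries
    are valid.
    """
    from .genomic_io import extract_contact_window, log_transform, window_scan

    out = []
    for chrom, scen in bundle.scenarios.items():
        if chroms is not None and chrom not in chroms:
            continue
        length = scen.n_bins * scen.bin_size
        windows = window_scan(
            chrom, length, model_cfg.window_length, step, model_cfg.bin_size
        )
        onehot_full = one_hot_encode(bundle.genome[chrom])
        ctcf_log = {
            cell: np.log1p(bundle.ctcf[(chrom, cell)].values)
            for cell in scen.cell_types
        }
        atac_log = {
            cell: np.log1p(bundle.atac[(chrom, cell)].values)
            for cell in scen.cell_types
        }
        source = bundle.contact_maps[(chrom, target)]
        for w in windows:
            raw = extract_contact_window(
                source.matrix, chrom, 0, scen.bin_size, w
            )
            out.append(
                WindowData(
                    window=w,
                    onehot=onehot_full[:, w.start : w.end],
                    ctcf_log={c: v[w.start : w.end] for c, v in ctcf_log.items()},
                    atac_log={c: v[w.start : w.end] for c, v in atac_log.items()},
                    hic_log=np.log1p(raw.matrix),
                    hic_raw=raw.matrix,
                )
            )
    return out


# ---------------------------------------------------------------------------
# the trainer
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: ChromNet
    history: list          # per-epoch dicts of train/val losses
    best_epoch: int


def train(
    train_windows: list[WindowData],
    model_cfg: ModelConfig,
    noise_cfg: NoiseConfig,
    train_cfg: TrainConfig,
    target: str,
    cell_order: tuple,
    seed: int = 0,
    val_windows: list[WindowData] | None = None,
    checkpoint_path=None,
) -> TrainResult:
    """Seeded joint training of reconstruction and classification."""
    if not train_windows:
        raise ValueError("no training windows")
    rng = np.random.default_rng([seed, 7])
    model = ChromNet(model_cfg, seed=seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.base_lr)
    steps_per_epoch = len(train_windows)
    total_steps = train_cfg.epochs * steps_per_epoch
    warmup = max(1, int(round(train_cfg.warmup_fraction * total_steps)))

    history = []
    best_val = math.inf
    best_epoch = -1
    best_state = None
    bad_epochs = 0
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(train_windows))
        ep_recon, ep_cls = [], []
        for wi in order:
            items = compose_batch(
                train_windows[wi], target, cell_order, noise_cfg, train_cfg, rng
            )
            breakdown, total = compute_loss(model, items)
            if not math.isfinite(breakdown.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: {breakdown}"
                )
            opt.zero_grad()
            total.backward()
            opt.lr = lr_schedule(step, warmup, total_steps, train_cfg.base_lr)
            opt.step()
            step += 1
            ep_recon.append(breakdown.recon)
            ep_cls.append(breakdown.cls)
        entry = {
            "epoch": epoch,
            "train_recon": float(np.mean(ep_recon)),
            "train_cls": float(np.mean(ep_cls)),
        }
        entry["train_total"] = entry["train_recon"] + entry["train_cls"]
        if val_windows:
            val = evaluate_loss(model, val_windows, target, cell_order)
            entry["val_recon"] = val.recon
            entry["val_cls"] = val.cls
            entry["val_total"] = val.total
            monitored = val.total
        else:
            monitored = entry["train_total"]
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if monitored < best_val:
            best_val = monitored
            best_epoch = epoch
            best_state = [p.data.copy() for p in model.parameters()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if train_cfg.patience is not None and bad_epochs > train_cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break
    if best_state is not None:
        for p, s in zip(model.parameters(), best_state):
            p.data = s
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def evaluate_loss(
    model: ChromNet, windows: list[WindowData], target: str, cell_order: tuple
) -> LossBreakdown:
    """Validation loss on clean target-cell inputs only."""
    labels = {c: i for i, c in enumerate(cell_order)}
    recon, cls = [], []
    for wd in windows:
        x = build_input(wd.onehot, wd.ctcf_log[target], wd.atac_log[target])
        out = model.forward(x, wd.window)
        recon.append(float(np.mean((out.contact_pred.matrix - wd.hic_log) ** 2)))
        z = out.cell_type_logits
        z = z - z.max()
        cls.append(float(np.log(np.exp(z).sum()) - z[labels[target]]))
    return LossBreakdown(recon=float(np.mean(recon)), cls=float(np.mean(cls)))


def predict_window(
    model: ChromNet, wd: WindowData, cell: str, only_ctcf=False, only_atac=False
):
    """Clean-signal inference for one window and one cell type."""
    ctcf = wd.ctcf_log[cell]
    atac = wd.atac_log[cell]
    if only_ctcf:
        atac = np.zeros_like(atac)
    if only_atac:
        ctcf = np.zeros_like(ctcf)
    x = build_input(wd.onehot, ctcf, atac)
    return model.forward(x, wd.window)
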