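"""Synthetic TAD scenarios: genomes, epigenetic tracks, and contact maps.

The generative model is deliberately simple so its ground truth is analytic:

* contacts decay exponentially with bin distance, ``exp(-gamma * |i-j|)``;
* pairs inside the same TAD are boosted by a multiplicative factor ``beta``;
* optional multiplicative lognormal noise keeps raw contacts positive;
* CTCF tracks carry Gaussian-shaped peaks at that cell type's TAD
  boundaries, ATAC tracks carry plateaus over a per-cell-type subset of
  "active" TADs; both sit on a small baseline shared between cell types so
  shared boundaries produce identical local signal.

With ``noise_sd == 0`` the insulation profile of a rendered map attains its
local minima exactly at the scenario's boundary bins, which is what makes
these fixtures usable as ground truth for boundary-recovery checks.

Two or more artificial "cell types" share a configurable fraction of
boundaries and differ at the rest, so cross-cell-type tasks are learnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genomic_io import (
    ContactMap,
    GenomicWindow,
    SignalTrack,
    write_bedgraph,
    write_dense_matrix,
    write_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_CELL_NAMES = ("cellA", "cellB", "cellC", "cellD")


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic generator (one chromosome's worth)."""

    n_bins: int = 64
    bin_size: int = 1024
    n_cell_types: int = 2
    n_boundaries: int = 3
    shared_boundary_fraction: float = 0.5
    gamma: float = 0.08          # exponential distance-decay rate per bin
    beta: float = 3.0            # intra-TAD contact boost (>1)
    noise_sd: float = 0.1        # lognormal sd on raw contacts
    peak_height: float = 8.0     # CTCF peak height over baseline
    peak_width_bins: float = 1.0 # CTCF peak Gaussian sd, in bins
    atac_height: float = 4.0     # ATAC plateau height over active TADs
    baseline_sd: float = 0.1     # shared baseline track noise (|N(0, sd)|)
    cell_noise_sd: float = 0.0   # per-cell-type additive track noise (|N(0, sd)|)
    cell_gain_sd: float = 0.0    # per-cell-type track gain: exp(N(0, sd^2))
    min_gap: int = 12            # min bins between boundaries / from edges
    seed: int = 0


@dataclass(frozen=True)
class TadScenario:
    """Realised boundary layout for every cell type on one chromosome."""

    config: ScenarioConfig
    chrom: str
    boundaries: dict  # cell type -> tuple of strictly increasing bin indices
    shared_boundaries: tuple
    active_tads: dict  # cell type -> frozenset of TAD indices with ATAC signal

    @property
    def n_bins(self):
        return self.config.n_bins

    @property
    def bin_size(self):
        return self.config.bin_size

    @property
    def cell_types(self):
        return tuple(self.boundaries)

    def tad_intervals(self, cell_type):
        """Half-open TAD bin intervals [(0, b1), (b1, b2), ..., (bk, n)]."""
        b = list(self.boundaries[cell_type])
        edges = [0] + b + [self.n_bins]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _sample_positions(rng, n, lo, hi, min_gap, taken=()):
    """Greedily draw n positions in [lo, hi) at least min_gap from each other
    and from `taken`."""
    if n <= 0:
        return []
    candidates = np.arange(lo, hi)
    rng.shuffle(candidates)
    chosen = []
    occupied = list(taken)
    for c in candidates:
        if all(abs(int(c) - p) >= min_gap for p in occupied):
            chosen.append(int(c))
            occupied.append(int(c))
            if len(chosen) == n:
                return chosen
    raise ValueError(
        f"cannot place {n} boundaries with min gap {min_gap} in [{lo}, {hi})"
    )


def make_scenario(config: ScenarioConfig, chrom: str = "chr1") -> TadScenario:
    """Draw a boundary layout deterministically from the config seed.

    Shared boundaries (``round(fraction * n_boundaries)`` of them) appear in
    every cell type; the remainder are private per cell type.
    """
    if config.n_bins < 16:
        raise ValueError("n_bins must be at least 16")
    if not 0.0 <= config.shared_boundary_fraction <= 1.0:
        raise ValueError("shared_boundary_fraction must lie in [0, 1]")
    if config.n_boundaries > config.n_bins - 2:
        raise ValueError("requested boundaries exceed n_bins - 2")
    rng = np.random.default_rng([config.seed, _stable_hash(chrom)])
    margin = config.min_gap
    lo, hi = margin, config.n_bins - margin
    n_shared = int(round(config.shared_boundary_fraction * config.n_boundaries))
    names = list(DEFAULT_CELL_NAMES[: config.n_cell_types])
    if config.n_cell_types > len(DEFAULT_CELL_NAMES):
        names += [f"cell{i}" for i in range(len(DEFAULT_CELL_NAMES), config.n_cell_types)]
    n_private = config.n_boundaries - n_shared
    # a greedy draw can paint itself into a corner; retry whole layouts
    for _attempt in range(200):
        try:
            shared = sorted(_sample_positions(rng, n_shared, lo, hi, config.min_gap))
            privates = {
                name: _sample_positions(rng, n_private, lo, hi, config.min_gap, shared)
                for name in names
            }
            break
        except ValueError:
            continue
    else:
        raise ValueError(
            f"cannot place {config.n_boundaries} boundaries with min gap "
            f"{config.min_gap} in {config.n_bins} bins"
        )
    boundaries = {}
    active = {}
    for name in names:
        blist = tuple(sorted(shared + privates[name]))
        boundaries[name] = blist
        n_tads = len(blist) + 1
        mask = rng.random(n_tads) < 0.5
        if not mask.any():
            mask[int(rng.integers(n_tads))] = True
        active[name] = frozenset(int(i) for i in np.flatnonzero(mask))
    return TadScenario(
        config=config,
        chrom=chrom,
        boundaries=boundaries,
        shared_boundaries=tuple(shared),
        active_tads=active,
    )


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "little")


def _tad_labels(scenario: TadScenario, cell_type: str) -> np.ndarray:
    labels = np.zeros(scenario.n_bins, dtype=int)
    for k, (s, e) in enumerate(scenario.tad_intervals(cell_type)):
        labels[s:e] = k
    return labels


def render_contact_map(scenario: TadScenario, cell_type: str) -> ContactMap:
    """Raw contact map: exp(-gamma |i-j|) x (beta inside a TAD) x noise."""
    if cell_type not in scenario.boundaries:
        raise KeyError(f"unknown cell type {cell_type!r}")
    cfg = scenario.config
    n = scenario.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    m = np.exp(-cfg.gamma * dist)
    labels = _tad_labels(scenario, cell_type)
    same_tad = labels[:, None] == labels[None, :]
    m = m * np.where(same_tad, cfg.beta, 1.0)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(
            [cfg.seed, _stable_hash(scenario.chrom), _stable_hash(cell_type), 1]
        )
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, n))
        eps = np.triu(eps) + np.triu(eps, 1).T  # symmetric noise field
        m = m * np.exp(eps)
    window = GenomicWindow(scenario.chrom, 0, n * scenario.bin_size, scenario.bin_size)
    return ContactMap(window, 0.5 * (m + m.T), "raw")


def render_tracks(scenario: TadScenario, cell_type: str):
    """Per-bp (CTCF, ATAC) raw tracks for one cell type.

    The baseline noise field is drawn once per chromosome and shared between
    cell types, so two cell types agree exactly wherever their peak layouts
    agree (in particular at shared boundaries).
    """
    if cell_type not in scenario.boundaries:
        raise KeyError(f"unknown cell type {cell_type!r}")
    cfg = scenario.config
    length = scenario.n_bins * cfg.bin_size
    base_rng = np.random.default_rng([cfg.seed, _stable_hash(scenario.chrom), 2])
    ctcf = np.abs(base_rng.normal(0.0, cfg.baseline_sd, size=length))
    atac = np.abs(base_rng.normal(0.0, cfg.baseline_sd, size=length))

    bp = np.arange(length, dtype=np.float64)
    sd_bp = cfg.peak_width_bins * cfg.bin_size
    for b in scenario.boundaries[cell_type]:
        center = (b + 0.5) * cfg.bin_size  # centred on the boundary bin
        ctcf += cfg.peak_height * np.exp(-0.5 * ((bp - center) / sd_bp) ** 2)

    intervals = scenario.tad_intervals(cell_type)
    for k in sorted(scenario.active_tads[cell_type]):
        s, e = intervals[k]
        atac[s * cfg.bin_size : e * cfg.bin_size] += cfg.atac_height

    if cfg.cell_noise_sd > 0:
        # independent coverage noise per cell type (two assays of the same
        # genome never share their noise floor)
        cell_rng = np.random.default_rng(
            [cfg.seed, _stable_hash(scenario.chrom), _stable_hash(cell_type), 5]
        )
        ctcf += np.abs(cell_rng.normal(0.0, cfg.cell_noise_sd, size=length))
        atac += np.abs(cell_rng.normal(0.0, cfg.cell_noise_sd, size=length))

    if cfg.cell_gain_sd > 0:
        # per-cell-type assay gain (sequencing depth / antibody efficiency);
        # the same gain applies genome-wide for that cell type
        gain_rng = np.random.default_rng([cfg.seed, _stable_hash(cell_type), 4])
        gain = float(np.exp(gain_rng.normal(0.0, cfg.cell_gain_sd)))
        ctcf *= gain
        atac *= gain

    mk = lambda vals: SignalTrack(chrom=scenario.chrom, values=vals, bin_size=1)
    return mk(ctcf), mk(atac)


def render_genome(scenario: TadScenario) -> str:
    """Uniform-random ACGT sequence for the scenario's chromosome."""
    cfg = scenario.config
    rng = np.random.default_rng([cfg.seed, _stable_hash(scenario.chrom), 3])
    length = scenario.n_bins * cfg.bin_size
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass
class SyntheticDatasetBundle:
    """In-memory dataset: one scenario per chromosome plus rendered arrays."""

    scenarios: dict            # chrom -> TadScenario
    genome: dict               # chrom -> sequence string
    ctcf: dict                 # (chrom, cell) -> SignalTrack (raw, per-bp)
    atac: dict                 # (chrom, cell) -> SignalTrack
    contact_maps: dict         # (chrom, cell) -> ContactMap (raw)
    manifest: dict

    @property
    def cell_types(self):
        first = next(iter(self.scenarios.values()))
        return first.cell_types


def build_bundle(configs: dict) -> SyntheticDatasetBundle:
    """Render a full bundle from {chrom: ScenarioConfig}."""
    scenarios = {c: make_scenario(cfg, chrom=c) for c, cfg in configs.items()}
    genome, ctcf, atac, maps = {}, {}, {}, {}
    for chrom, scen in scenarios.items():
        genome[chrom] = render_genome(scen)
        for cell in scen.cell_types:
            t_ctcf, t_atac = render_tracks(scen, cell)
            ctcf[(chrom, cell)] = t_ctcf
            atac[(chrom, cell)] = t_atac
            maps[(chrom, cell)] = render_contact_map(scen, cell)
    manifest = {
        "format": "chromnet-synthetic-v1",
        "chromosomes": {c: asdict(cfg) for c, cfg in configs.items()},
    }
    return SyntheticDatasetBundle(scenarios, genome, ctcf, atac, maps, manifest)


def make_dataset(configs: dict, out_dir, force: bool = False) -> SyntheticDatasetBundle:
    """Render a bundle and write it to disk in the formats the readers consume
    (FASTA, bedGraph, dense-text matrices, JSON manifest)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_bundle(configs)
    write_fasta(bundle.genome, out / "genome.fa")
    for (chrom, cell), track in bundle.ctcf.items():
        write_bedgraph(track, out / f"ctcf_{cell}_{chrom}.bedGraph")
    for (chrom, cell), track in bundle.atac.items():
        write_bedgraph(track, out / f"atac_{cell}_{chrom}.bedGraph")
    for (chrom, cell), cmap in bundle.contact_maps.items():
        write_dense_matrix(cmap, out / f"hic_{cell}_{chrom}.txt")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote synthetic dataset to %s", out)
    return bundle


def load_manifest_configs(path) -> dict:
    """Rebuild {chrom: ScenarioConfig} from a dataset manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return {
        chrom: ScenarioConfig(**cfg)
        for chrom, cfg in manifest["chromosomes"].items()
    }
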