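"""In-silico epigenetic perturbation: delete CTCF peaks and difference the
model's predictions.

The workflow edits the raw CTCF track inside user-supplied intervals (hard
zeroing by default), re-runs noise-free inference, and reports
``original prediction - perturbed prediction`` so that positive values mark
interactions lost upon deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .architecture import ChromNet
from .genomic_io import GenomicWindow, SignalTrack
from .training import WindowData, build_input

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSpec:
    """Half-open bp intervals to delete, plus the deletion mode.

    mode "zero" hard-removes the signal; "baseline" replaces it with the
    track's median outside the intervals (for robustness studies).
    """

    intervals: tuple  # ((chrom, start, end), ...)
    mode: str = "zero"

    def __post_init__(self):
        if self.mode not in ("zero", "baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        merged = merge_intervals(self.intervals)
        object.__setattr__(self, "intervals", merged)

    @classmethod
    def from_bed(cls, path, mode: str = "zero") -> "PerturbationSpec":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                intervals.append((f[0], int(f[1]), int(f[2])))
        return cls(tuple(intervals), mode)


def merge_intervals(intervals):
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict = {}
    for chrom, s, e in intervals:
        if s >= e:
            raise ValueError(f"empty interval {chrom}:{s}-{e}")
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return tuple(out)


@dataclass
class DifferenceMap:
    """original_pred - perturbed_pred on the log scale; symmetric."""

    delta: np.ndarray
    window: GenomicWindow
    original: np.ndarray
    perturbed: np.ndarray


def delete_peaks(track: SignalTrack, spec: PerturbationSpec) -> SignalTrack:
    """Remove signal inside the spec's intervals; the input is not modified."""
    if track.bin_size != 1:
        raise ValueError("peak deletion operates on per-bp tracks")
    values = track.values.copy()
    track_end = track.start + len(values)
    mask = np.zeros(len(values), dtype=bool)
    for chrom, s, e in spec.intervals:
        if chrom != track.chrom:
            continue
        if s < track.start or e > track_end:
            raise ValueError(
                f"interval {chrom}:{s}-{e} outside track bounds "
                f"{track.chrom}:{track.start}-{track_end}"
            )
        mask[s - track.start : e - track.start] = True
    if spec.mode == "zero":
        values[mask] = 0.0
    else:
        outside = values[~mask]
        baseline = float(np.median(outside)) if outside.size else 0.0
        values[mask] = baseline
    return SignalTrack(
        chrom=track.chrom,
        values=values,
        bin_size=1,
        transform_state=track.transform_state,
        start=track.start,
    )


def predict_difference(
    model: ChromNet,
    wd: WindowData,
    cell: str,
    spec: PerturbationSpec,
    ctcf_raw: SignalTrack | None = None,
) -> DifferenceMap:
    """Forward the clean and CTCF-deleted inputs and difference the maps.

    Deletion is applied to the raw CTCF track before log transform; ATAC is
    left intact.  If ``ctcf_raw`` is omitted it is recovered from the
    window's stored log-state track (the transform is exactly invertible).
    """
    window = wd.window
    for chrom, s, e in spec.intervals:
        if chrom != window.chrom:
            continue
        if s < window.start or e > window.end:
            raise ValueError(
                f"interval {chrom}:{s}-{e} outside window "
                f"{window.chrom}:{window.start}-{window.end}"
            )
    if ctcf_raw is None:
        ctcf_raw = SignalTrack(
            chrom=window.chrom,
            values=np.expm1(wd.ctcf_log[cell]),
            bin_size=1,
            start=window.start,
        )
    deleted = delete_peaks(ctcf_raw, spec)
    x_clean = build_input(wd.onehot, np.log1p(ctcf_raw.values), wd.atac_log[cell])
    x_pert = build_input(wd.onehot, np.log1p(deleted.values), wd.atac_log[cell])
    pred_clean = model.forward(x_clean, window).contact_pred.matrix
    pred_pert = model.forward(x_pert, window).contact_pred.matrix
    return DifferenceMap(
        delta=pred_clean - pred_pert,
        window=window,
        original=pred_clean,
        perturbed=pred_pert,
    )


def locality_statistic(
    diff: DifferenceMap, peak_bin: int, neighborhood_bins: int = 20
):
    """Mean |delta| near the deleted peak vs elsewhere.

    "Near" means both matrix axes within ``neighborhood_bins`` of the peak's
    bin.  Returns (near_mean, far_mean).
    """
    n = diff.delta.shape[0]
    lo = max(0, peak_bin - neighborhood_bins)
    hi = min(n, peak_bin + neighborhood_bins + 1)
    absd = np.abs(diff.delta)
    near_mask = np.zeros((n, n), dtype=bool)
    near_mask[lo:hi, lo:hi] = True
    near = float(absd[near_mask].mean())
    far = float(absd[~near_mask].mean()) if (~near_mask).any() else 0.0
    return near, far
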