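"""Genomic file I/O and window-level tensor preparation.

Coordinates are 0-based, half-open throughout (BED convention).  Sequence
comes from indexed FASTA (pyfaidx), signal tracks from bigWig (pyBigWig) or
4-column bedGraph, and contact matrices from whitespace-delimited dense text
with a sidecar coordinate header.  Missing track coverage reads as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

CHANNELS = "ATCGN"
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval carrying its model bin grid."""

    chrom: str
    start: int
    end: int
    bin_size: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative window start {self.start}")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if (self.end - self.start) % self.bin_size != 0:
            raise ValueError(
                f"window length {self.end - self.start} not divisible by "
                f"bin size {self.bin_size}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_bins(self) -> int:
        return self.length // self.bin_size


@dataclass
class OneHotSequence:
    """Five-channel (A,T,C,G,N) one-hot encoding of a nucleotide string."""

    matrix: np.ndarray
    window: GenomicWindow | None = None


@dataclass
class SignalTrack:
    """Non-negative coverage values for one chromosome interval.

    ``bin_size == 1`` means per-bp values.  ``transform_state`` is "raw" or
    "log"; the log state holds ln(1 + raw) elementwise.
    """

    chrom: str
    values: np.ndarray
    bin_size: int = 1
    transform_state: str = "raw"
    start: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class ContactMap:
    """Square symmetric contact matrix on a window's bin grid."""

    window: GenomicWindow
    matrix: np.ndarray
    scale_state: str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = self.window.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match window "
                f"bin grid ({n}, {n})"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("contact matrix contains non-finite values")

    def symmetrized(self) -> "ContactMap":
        m = 0.5 * (self.matrix + self.matrix.T)
        return ContactMap(self.window, m, self.scale_state)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint chromosome partitions for train / validation / test."""

    train_chroms: frozenset
    val_chroms: frozenset
    test_chroms: frozenset

    def __post_init__(self):
        sets = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(
                        f"split sets overlap on {sorted(sets[i] & sets[j])}"
                    )

    @classmethod
    def from_lists(cls, train, val, test) -> "SplitSpec":
        return cls(frozenset(train), frozenset(val), frozenset(test))


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a 5 x len {0,1} matrix (A,T,C,G,N).

    Any character outside ACGT (after uppercasing) maps to the N channel, so
    every column sums to exactly 1.
    """
    if len(seq) == 0:
        raise ValueError("empty input")
    up = seq.upper()
    idx = np.fromiter(
        (_CHANNEL_INDEX.get(c, 4) for c in up), dtype=np.intp, count=len(up)
    )
    mat = np.zeros((5, len(up)), dtype=np.float64)
    mat[idx, np.arange(len(up))] = 1.0
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (uppercase, non-ACGT as N)."""
    if matrix.shape[0] != 5:
        raise ValueError("expected 5 channels")
    return "".join(CHANNELS[i] for i in matrix.argmax(axis=0))


def read_fasta_window(path, window: GenomicWindow) -> str:
    """Fetch the window's sequence from an indexed FASTA file."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        if window.chrom not in fa:
            raise KeyError(f"chromosome {window.chrom!r} absent from {path}")
        return str(fa[window.chrom][window.start : window.end])


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


def load_signal_track(path, chrom: str, start: int, end: int) -> SignalTrack:
    """Load per-bp raw signal over [start, end); uncovered bp are zero.

    Format is sniffed from the extension: .bw/.bigwig via pyBigWig, anything
    else parsed as 4-column bedGraph.
    """
    if start >= end:
        raise ValueError(f"start {start} must be < end {end}")
    path = Path(path)
    if path.suffix.lower() in {".bw", ".bigwig"}:
        values = _load_bigwig(path, chrom, start, end)
    else:
        values = _load_bedgraph(path, chrom, start, end)
    n_zero = int(np.count_nonzero(values == 0))
    logger.info(
        "loaded %s %s:%d-%d (%.1f%% zero-filled bp)",
        path.name,
        chrom,
        start,
        end,
        100.0 * n_zero / (end - start),
    )
    if np.any(values < 0):
        raise ValueError(f"negative signal values in {path}")
    return SignalTrack(chrom=chrom, values=values, bin_size=1, start=start)


def _load_bigwig(path, chrom, start, end):
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if chrom not in bw.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from {path}")
        vals = np.array(bw.values(chrom, start, end), dtype=np.float64)
    finally:
        bw.close()
    return np.nan_to_num(vals, nan=0.0)


def _load_bedgraph(path, chrom, start, end):
    values = np.zeros(end - start, dtype=np.float64)
    found_chrom = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if fields[0] != chrom:
                continue
            found_chrom = True
            s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                values[lo - start : hi - start] = v
    if not found_chrom:
        raise KeyError(f"chromosome {chrom!r} absent from {path}")
    return values


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as run-length-compressed bedGraph (zero runs skipped)."""
    vals = track.values
    step = track.bin_size
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                v = vals[run_start]
                if v != 0:
                    s = track.start + run_start * step
                    e = track.start + i * step
                    fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")
                run_start = i


def write_bigwig(track: SignalTrack, path, chrom_length: int) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(track.chrom, chrom_length)])
        n = len(track.values)
        starts = track.start + np.arange(n, dtype=np.int64) * track.bin_size
        bw.addEntries(
            [track.chrom] * n,
            [int(s) for s in starts],
            ends=[int(s + track.bin_size) for s in starts],
            values=[float(v) for v in track.values],
        )
    finally:
        bw.close()


def bin_signal(track: SignalTrack, bin_size: int) -> SignalTrack:
    """Average per-bp values into fixed-size bins."""
    if track.bin_size != 1:
        raise ValueError("bin_signal expects a per-bp track")
    n = len(track.values)
    if n % bin_size != 0:
        raise ValueError(f"track length {n} not divisible by bin size {bin_size}")
    binned = track.values.reshape(n // bin_size, bin_size).mean(axis=1)
    return SignalTrack(
        chrom=track.chrom,
        values=binned,
        bin_size=bin_size,
        transform_state=track.transform_state,
        start=track.start,
    )


def log_transform(x, inverse: bool = False):
    """Reversible shifted natural log: y = ln(1+x), x = exp(y) - 1.

    The shift keeps zero contacts/signals finite and makes the transform
    exactly invertible on non-negative data.
    """
    if isinstance(x, SignalTrack):
        if inverse:
            if x.transform_state != "log":
                raise ValueError("inverse transform requires log-state input")
            vals = np.expm1(x.values)
            state = "raw"
        else:
            if x.transform_state != "raw":
                raise ValueError("signal already log-transformed")
            if np.any(x.values < 0):
                raise ValueError("negative raw values")
            vals = np.log1p(x.values)
            state = "log"
        return SignalTrack(
            chrom=x.chrom,
            values=vals,
            bin_size=x.bin_size,
            transform_state=state,
            start=x.start,
        )
    if isinstance(x, ContactMap):
        if inverse:
            if x.scale_state != "log":
                raise ValueError("inverse transform requires log-state input")
            return ContactMap(x.window, np.expm1(x.matrix), "raw")
        if x.scale_state != "raw":
            raise ValueError("contact map already log-transformed")
        if np.any(x.matrix < 0):
            raise ValueError("negative raw contact values")
        return ContactMap(x.window, np.log1p(x.matrix), "log")
    raise TypeError(f"unsupported type {type(x).__name__}")


# ---------------------------------------------------------------------------
# windows and splits
# ---------------------------------------------------------------------------


def window_scan(
    chrom: str, chrom_length: int, window_length: int, step: int, bin_size: int
) -> list[GenomicWindow]:
    """Enumerate sliding windows at starts 0, step, 2*step, ...

    Windows whose span would exceed the chromosome are dropped, not padded.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window_length > chrom_length:
        logger.warning(
            "window length %d exceeds chromosome %s length %d; no windows",
            window_length,
            chrom,
            chrom_length,
        )
        return []
    count = (chrom_length - window_length) // step + 1
    return [
        GenomicWindow(chrom, i * step, i * step + window_length, bin_size)
        for i in range(count)
    ]


def split_chromosomes(
    chrom_lengths: dict,
    spec: SplitSpec,
    window_length: int,
    step: int,
    bin_size: int,
) -> dict:
    """Assign every scanned window to exactly one split by its chromosome."""
    assigned = {"train": [], "val": [], "test": []}
    membership = {}
    for name, chroms in (
        ("train", spec.train_chroms),
        ("val", spec.val_chroms),
        ("test", spec.test_chroms),
    ):
        for c in chroms:
            membership[c] = name
    for chrom, length in chrom_lengths.items():
        split = membership.get(chrom)
        if split is None:
            logger.warning("chromosome %s is in no split; excluded", chrom)
            continue
        assigned[split].extend(window_scan(chrom, length, window_length, step, bin_size))
    for name in ("train", "val", "test"):
        if not assigned[name]:
            logger.warning("split %r is empty", name)
    return assigned


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------


def extract_contact_window(
    source: np.ndarray,
    source_chrom: str,
    source_start: int,
    source_bin: int,
    window: GenomicWindow,
    method: str = "area",
) -> ContactMap:
    """Cut a window's contact map out of a chromosome-level matrix.

    Re-binning from ``source_bin`` to the window's bin size uses
    area-weighted averaging: each target cell is the overlap-length-weighted
    mean of intersecting source cells.  ``method="nearest"`` instead copies
    the source cell containing each target-bin midpoint.
    """
    if window.chrom != source_chrom:
        raise ValueError(f"window chrom {window.chrom!r} != source {source_chrom!r}")
    source = np.asarray(source, dtype=np.float64)
    n_source = source.shape[0]
    source_end = source_start + n_source * source_bin
    if window.start < source_start or window.end > source_end:
        raise ValueError(
            f"window {window.start}-{window.end} outside source coverage "
            f"{source_start}-{source_end}"
        )
    bad = np.argwhere(np.isnan(source))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"NaN in source matrix at cell ({i}, {j})")

    nb = window.n_bins
    tb = window.bin_size
    if method == "nearest":
        mids = window.start + (np.arange(nb) + 0.5) * tb
        src_idx = ((mids - source_start) // source_bin).astype(int)
        sub = source[np.ix_(src_idx, src_idx)]
    elif method == "area":
        # overlap matrix R[t, s] = bp overlap of target bin t with source bin s
        t_edges = window.start + np.arange(nb + 1) * tb
        s_edges = source_start + np.arange(n_source + 1) * source_bin
        lo = np.maximum(t_edges[:-1, None], s_edges[None, :-1])
        hi = np.minimum(t_edges[1:, None], s_edges[None, 1:])
        overlap = np.clip(hi - lo, 0, None).astype(np.float64)
        weight = overlap.sum(axis=1)  # == tb by the coverage precondition
        sub = (overlap @ source @ overlap.T) / np.outer(weight, weight)
    else:
        raise ValueError(f"unknown re-binning method {method!r}")
    sym = 0.5 * (sub + sub.T)
    return ContactMap(window, sym, "raw")


_MATRIX_HEADER = "# chrom={chrom} start={start} bin_size={bin_size} scale={scale}"


def write_dense_matrix(cmap: ContactMap, path) -> None:
    """Write a contact map as whitespace-delimited text with a coordinate
    header line (chrom, start, bin size, scale state)."""
    header = _MATRIX_HEADER.format(
        chrom=cmap.window.chrom,
        start=cmap.window.start,
        bin_size=cmap.window.bin_size,
        scale=cmap.scale_state,
    )
    np.savetxt(path, cmap.matrix, header=header[2:], comments="# ", fmt="%.10g")


def read_dense_matrix(path) -> ContactMap:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path} lacks the coordinate header line")
    meta = dict(item.split("=") for item in header[1:].split())
    matrix = np.loadtxt(path)
    n = matrix.shape[0]
    bin_size = int(meta["bin_size"])
    start = int(meta["start"])
    window = GenomicWindow(meta["chrom"], start, start + n * bin_size, bin_size)
    return ContactMap(window, matrix, meta.get("scale", "raw"))


def write_fasta(sequences: dict, path, line_width: int = 70) -> None:
    """Write {name: sequence} to FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
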