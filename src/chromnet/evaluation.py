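"""Quantitative comparison of predicted and experimental contact maps.

Implements the evaluation stack used throughout the package:

* per-bin insulation profiles (sliding cross-boundary square, mean
  aggregation; local minima mark TAD boundaries) and their z-scored form;
* Pearson/Spearman correlation of insulation profiles;
* distance-stratified correlations (per off-diagonal of the contact map);
* dynamic time warping between differential insulation profiles, with the
  standard monotonicity/continuity step pattern and absolute-difference
  local cost;
* Cohen's d and the coefficient of variation as effect-size utilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import ContactMap

logger = logging.getLogger(__name__)

DEFAULT_INSULATION_WINDOW = 10


@dataclass
class InsulationProfile:
    """Per-bin insulation scores; edge bins without a full window are NaN."""

    scores: np.ndarray
    window_bins: int
    zscored: bool = False
    mu: float | None = None
    sigma: float | None = None


@dataclass
class DifferentialProfile:
    """Difference of two z-scored insulation profiles (cell A minus B)."""

    delta: np.ndarray


@dataclass
class DtwResult:
    distance: float
    path: list  # [(i, j), ...] 0-based, starts (0,0), ends (n-1, m-1)


@dataclass
class DistanceStratifiedResult:
    offsets: np.ndarray
    pearson: np.ndarray
    spearman: np.ndarray
    n_pairs: np.ndarray


def insulation_profile(
    cmap: ContactMap, window_bins: int = DEFAULT_INSULATION_WINDOW
) -> InsulationProfile:
    """Mean contact intensity of the w x w square crossing each bin boundary.

    ``score[i]`` averages the submatrix rows ``i-w .. i-1`` by columns
    ``i .. i+w-1``; lower values mean fewer contacts across the bin, i.e. a
    stronger boundary.  Bins without a full square on both sides get NaN.
    """
    m = cmap.matrix
    n = m.shape[0]
    w = int(window_bins)
    if not 1 <= w < n / 2:
        raise ValueError(f"window_bins {w} must satisfy 1 <= w < n_bins/2 ({n / 2})")
    scores = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        scores[i] = m[i - w : i, i : i + w].mean()
    return InsulationProfile(scores=scores, window_bins=w)


def zscore(profile: InsulationProfile) -> InsulationProfile:
    """Standardise to mean 0 / population sd 1 over the non-NaN bins."""
    s = profile.scores
    valid = ~np.isnan(s)
    if valid.sum() < 2:
        raise ValueError("need at least 2 scorable bins to z-score")
    mu = float(s[valid].mean())
    sigma = float(s[valid].std())  # population (1/n) sd
    if sigma == 0:
        raise ValueError("degenerate profile: zero standard deviation")
    out = np.full_like(s, np.nan)
    out[valid] = (s[valid] - mu) / sigma
    return InsulationProfile(
        scores=out, window_bins=profile.window_bins, zscored=True, mu=mu, sigma=sigma
    )


def insulation_correlation(
    pred: ContactMap, truth: ContactMap, window_bins: int = DEFAULT_INSULATION_WINDOW
):
    """(Pearson, Spearman) between the two maps' insulation profiles."""
    if pred.matrix.shape != truth.matrix.shape:
        raise ValueError("contact maps must share geometry")
    p = insulation_profile(pred, window_bins).scores
    t = insulation_profile(truth, window_bins).scores
    valid = ~(np.isnan(p) | np.isnan(t))
    if valid.sum() < 3:
        raise ValueError("fewer than 3 commonly scorable bins")
    pearson = stats.pearsonr(p[valid], t[valid]).statistic
    spearman = stats.spearmanr(p[valid], t[valid]).statistic
    return float(pearson), float(spearman)


def distance_stratified_correlation(
    pred: ContactMap, truth: ContactMap, max_offset: int | None = None
) -> DistanceStratifiedResult:
    """Pearson/Spearman between matching superdiagonals, one offset at a time.

    ``max_offset`` defaults to ``2 Mb / bin_size`` capped at ``n_bins - 1``.
    Zero-variance diagonals yield NaN with a warning, never an exception.
    """
    if pred.matrix.shape != truth.matrix.shape:
        raise ValueError("contact maps must share geometry")
    n = pred.matrix.shape[0]
    if max_offset is None:
        max_offset = min(n - 1, 2_000_000 // pred.window.bin_size)
    if not 1 <= max_offset < n:
        raise ValueError(f"max_offset {max_offset} must lie in [1, n_bins)")
    offsets = np.arange(1, max_offset + 1)
    pearson = np.full(len(offsets), np.nan)
    spearman = np.full(len(offsets), np.nan)
    n_pairs = np.zeros(len(offsets), dtype=int)
    for k, d in enumerate(offsets):
        a = np.diagonal(pred.matrix, offset=d)
        b = np.diagonal(truth.matrix, offset=d)
        n_pairs[k] = len(a)
        if a.std() == 0 or b.std() == 0:
            logger.warning("zero-variance diagonal at offset %d", d)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pearson[k] = stats.pearsonr(a, b).statistic
            spearman[k] = stats.spearmanr(a, b).statistic
    return DistanceStratifiedResult(offsets, pearson, spearman, n_pairs)


def differential_profile(
    profile_a: InsulationProfile, profile_b: InsulationProfile
) -> DifferentialProfile:
    """Elementwise difference of two z-scored profiles (A minus B)."""
    if not (profile_a.zscored and profile_b.zscored):
        raise ValueError("differential profile requires z-scored inputs")
    if profile_a.scores.shape != profile_b.scores.shape:
        raise ValueError("profiles must have equal length")
    return DifferentialProfile(delta=profile_a.scores - profile_b.scores)


def dtw_distance(x, y) -> DtwResult:
    """Dynamic time warping with |x_i - y_j| local cost.

    Unconstrained band; the warping path must start at (0, 0), end at
    (n-1, m-1), and move by one in i, j, or both (monotonicity +
    continuity).  Ties between moves prefer the diagonal.
    """
    x = _as_sequence(x)
    y = _as_sequence(y)
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n, m), np.inf)
    move = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    acc[0, 0] = cost[0, 0]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        move[i, 0] = 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        move[0, j] = 2
    for i in range(1, n):
        for j in range(1, m):
            options = (acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            best = int(np.argmin(options))  # argmin takes first = diagonal on ties
            acc[i, j] = options[best] + cost[i, j]
            move[i, j] = best
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        step = move[i, j]
        if step == 0:
            i, j = i - 1, j - 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return DtwResult(distance=float(acc[n - 1, m - 1]), path=path)


def _as_sequence(x):
    if isinstance(x, DifferentialProfile):
        x = x.delta
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("empty input sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values (drop NaN bins first)")
    return arr


def drop_nan_pairwise(a: np.ndarray, b: np.ndarray):
    """Keep positions where both vectors are finite (for pre-DTW cleanup)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mask = np.isfinite(a) & np.isfinite(b)
    return a[mask], b[mask]


def cohens_d(sample_a, sample_b) -> float:
    """Standardised mean difference with the pooled-sd (n_a+n_b-2) denominator."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def coefficient_of_variation(sample) -> float:
    """Population sd divided by the mean."""
    x = np.asarray(sample, dtype=np.float64)
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    return float(x.std() / mean)


def local_minima(profile: InsulationProfile) -> np.ndarray:
    """Bins whose score is strictly below both finite neighbours.

    Used to read TAD boundaries off an insulation profile.
    """
    s = profile.scores
    n = len(s)
    out = []
    for i in range(1, n - 1):
        if np.isnan(s[i - 1]) or np.isnan(s[i]) or np.isnan(s[i + 1]):
            continue
        if s[i] < s[i - 1] and s[i] < s[i + 1]:
            out.append(i)
    return np.array(out, dtype=int)
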