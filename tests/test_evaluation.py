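"""Unit and property tests for the evaluation stack.

Each metric is checked against an independent brute-force oracle; DTW is
checked against exhaustive enumeration of all monotone warping paths.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromnet.evaluation import (
    DifferentialProfile,
    InsulationProfile,
    cohens_d,
    coefficient_of_variation,
    differential_profile,
    distance_stratified_correlation,
    dtw_distance,
    drop_nan_pairwise,
    insulation_correlation,
    insulation_profile,
    local_minima,
    zscore,
)
from chromnet.genomic_io import ContactMap, GenomicWindow


def random_map(n, seed, bin_size=1024):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    w = GenomicWindow("c", 0, n * bin_size, bin_size)
    return ContactMap(w, m, "raw")


def insulation_oracle(matrix, w):
    """Independent double-loop implementation of the cross-boundary square."""
    n = matrix.shape[0]
    scores = np.full(n, np.nan)
    for i in range(n):
        if i - w < 0 or i + w > n:
            continue
        total, count = 0.0, 0
        for r in range(i - w, i):
            for c in range(i, i + w):
                total += matrix[r, c]
                count += 1
        scores[i] = total / count
    return scores


class TestInsulation:
    def test_constant_matrix_gives_constant_profile(self):
        w = GenomicWindow("c", 0, 16 * 64, 64)
        cmap = ContactMap(w, np.full((16, 16), 3.0), "raw")
        prof = insulation_profile(cmap, 4)
        valid = ~np.isnan(prof.scores)
        assert np.allclose(prof.scores[valid], 3.0)
        # edge bins unscorable
        assert np.isnan(prof.scores[:4]).all() and np.isnan(prof.scores[-3:]).all()

    def test_two_tad_block_matrix_argmin_at_boundary(self):
        n, b, beta, gamma = 32, 14, 50.0, 0.05
        idx = np.arange(n)
        m = np.exp(-gamma * np.abs(idx[:, None] - idx[None, :]))
        same = (idx[:, None] < b) == (idx[None, :] < b)
        m = m * np.where(same, beta, 1.0)
        w = GenomicWindow("c", 0, n * 64, 64)
        prof = insulation_profile(ContactMap(w, m, "raw"), 5)
        assert np.nanargmin(prof.scores) == b

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("w", [1, 4, 10])
    def test_matches_brute_force_oracle(self, seed, w):
        cmap = random_map(48, seed)
        got = insulation_profile(cmap, w).scores
        want = insulation_oracle(cmap.matrix, w)
        assert np.allclose(got, want, atol=1e-9, equal_nan=True)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            insulation_profile(random_map(16, 0), 8)


class TestZscore:
    def test_closed_form(self):
        prof = InsulationProfile(np.array([1.0, 2.0, 3.0]), 1)
        z = zscore(prof)
        assert np.allclose(z.scores.mean(), 0)
        assert np.allclose(z.scores.std(), 1)  # population sd
        assert z.zscored

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(0)
        prof = InsulationProfile(rng.normal(size=50), 1)
        z1 = zscore(prof)
        z2 = zscore(z1)
        assert np.abs(z1.scores - z2.scores).max() < 1e-12

    def test_nan_edges_preserved_and_stats_masked(self):
        scores = np.array([np.nan, 1.0, 2.0, 3.0, np.nan])
        z = zscore(InsulationProfile(scores, 1))
        assert np.isnan(z.scores[[0, 4]]).all()
        inner = z.scores[1:4]
        # oracle: z-score of the non-NaN entries only
        want = (scores[1:4] - 2.0) / np.std([1, 2, 3])
        assert np.allclose(inner, want)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            zscore(InsulationProfile(np.full(10, 2.0), 1))


class TestInsulationCorrelation:
    def test_identical_maps_give_unity(self):
        cmap = random_map(32, 1)
        p, s = insulation_correlation(cmap, cmap, 5)
        assert p == pytest.approx(1.0) and s == pytest.approx(1.0)

    def test_negated_profile_anticorrelates(self):
        cmap = random_map(32, 2)
        neg = ContactMap(cmap.window, cmap.matrix.max() - cmap.matrix, "raw")
        p, _ = insulation_correlation(cmap, neg, 5)
        assert p == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        a, b = random_map(40, 3), random_map(40, 4)
        p, s = insulation_correlation(a, b, 6)
        pa = insulation_oracle(a.matrix, 6)
        pb = insulation_oracle(b.matrix, 6)
        mask = ~(np.isnan(pa) | np.isnan(pb))
        x, y = pa[mask], pb[mask]
        xc, yc = x - x.mean(), y - y.mean()
        want_p = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert p == pytest.approx(want_p, abs=1e-9)
        want_s = stats.spearmanr(x, y).statistic
        assert s == pytest.approx(want_s, abs=1e-12)


class TestDistanceStratified:
    def test_identity_gives_unity_everywhere(self):
        cmap = random_map(32, 5)
        res = distance_stratified_correlation(cmap, cmap, 10)
        assert np.allclose(res.pearson, 1.0)
        assert np.array_equal(res.n_pairs, 32 - res.offsets)

    def test_location_invariance(self):
        cmap = random_map(32, 6)
        shifted = ContactMap(cmap.window, cmap.matrix + 5.0, "raw")
        res = distance_stratified_correlation(cmap, shifted, 10)
        assert np.allclose(res.pearson, 1.0)

    def test_matches_explicit_index_oracle_at_offset_3(self):
        a, b = random_map(24, 7), random_map(24, 8)
        res = distance_stratified_correlation(a, b, 5)
        xs = [a.matrix[i, i + 3] for i in range(24 - 3)]
        ys = [b.matrix[i, i + 3] for i in range(24 - 3)]
        want = stats.pearsonr(xs, ys).statistic
        assert res.pearson[2] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_diagonal_gives_nan_not_error(self):
        w = GenomicWindow("c", 0, 8 * 64, 64)
        flat = ContactMap(w, np.ones((8, 8)), "raw")
        res = distance_stratified_correlation(flat, flat, 3)
        assert np.isnan(res.pearson).all()

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_stratified_correlation(random_map(8, 0), random_map(16, 0), 3)


class TestDifferentialProfile:
    def _z(self, values):
        return zscore(InsulationProfile(np.asarray(values, float), 1))

    def test_identical_profiles_give_zero(self):
        a = self._z([1, 2, 3, 4])
        assert np.allclose(differential_profile(a, a).delta, 0)

    def test_antisymmetry(self):
        a, b = self._z([1, 2, 3, 4]), self._z([4, 1, 3, 2])
        assert np.allclose(
            differential_profile(a, b).delta, -differential_profile(b, a).delta
        )

    def test_identity_subtraction(self):
        a = InsulationProfile(np.array([1.0, 0.0, -1.0]), 1, zscored=True)
        b = InsulationProfile(np.zeros(3), 1, zscored=True)
        assert np.array_equal(differential_profile(a, b).delta, [1, 0, -1])

    def test_requires_zscored_inputs(self):
        raw = InsulationProfile(np.array([1.0, 2.0, 3.0]), 1)
        with pytest.raises(ValueError, match="z-scored"):
            differential_profile(raw, raw)


def dtw_oracle(x, y):
    """Exhaustive enumeration of every monotone, continuous warping path."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(x[i] - y[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDtw:
    def test_equal_sequences_give_zero_and_diagonal_path(self):
        x = np.array([0.3, -1.2, 0.8, 2.0])
        res = dtw_distance(x, x)
        assert res.distance == 0
        assert res.path == [(i, i) for i in range(4)]

    def test_two_point_example(self):
        res = dtw_distance([0.0, 0.0], [1.0, 1.0])
        assert res.distance == pytest.approx(2.0)

    def test_warping_absorbs_repeats(self):
        res = dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0])
        assert res.distance == pytest.approx(0.0)

    def test_path_constraints(self):
        rng = np.random.default_rng(9)
        res = dtw_distance(rng.normal(size=7), rng.normal(size=5))
        assert res.path[0] == (0, 0) and res.path[-1] == (6, 4)
        for (i0, j0), (i1, j1) in zip(res.path, res.path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}

    def test_distance_is_cost_sum_along_path(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = dtw_distance(x, y)
        assert res.distance == pytest.approx(
            sum(abs(x[i] - y[j]) for i, j in res.path)
        )

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(1, 6))
        m = data.draw(st.integers(1, 6))
        x = np.array(data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=m, max_size=m)))
        assert dtw_distance(x, y).distance == pytest.approx(
            dtw_oracle(x, y), abs=1e-9
        )

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            d_xy = dtw_distance(x, y).distance
            d_yx = dtw_distance(y, x).distance
            assert d_xy >= 0
            assert d_xy == pytest.approx(d_yx)

    def test_accepts_differential_profiles_and_drops_nan(self):
        a = DifferentialProfile(np.array([np.nan, 1.0, 2.0]))
        b = DifferentialProfile(np.array([1.0, 2.0, np.nan]))
        xa, xb = drop_nan_pairwise(a.delta, b.delta)
        # only position 1 survives in both: |1 - 2| = 1
        assert np.array_equal(xa, [1.0]) and np.array_equal(xb, [2.0])
        assert dtw_distance(xa, xb).distance == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestEffectSizes:
    def test_cohens_d_identical_samples_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0

    def test_cohens_d_hand_example(self):
        # means 3, 1; pooled sd sqrt(2) -> d = sqrt(2)
        assert cohens_d([2, 4], [0, 2]) == pytest.approx(np.sqrt(2))

    def test_cohens_d_antisymmetric(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_cohens_d_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_cv_constant_sample_is_zero(self):
        assert coefficient_of_variation([5, 5, 5]) == 0

    def test_cv_closed_form(self):
        assert coefficient_of_variation([1, 3]) == pytest.approx(0.5)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(2, 1, size=30) + 1
        assert coefficient_of_variation(3.7 * x) == pytest.approx(
            coefficient_of_variation(x)
        )

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestBoundaryRecovery:
    def test_local_minima_equal_generator_boundaries(self):
        from chromnet.synthetic import ScenarioConfig, make_scenario, render_contact_map

        for seed in range(8):
            cfg = ScenarioConfig(n_bins=64, n_boundaries=3, noise_sd=0.0, seed=seed)
            scen = make_scenario(cfg)
            for cell in scen.cell_types:
                cmap = render_contact_map(scen, cell)
                prof = insulation_profile(cmap, 5)
                assert set(local_minima(prof)) == set(scen.boundaries[cell])
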