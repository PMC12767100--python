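"""Unit tests for coordinates, encodings, tracks, and contact-matrix I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromnet.genomic_io import (
    ContactMap,
    GenomicWindow,
    SignalTrack,
    SplitSpec,
    bin_signal,
    decode_one_hot,
    extract_contact_window,
    load_signal_track,
    log_transform,
    one_hot_encode,
    read_dense_matrix,
    split_chromosomes,
    window_scan,
    write_bedgraph,
    write_bigwig,
    write_dense_matrix,
)


class TestOneHot:
    @pytest.mark.parametrize(
        "char,channel",
        [("A", 0), ("T", 1), ("C", 2), ("G", 3), ("N", 4), ("n", 4), ("X", 4)],
    )
    def test_single_character_channel(self, char, channel):
        col = one_hot_encode(char)[:, 0]
        expected = np.zeros(5)
        expected[channel] = 1
        assert np.array_equal(col, expected)

    def test_atcgn_gives_identity_permutation(self):
        mat = one_hot_encode("ATCGN")
        assert np.array_equal(mat, np.eye(5))
        assert np.array_equal(mat.sum(axis=0), np.ones(5))

    def test_columns_sum_to_one_and_roundtrip(self):
        seq = "acgtNRYWSxq" * 5
        mat = one_hot_encode(seq)
        assert mat.shape == (5, len(seq))
        assert np.array_equal(mat.sum(axis=0), np.ones(len(seq)))
        decoded = decode_one_hot(mat)
        expected = "".join(c if c in "ATCG" else "N" for c in seq.upper())
        assert decoded == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty input"):
            one_hot_encode("")

    def test_matches_per_character_lookup(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTNX"), size=50))
        mat = one_hot_encode(seq)
        lookup = {"A": 0, "T": 1, "C": 2, "G": 3}
        for i, ch in enumerate(seq):
            assert mat[:, i].argmax() == lookup.get(ch, 4)


class TestSignalTracks:
    def test_bedgraph_zero_fill(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t10\t12\t3.0\n")
        track = load_signal_track(p, "chr1", 10, 14)
        assert np.array_equal(track.values, [3, 3, 0, 0])

    def test_query_outside_coverage_is_zero(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t10\t12\t3.0\n")
        track = load_signal_track(p, "chr1", 100, 110)
        assert np.array_equal(track.values, np.zeros(10))

    def test_absent_chromosome_errors(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t10\t12\t3.0\n")
        with pytest.raises(KeyError, match="chr9"):
            load_signal_track(p, "chr9", 0, 10)

    def test_reversed_interval_errors(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t10\t12\t3.0\n")
        with pytest.raises(ValueError):
            load_signal_track(p, "chr1", 10, 10)

    def test_bedgraph_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        values = np.round(rng.gamma(1.0, 2.0, size=200), 4)
        track = SignalTrack(chrom="chr1", values=values)
        path = tmp_path / "rt.bedGraph"
        write_bedgraph(track, path)
        back = load_signal_track(path, "chr1", 0, 200)
        assert np.allclose(back.values, values, atol=1e-6)

    def test_bigwig_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        values = rng.gamma(1.0, 2.0, size=100).astype(np.float32).astype(float)
        track = SignalTrack(chrom="chr1", values=values)
        path = tmp_path / "rt.bw"
        write_bigwig(track, path, chrom_length=1000)
        back = load_signal_track(path, "chr1", 0, 100)
        assert np.allclose(back.values, values, atol=1e-4)

    def test_bin_signal_means(self):
        track = SignalTrack(chrom="c", values=[1, 1, 3, 3])
        assert np.array_equal(bin_signal(track, 2).values, [1, 3])

    def test_bin_signal_constant(self):
        track = SignalTrack(chrom="c", values=np.full(12, 2.5))
        assert np.allclose(bin_signal(track, 4).values, 2.5)

    def test_bin_signal_matches_blockwise_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.random(32)
        got = bin_signal(SignalTrack(chrom="c", values=values), 4).values
        oracle = [values[i : i + 4].mean() for i in range(0, 32, 4)]
        assert np.allclose(got, oracle)

    def test_bin_signal_nondivisible_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            bin_signal(SignalTrack(chrom="c", values=np.ones(10)), 3)


class TestLogTransform:
    def test_closed_form_values(self):
        t = SignalTrack(chrom="c", values=[0.0, np.e - 1.0])
        out = log_transform(t)
        assert out.transform_state == "log"
        assert np.allclose(out.values, [0.0, 1.0])

    def test_roundtrip_track_and_map(self):
        rng = np.random.default_rng(4)
        t = SignalTrack(chrom="c", values=rng.gamma(1, 5, size=100))
        rt = log_transform(log_transform(t), inverse=True)
        assert np.abs(rt.values - t.values).max() < 1e-9

        w = GenomicWindow("c", 0, 8, 1)
        m = rng.gamma(1, 5, size=(8, 8))
        m = 0.5 * (m + m.T)
        cm = ContactMap(w, m, "raw")
        back = log_transform(log_transform(cm), inverse=True)
        assert np.abs(back.matrix - m).max() < 1e-9

    def test_state_errors(self):
        t = log_transform(SignalTrack(chrom="c", values=[1.0]))
        with pytest.raises(ValueError):
            log_transform(t)  # double forward
        with pytest.raises(ValueError):
            log_transform(SignalTrack(chrom="c", values=[1.0]), inverse=True)

    def test_negative_raw_rejected(self):
        t = SignalTrack(chrom="c", values=[1.0])
        t.values = np.array([-1.0])
        with pytest.raises(ValueError, match="negative"):
            log_transform(t)


class TestWindowScan:
    def test_enumeration_example(self):
        ws = window_scan("chr1", 3_097_152, 2_097_152, 500_000, 8192)
        assert [w.start for w in ws] == [0, 500_000, 1_000_000]

    def test_exact_fit_gives_one_window(self):
        assert len(window_scan("c", 4096, 4096, 1024, 64)) == 1

    def test_large_step_gives_one_window(self):
        assert len(window_scan("c", 5000 * 64, 4096 * 64, 10**9, 64)) == 1

    def test_oversized_window_gives_empty_list(self):
        assert window_scan("c", 1000, 2048, 100, 64) == []

    @given(
        st.integers(1, 500),
        st.integers(1, 500),
        st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_count_matches_closed_form(self, length_bins, window_bins, step_bins):
        # work in units of one 64-bp bin so windows stay grid-aligned
        b = 64
        if window_bins > length_bins:
            return
        ws = window_scan("c", length_bins * b, window_bins * b, step_bins * b, b)
        expected = (length_bins - window_bins) // step_bins + 1
        assert len(ws) == expected
        assert all(w.end <= length_bins * b for w in ws)


class TestSplits:
    def test_partition_counts_match_per_chrom_scans(self):
        lengths = {f"c{i}": 64 * (100 + 10 * i) for i in range(1, 6)}
        spec = SplitSpec.from_lists(["c1", "c2", "c3"], ["c4"], ["c5"])
        splits = split_chromosomes(lengths, spec, 64 * 10, 64 * 3, 64)
        for name, chroms in [("train", ["c1", "c2", "c3"]), ("val", ["c4"]), ("test", ["c5"])]:
            expected = sum(
                len(window_scan(c, lengths[c], 64 * 10, 64 * 3, 64)) for c in chroms
            )
            assert len(splits[name]) == expected
        # no window appears in two splits
        all_windows = [
            (w.chrom, w.start) for part in splits.values() for w in part
        ]
        assert len(all_windows) == len(set(all_windows))

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec.from_lists(["c1"], ["c1"], ["c2"])

    def test_empty_val_is_valid(self):
        lengths = {"c1": 64 * 100}
        spec = SplitSpec.from_lists(["c1"], [], [])
        splits = split_chromosomes(lengths, spec, 64 * 10, 64 * 5, 64)
        assert splits["val"] == [] and len(splits["train"]) > 0

    def test_unassigned_chromosome_excluded(self, caplog):
        lengths = {"c1": 64 * 100, "c9": 64 * 100}
        spec = SplitSpec.from_lists(["c1"], [], [])
        splits = split_chromosomes(lengths, spec, 64 * 10, 64 * 5, 64)
        assert all(w.chrom == "c1" for w in splits["train"])


class TestContactExtraction:
    def test_identity_rebinning_is_submatrix_copy(self):
        rng = np.random.default_rng(5)
        m = rng.random((16, 16))
        m = 0.5 * (m + m.T)
        w = GenomicWindow("c", 4 * 10, 12 * 10, 10)
        out = extract_contact_window(m, "c", 0, 10, w)
        assert np.allclose(out.matrix, m[4:12, 4:12])

    def test_area_weighted_2x2_to_1(self):
        src = np.array([[4.0, 0.0], [0.0, 4.0]])
        w = GenomicWindow("c", 0, 4, 4)
        out = extract_contact_window(src, "c", 0, 2, w)
        assert out.matrix.shape == (1, 1)
        assert np.isclose(out.matrix[0, 0], 2.0)

    def test_output_symmetric_for_random_symmetric_source(self):
        rng = np.random.default_rng(6)
        m = rng.random((24, 24))
        m = 0.5 * (m + m.T)
        w = GenomicWindow("c", 0, 240, 30)  # 10 -> 30 bp re-binning
        out = extract_contact_window(m, "c", 0, 10, w)
        assert np.abs(out.matrix - out.matrix.T).max() < 1e-9

    def test_mass_conservation_on_aligned_grids(self):
        rng = np.random.default_rng(7)
        m = rng.random((24, 24))
        m = 0.5 * (m + m.T)
        w = GenomicWindow("c", 0, 240, 20)  # whole span, 10 -> 20 bp
        out = extract_contact_window(m, "c", 0, 10, w)
        # area-weighted mean conserves total mass: sum(cell * area) invariant
        assert np.isclose((out.matrix * 20 * 20).sum(), (m * 10 * 10).sum(), rtol=1e-6)

    def test_out_of_coverage_errors(self):
        m = np.ones((4, 4))
        w = GenomicWindow("c", 0, 80, 10)
        with pytest.raises(ValueError, match="outside source coverage"):
            extract_contact_window(m, "c", 0, 10, w)

    def test_nan_names_offending_cell(self):
        m = np.ones((8, 8))
        m[2, 3] = np.nan
        w = GenomicWindow("c", 0, 80, 10)
        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            extract_contact_window(m, "c", 0, 10, w)


class TestDenseMatrixIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        m = rng.random((8, 8))
        m = 0.5 * (m + m.T)
        w = GenomicWindow("chr2", 64, 64 + 8 * 16, 16)
        path = tmp_path / "m.txt"
        write_dense_matrix(ContactMap(w, m, "raw"), path)
        back = read_dense_matrix(path)
        assert back.window == w
        assert back.scale_state == "raw"
        assert np.allclose(back.matrix, m, atol=1e-9)
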