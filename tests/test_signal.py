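"""Pileup, Tn5 correction, matrices and metagene profiles."""

from __future__ import annotations

import numpy as np
import pytest

from epitype.intervals import GenomicInterval, PeakSet
from epitype.signal import (
    ReadRecord,
    SignalTrack,
    SiteSignalMatrix,
    bimodality_index,
    exclude_chroms,
    extend_and_pileup,
    metagene_profile,
    normalize_per_million,
    read_bedgraph,
    signal_matrix,
    tn5_correct,
    write_bedgraph,
)

from oracles import bruteforce_matrix


def random_reads(rng, n, chrom_len, chrom="chr1"):
    return [
        ReadRecord(
            chrom,
            int(rng.integers(200, chrom_len - 200)),
            "+" if rng.random() < 0.5 else "-",
        )
        for _ in range(n)
    ]


class TestTn5Correct:
    def test_plus_and_minus_offsets(self):
        out = tn5_correct([ReadRecord("chr1", 1000, "+"), ReadRecord("chr1", 2000, "-")])
        assert (out[0].five_prime, out[1].five_prime) == (1004, 1995)

    def test_empty_and_clipping(self):
        assert tn5_correct([]) == []
        assert tn5_correct([ReadRecord("chr1", 2, "-")])[0].five_prime == 0

    def test_count_and_strand_composition_preserved(self, rng):
        reads = random_reads(rng, 500, 100_000)
        out = tn5_correct(reads)
        assert len(out) == len(reads)
        assert sum(r.strand == "+" for r in out) == sum(r.strand == "+" for r in reads)
        for before, after in zip(reads, out):
            assert after.five_prime == before.five_prime + (4 if before.strand == "+" else -5)

    def test_mitochondrial_exclusion(self):
        reads = [ReadRecord("chrM", 5, "+"), ReadRecord("chr1", 5, "+")]
        assert [r.chrom for r in exclude_chroms(reads)] == ["chr1"]


class TestExtendAndPileup:
    def test_single_plus_read(self):
        track = extend_and_pileup([ReadRecord("chr1", 100, "+")], 150)
        v = track.values["chr1"]
        assert v[99] == 0 and np.all(v[100:250] == 1.0)
        assert track.total_reads == 1 and track.fragment_length == 150

    def test_minus_read_covers_five_prime_base(self):
        track = extend_and_pileup([ReadRecord("chr1", 500, "-")], 100,
                                  chrom_lengths={"chr1": 1000})
        v = track.values["chr1"]
        assert np.all(v[401:501] == 1.0) and v[400] == 0 and v[501] == 0

    def test_mass_conservation(self, rng):
        for fragment in (150, 200, 230, 250):
            reads = random_reads(rng, 200, 50_000)
            track = extend_and_pileup(reads, fragment,
                                      chrom_lengths={"chr1": 50_000})
            assert track.total_signal() + track.clipped_mass == pytest.approx(
                200 * fragment
            )

    def test_clipped_mass_accounting(self):
        track = extend_and_pileup([ReadRecord("chr1", 5, "-")], 100,
                                  chrom_lengths={"chr1": 1000})
        assert track.total_signal() == 6  # bases [0, 6)
        assert track.clipped_mass == 94

    def test_binned_pileup_is_per_base_mean(self, rng):
        reads = random_reads(rng, 50, 5_000)
        base = extend_and_pileup(reads, 80, chrom_lengths={"chr1": 5_000})
        binned = extend_and_pileup(reads, 80, bin_size=25,
                                   chrom_lengths={"chr1": 5_000})
        expected = base.values["chr1"].reshape(-1, 25).mean(axis=1)
        np.testing.assert_allclose(binned.values["chr1"], expected)

    def test_fragment_length_validation(self):
        with pytest.raises(ValueError):
            extend_and_pileup([], 0)


class TestNormalize:
    def test_scaling_and_identity(self):
        t = SignalTrack({"chr1": np.array([3.0])}, total_reads=1_500_000)
        assert normalize_per_million(t).values["chr1"][0] == pytest.approx(2.0)
        t2 = SignalTrack({"chr1": np.array([3.0, 7.0])}, total_reads=1_000_000)
        np.testing.assert_allclose(
            normalize_per_million(t2).values["chr1"], t2.values["chr1"]
        )

    def test_mass_scales_by_factor(self, rng):
        v = rng.random(1000)
        t = SignalTrack({"chr1": v}, total_reads=123_456)
        n = normalize_per_million(t)
        assert n.total_signal() == pytest.approx(t.total_signal() * 1e6 / 123_456)

    def test_error_cases(self):
        t = SignalTrack({"chr1": np.ones(4)}, total_reads=0)
        with pytest.raises(ValueError):
            normalize_per_million(t)
        t2 = SignalTrack({"chr1": np.ones(4)}, total_reads=10)
        with pytest.raises(ValueError):
            normalize_per_million(normalize_per_million(t2))


class TestSignalMatrix:
    def test_column_count_and_constant_track(self):
        track = SignalTrack({"chr1": np.full(100_000, 2.5)})
        sites = PeakSet([GenomicInterval("chr1", 50_000, 50_300)])
        m = signal_matrix(track, sites, window=1500, bin_size=50)
        assert m.values.shape == (1, 60)
        np.testing.assert_allclose(m.values, 2.5)

    def test_matches_per_base_bruteforce(self, rng):
        for _ in range(5):
            arr = rng.random(50_000)
            track = SignalTrack({"chr1": arr})
            sites = PeakSet([
                GenomicInterval("chr1", int(s), int(s) + 200)
                for s in rng.integers(500, 48_000, size=8)
            ])
            m = signal_matrix(track, sites, window=1500, bin_size=50)
            expected = bruteforce_matrix({"chr1": arr}, sites.intervals, 1500, 50)
            np.testing.assert_allclose(m.values, expected, atol=1e-12)

    def test_chromosome_edge_padded_with_zeros(self):
        track = SignalTrack({"chr1": np.ones(2_000)})
        sites = PeakSet([GenomicInterval("chr1", 0, 100)])  # centre 50
        m = signal_matrix(track, sites, window=1500, bin_size=50)
        expected = bruteforce_matrix({"chr1": np.ones(2_000)}, sites.intervals, 1500, 50)
        np.testing.assert_allclose(m.values, expected)

    def test_missing_chromosome_names_site(self):
        track = SignalTrack({"chr1": np.ones(10_000)})
        sites = PeakSet([GenomicInterval("chr2", 100, 200, name="lost")])
        with pytest.raises(KeyError, match="lost"):
            signal_matrix(track, sites)

    def test_indivisible_window_rejected(self):
        track = SignalTrack({"chr1": np.ones(10_000)})
        with pytest.raises(ValueError):
            signal_matrix(track, PeakSet([GenomicInterval("chr1", 5000, 5100)]),
                          window=1500, bin_size=49)

    def test_tsv_roundtrip(self, tmp_path, rng):
        m = SiteSignalMatrix(
            ["a", "b"], "ATAC", 1500, 50, rng.random((2, 60))
        )
        m.to_tsv(tmp_path / "m.tsv")
        back = SiteSignalMatrix.from_tsv(tmp_path / "m.tsv", assay="ATAC")
        assert back.site_ids == ["a", "b"]
        assert (back.window, back.bin_size) == (1500, 50)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5)


class TestMetageneAndBimodality:
    def test_single_site_profile_is_its_row(self, rng):
        row = rng.random(60)
        m = SiteSignalMatrix(["s"], "x", 1500, 50, row[None, :])
        np.testing.assert_allclose(metagene_profile(m), row)

    def test_mirror_pair_gives_constant_profile(self):
        r = np.linspace(0, 1, 60)
        c = 2.0
        m = SiteSignalMatrix(["a", "b"], "x", 1500, 50,
                             np.vstack([r, -r + 2 * c]))
        np.testing.assert_allclose(metagene_profile(m), c)

    def test_profile_is_column_mean(self, rng):
        vals = rng.random((100, 60))
        m = SiteSignalMatrix([f"s{i}" for i in range(100)], "x", 1500, 50, vals)
        np.testing.assert_allclose(metagene_profile(m), vals.mean(axis=0),
                                   atol=1e-9)
        with pytest.raises(ValueError):
            metagene_profile(
                SiteSignalMatrix([], "x", 1500, 50, np.empty((0, 60)))
            )

    def _profile_from(self, f, window=1500, bin_size=50):
        centers = np.arange(-window, window, bin_size) + bin_size / 2
        return f(centers)

    def test_flat_profile_is_unity(self):
        p = np.full(60, 3.0)
        assert bimodality_index(p) == pytest.approx(1.0, abs=1e-6)

    def test_flank_peaks_give_index_above_one(self):
        p = self._profile_from(
            lambda x: np.exp(-0.5 * ((x - 500) / 150) ** 2)
            + np.exp(-0.5 * ((x + 500) / 150) ** 2)
        )
        assert bimodality_index(p) > 1

    def test_center_peak_gives_index_below_one(self):
        p = self._profile_from(lambda x: np.exp(-0.5 * (x / 150) ** 2))
        assert bimodality_index(p) < 1

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            bimodality_index(np.ones(16), window=400, bin_size=50)


class TestBedGraphIO:
    def test_roundtrip(self, tmp_path, rng):
        v = np.round(rng.random(400), 4)
        v[rng.random(400) < 0.3] = 0.0
        t = SignalTrack({"chr1": v, "chr2": np.zeros(10)})
        write_bedgraph(t, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph")
        np.testing.assert_allclose(back.values["chr1"][: len(v)], v)
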