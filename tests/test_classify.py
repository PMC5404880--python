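"""Clustering, type labelling, chi-square, categories, retention and PCA."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epitype.classify import (
    AccessibilityProfile,
    EnhancerSignature,
    chi_square_accessibility,
    classify_types,
    enhancer_categories,
    enhancer_retention,
    kmeans_sites,
    pca_samples,
)
from epitype.intervals import GenomicInterval, PeakSet

from conftest import random_peakset
from oracles import chi2_closed_form, pair_overlaps


class TestKMeans:
    def test_separable_groups(self):
        X = np.vstack([np.zeros((5, 4)), np.full((5, 4), 10.0)])
        labels, inertia = kmeans_sites(X, k=2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert inertia == pytest.approx(0.0)

    def test_identical_rows_do_not_crash(self):
        X = np.ones((6, 3))
        labels, _ = kmeans_sites(X, k=2, seed=0)
        assert len(labels) == 6

    def test_two_archetypes_recovered_exactly(self):
        rng = np.random.default_rng(13)
        sigma = 1.0
        a = rng.normal(0.0, sigma, size=(100, 6))
        b = rng.normal(5 * sigma, sigma, size=(100, 6))  # 5 sigma separation
        X = np.vstack([a, b])
        truth = np.array([0] * 100 + [1] * 100)
        labels, _ = kmeans_sites(X, k=2, seed=13)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.random((40, 4))
        l1, _ = kmeans_sites(X, k=3, seed=11)
        l2, _ = kmeans_sites(X, k=3, seed=11)
        assert np.array_equal(l1, l2)

    def test_k_larger_than_rows_is_error(self):
        with pytest.raises(ValueError):
            kmeans_sites(np.ones((3, 2)), k=4, seed=0)


def _profiles(values_list, tps=("+Dox", "12h", "24h", "3d")):
    return [
        AccessibilityProfile(f"s{i}", tps, tuple(float(x) for x in v))
        for i, v in enumerate(values_list)
    ]


class TestClassifyTypes:
    def test_collapsing_and_persistent_sites_labelled(self):
        vals = [(10, 1, 1, 1)] * 5 + [(10, 9, 9, 8)] * 5
        out = classify_types(_profiles(vals), seed=0, persistence_threshold=0.5)
        labels = {c.site_id: c.type_label for c in out}
        assert all(labels[f"s{i}"] == "Type1" for i in range(5))
        assert all(labels[f"s{i}"] == "Type2" for i in range(5, 10))
        ratios = {c.site_id: c.persistence_ratio for c in out}
        assert ratios["s0"] == pytest.approx(0.1)
        assert ratios["s5"] == pytest.approx(0.9)

    def test_zero_baseline_marked_unassigned(self):
        vals = [(10, 1, 1, 1)] * 3 + [(10, 9, 9, 8)] * 3 + [(0, 0, 0, 0)]
        out = classify_types(_profiles(vals), seed=0)
        by_id = {c.site_id: c for c in out}
        assert by_id["s6"].type_label == "unassigned"
        assert by_id["s6"].cluster == -1

    def test_scale_and_order_invariance(self):
        vals = [(10, 1, 2, 1)] * 4 + [(8, 7, 7, 6)] * 4
        base = classify_types(_profiles(vals), seed=3)
        scaled = classify_types(
            _profiles([tuple(10 * x for x in v) for v in vals]), seed=3
        )
        assert [c.type_label for c in base] == [c.type_label for c in scaled]
        shuffled = list(reversed(_profiles(vals)))
        out = classify_types(shuffled, seed=3)
        lab = {c.site_id: c.type_label for c in out}
        assert lab == {c.site_id: c.type_label for c in base}

    def test_labels_assigned_per_cluster_not_per_site(self):
        # one stray persistent-looking profile inside the collapsing group
        vals = [(10, 1, 1, 1)] * 10 + [(10, 9, 9, 9)] * 10
        out = classify_types(_profiles(vals), seed=0)
        clusters = {}
        for c in out:
            clusters.setdefault(c.cluster, set()).add(c.type_label)
        assert all(len(s) == 1 for s in clusters.values())


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi_square_accessibility([[50, 50], [50, 50]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(1, 200, size=(2, 2))
            stat, p = chi_square_accessibility(t)
            stat_o, p_o = chi2_closed_form(t)
            assert stat == pytest.approx(stat_o, rel=1e-9)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_zero_row_or_column_is_error(self):
        with pytest.raises(ValueError):
            chi_square_accessibility([[0, 0], [10, 10]])
        with pytest.raises(ValueError):
            chi_square_accessibility([[0, 10], [0, 10]])


class TestEnhancerCategories:
    def _interval(self, start, end):
        return GenomicInterval("chr1", start, end)

    def test_both_and_neither(self):
        sites = PeakSet([self._interval(100, 200), self._interval(5000, 5100)])
        k4 = PeakSet([self._interval(150, 300)])
        k27 = PeakSet([self._interval(50, 120)])
        sigs, fracs = enhancer_categories(sites, k4, k27)
        assert sigs[0].category == "both"
        assert sigs[1].category == "neither"
        assert sum(fracs.values()) == Fraction(1)

    def test_fractions_match_bruteforce_tally(self, rng):
        sites = random_peakset(rng, 100, 50_000)
        k4 = random_peakset(rng, 30, 50_000)
        k27 = random_peakset(rng, 30, 50_000)
        sigs, fracs = enhancer_categories(sites, k4, k27)
        for sig, iv in zip(sigs, sites):
            h1 = any(pair_overlaps(iv, m) for m in k4)
            h2 = any(pair_overlaps(iv, m) for m in k27)
            expected = (
                "both" if h1 and h2
                else "H3K4me1 only" if h1
                else "H3K27ac only" if h2
                else "neither"
            )
            assert sig.category == expected
        assert sum(fracs.values()) == Fraction(1)


class TestRetention:
    def _sigs(self, cats):
        return [EnhancerSignature(f"s{i}", c) for i, c in enumerate(cats)]

    def test_identical_before_after_gives_full_retention(self):
        before = self._sigs(["both", "both", "neither"])
        types = {"s0": "Type1", "s1": "Type2", "s2": "Type2"}
        out = enhancer_retention(before, before, types)
        assert out == {"Type1": 1.0, "Type2": 1.0}

    def test_total_loss_gives_zero(self):
        before = self._sigs(["both", "both"])
        after = self._sigs(["neither", "neither"])
        types = {"s0": "Type1", "s1": "Type2"}
        out = enhancer_retention(before, after, types)
        assert out == {"Type1": 0.0, "Type2": 0.0}

    def test_mismatched_universe_is_error(self):
        with pytest.raises(ValueError):
            enhancer_retention(
                self._sigs(["both"]), self._sigs(["both", "both"]), {"s0": "Type1"}
            )


class TestPCA:
    def _table(self, rows, columns=None):
        arr = np.asarray(rows, dtype=float)
        cols = columns or [f"chr1:{i * 1000}-{i * 1000 + 100}"
                           for i in range(arr.shape[1])]
        return pd.DataFrame(arr, columns=cols)

    def test_identical_samples_get_identical_coordinates(self):
        t = self._table([[1, 2, 3, 4]] * 2 + [[5, 1, 0, 2]])
        coords, _ = pca_samples(t)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_explained_variance_sums_to_one_and_decreases(self, rng):
        t = self._table(rng.random((6, 10)))
        _, ev = pca_samples(t)
        assert ev.sum() == pytest.approx(1.0)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_sign_convention_makes_output_reproducible(self, rng):
        t = self._table(rng.random((5, 8)))
        c1, _ = pca_samples(t)
        c2, _ = pca_samples(t.copy())
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy())

    def test_restriction_filters_features(self):
        t = self._table(
            [[1, 0, 5], [2, 0, 6], [3, 0, 7]],
            columns=["chr1:0-100", "chr1:500-600", "chr2:0-100"],
        )
        keep = PeakSet([GenomicInterval("chr1", 0, 100),
                        GenomicInterval("chr2", 0, 100)])
        coords, ev = pca_samples(t, restrict_to=keep)
        assert coords.shape[0] == 3
        # the two kept features vary identically -> one informative component
        assert ev[0] == pytest.approx(1.0)

    def test_too_few_features_after_restriction_is_error(self):
        t = self._table([[1, 2], [3, 4]],
                        columns=["chr1:0-100", "chr1:500-600"])
        with pytest.raises(ValueError):
            pca_samples(t, restrict_to=PeakSet([GenomicInterval("chr1", 0, 100)]))
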