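"""Diversity statistics, distances, ordination and the Mantel test."""
from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from ssrgbs.config_io import GenotypeMatrix, SampleEntry
from ssrgbs.errors import PipelineError
from ssrgbs.popgen import (DistanceMatrix, allele_sharing_spectrum,
                           filter_markers_by_missing, geographic_distances,
                           locus_stats, mantel, pairwise_allele_distance, pcoa)


def _matrix(calls: dict, samples, loci, coding="sequence") -> GenotypeMatrix:
    m = GenotypeMatrix(samples=list(samples), loci=list(loci), coding=coding)
    for (s, l), call in calls.items():
        m.set_call(s, l, call)
    return m


# -- locus statistics -------------------------------------------------------


class TestLocusStats:
    def test_monomorphic_locus(self):
        m = _matrix({(s, "L1"): (1, 1) for s in "abcd"}, "abcd", ["L1"])
        (st,) = locus_stats(m)
        assert (st.Na, st.He, st.PIC, st.Ho) == (1, 0.0, 0.0, 0.0)

    def test_two_alleles_at_half(self):
        """He = 1 - 2(0.5^2) = 0.5; PIC = 0.5 - 2(0.25*0.25) = 0.375."""
        m = _matrix({("a", "L1"): (1, 2), ("b", "L1"): (2, 1)}, "ab", ["L1"])
        (st,) = locus_stats(m)
        assert st.He == pytest.approx(0.5, abs=1e-12)
        assert st.PIC == pytest.approx(0.375, abs=1e-12)
        assert st.Ho == 1.0

    def test_four_alleles_uniform(self):
        """He = 0.75; PIC = 1 - 0.25 - ((0.25)^2 - 4(0.25^4))... = 0.703125."""
        m = _matrix({("a", "L1"): (1, 2), ("b", "L1"): (3, 4)}, "ab", ["L1"])
        (st,) = locus_stats(m)
        assert st.He == pytest.approx(0.75, abs=1e-12)
        assert st.PIC == pytest.approx(0.703125, abs=1e-12)

    def test_pic_never_exceeds_he_on_random_frequency_vectors(self, rng):
        from ssrgbs.popgen import _pic

        for _ in range(1000):
            k = int(rng.integers(1, 8))
            p = rng.dirichlet(np.ones(k))
            he = 1.0 - float(np.sum(p ** 2))
            assert _pic(p) <= he + 1e-12

    def test_missing_fraction_and_subset(self):
        calls = {("a", "L1"): (1, 1), ("b", "L1"): (1, 2)}
        m = _matrix(calls, "abcd", ["L1"])
        (st,) = locus_stats(m)
        assert st.missing_frac == pytest.approx(0.5)
        (st_sub,) = locus_stats(m, samples=["a", "b"])
        assert st_sub.missing_frac == 0.0


def test_filter_markers_by_missing():
    calls = {("a", "L1"): (1, 1), ("b", "L1"): (1, 2),
             ("a", "L2"): (1, 1)}  # L2 missing for 2/3 samples
    m = _matrix(calls, "abc", ["L1", "L2"])
    filtered, removed = filter_markers_by_missing(m, max_missing=0.5)
    assert removed == ["L2"]
    assert filtered.loci == ["L1"]
    # threshold 1.0 keeps everything
    same, none_removed = filter_markers_by_missing(m, max_missing=1.0)
    assert none_removed == []
    with pytest.raises(PipelineError):
        filter_markers_by_missing(m, max_missing=-0.1)


def test_allele_sharing_spectrum_counts_each_allele_once():
    calls = {("a", "L1"): (1, 1), ("b", "L1"): (1, 2), ("c", "L1"): (3, 3),
             ("a", "L2"): (1, 2)}
    m = _matrix(calls, "abc", ["L1", "L2"])
    spectrum = allele_sharing_spectrum(m)
    # L1: allele1 carried by a,b (2); allele2 by b (1); allele3 by c (1);
    # L2: alleles 1,2 by a only -> two singletons
    assert spectrum == {1: 4, 2: 1}
    assert sum(spectrum.values()) == 5  # total distinct alleles


# -- distances --------------------------------------------------------------


def _brute_pair_distance(call_a, call_b):
    """Oracle: count how many of B's allele copies A cannot match."""
    remaining = list(call_a)
    diff = 0
    for allele in call_b:
        if allele in remaining:
            remaining.remove(allele)
        else:
            diff += 1
    return diff


class TestPairwiseDistance:
    def test_identical_genotypes_zero(self):
        m = _matrix({("a", "L1"): (1, 2), ("b", "L1"): (1, 2)}, "ab", ["L1"])
        total, mean = pairwise_allele_distance(m)
        assert total.values[0, 1] == 0

    def test_definitional_cases(self):
        m = _matrix({("a", "L1"): (1, 1), ("b", "L1"): (1, 2),
                     ("c", "L1"): (2, 2)}, "abc", ["L1"])
        total, _ = pairwise_allele_distance(m)
        assert total.values[0, 1] == 1  # {a,a} vs {a,b}
        assert total.values[0, 2] == 2  # {a,a} vs {b,b}

    def test_matches_brute_force_on_random_matrices(self, rng):
        samples = [f"s{i}" for i in range(5)]
        loci = [f"L{j}" for j in range(4)]
        for _ in range(1000):
            calls = {}
            for s in samples:
                for l in loci:
                    if rng.random() < 0.15:
                        continue  # missing cell
                    calls[(s, l)] = tuple(sorted(rng.integers(1, 4, size=2)))
            m = _matrix(calls, samples, loci)
            total, mean = pairwise_allele_distance(m)
            for i, a in enumerate(samples):
                for j, b in enumerate(samples[i + 1:], start=i + 1):
                    acc, shared = 0, 0
                    for l in loci:
                        ca, cb = m.get(a, l), m.get(b, l)
                        if ca and cb:
                            acc += _brute_pair_distance(ca, cb)
                            shared += 1
                    if shared:
                        assert total.values[i, j] == acc
                        assert mean.values[i, j] == pytest.approx(acc / shared)
                    else:
                        assert np.isnan(total.values[i, j])

    def test_mean_distance_uses_cotyped_loci_only(self):
        calls = {("a", "L1"): (1, 1), ("b", "L1"): (2, 2),
                 ("a", "L2"): (1, 1)}  # L2 typed only in a
        m = _matrix(calls, "ab", ["L1", "L2"])
        total, mean = pairwise_allele_distance(m)
        assert total.values[0, 1] == 2
        assert mean.values[0, 1] == 2.0  # divided by 1 co-typed locus


# -- ordination -------------------------------------------------------------


class TestPcoa:
    def test_recovers_planted_plane_configuration(self, rng):
        points = rng.normal(size=(12, 2))
        diff = points[:, None, :] - points[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
        res = pcoa(dm, n_axes=2)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(points, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_identical_samples_identical_coordinates(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        coords = res.coordinates.to_numpy()
        assert np.allclose(coords[0], coords[1])

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        points = rng.normal(size=(8, 3))
        diff = points[:, None, :] - points[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        d2 = d ** 2
        centered = -0.5 * (d2 - d2.mean(0) - d2.mean(1)[:, None] + d2.mean())
        assert res.eigenvalues.sum() == pytest.approx(np.trace(centered))

    def test_missing_entries_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(PipelineError, match="missing"):
            pcoa(DistanceMatrix(["a", "b"], d))


class TestMantel:
    @staticmethod
    def _random_dm(rng, n, ids=None):
        x = rng.random((n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        return DistanceMatrix(ids or [f"s{i}" for i in range(n)], d)

    def test_self_comparison_gives_r_one_and_minimal_p(self, rng):
        dm = self._random_dm(rng, 10)
        r, p = mantel(dm, dm, permutations=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 999)

    def test_independent_matrices_give_small_r_large_p(self, rng):
        r, p = mantel(self._random_dm(rng, 15), self._random_dm(rng, 15),
                      permutations=499, seed=2)
        assert abs(r) < 0.5
        assert p > 0.01

    def test_seeded_p_reproducible(self, rng):
        a, b = self._random_dm(rng, 12), self._random_dm(rng, 12)
        assert mantel(a, b, 299, seed=7) == mantel(a, b, 299, seed=7)

    def test_constant_matrix_rejected(self):
        ones = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), ones)
        with pytest.raises(PipelineError, match="constant"):
            mantel(dm, dm, permutations=99, seed=0)

    def test_agrees_with_skbio_r(self, rng):
        """Cross-check the correlation statistic against an independent
        implementation (permutation p-values are stochastic, r is exact)."""
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        a, b = self._random_dm(rng, 10), self._random_dm(rng, 10)
        r_ours, _ = mantel(a, b, permutations=99, seed=3)
        r_skbio, _, _ = sk_mantel(SkDM(a.values, ids=a.ids),
                                  SkDM(b.values, ids=b.ids),
                                  permutations=0, alternative="greater")
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-10)


def test_geographic_distances_haversine():
    entries = [
        SampleEntry("a", ("f",), lon_lat=(0.0, 0.0)),
        SampleEntry("b", ("f",), lon_lat=(180.0, 0.0)),  # antipodal on equator
        SampleEntry("c", ("f",), lon_lat=(0.0, 0.0)),
        SampleEntry("d", ("f",), lon_lat=None),
    ]
    dm, excluded = geographic_distances(entries)
    assert excluded == ["d"]
    assert dm.values[0, 1] == pytest.approx(20015.087, abs=0.5)
    assert dm.values[0, 2] == 0.0
    # symmetry and triangle inequality
    assert np.allclose(dm.values, dm.values.T)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                assert dm.values[i, j] <= dm.values[i, k] + dm.values[k, j] + 1e-9
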