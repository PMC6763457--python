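"""GFP, peak extraction, AAHC clustering, GEV, aggregation, and sorting."""
import itertools

import numpy as np
import pytest

import microdyn as md
from microdyn.containers import demean
from microdyn.topoclust import aahc, correlation_matrix, gev_from_samples


def planted_peak_maps(templates, n_per=50, gfp_scale=None, sign_flips=True, seed=0):
    """Noise-free maps drawn from planted templates with random signs/scales."""
    rng = np.random.default_rng(seed)
    k, n_ch = templates.shape
    labels = np.repeat(np.arange(k), n_per)
    rng.shuffle(labels)
    scales = rng.uniform(0.5, 2.0, size=labels.size) if gfp_scale is None else gfp_scale
    signs = rng.choice([-1.0, 1.0], size=labels.size) if sign_flips else 1.0
    maps = templates[labels] * (scales * signs)[:, None]
    return maps, labels


class TestGfp:
    def test_equal_channels_zero(self):
        assert md.compute_gfp(np.full(7, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_channel_unit(self):
        assert md.compute_gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_four_channel_population_sd(self):
        assert md.compute_gfp(np.array([1.0, -1.0, 2.0, -2.0])) == pytest.approx(
            np.sqrt(2.5)
        )

    def test_matrix_input_per_sample(self):
        data = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert np.allclose(md.compute_gfp(data), [1.0, 0.0])


class TestPeakExtraction:
    def test_single_interior_maximum(self):
        assert list(md.extract_gfp_peaks(np.array([1.0, 3.0, 1.0]))) == [1]

    def test_monotone_series_has_no_peak(self):
        assert md.extract_gfp_peaks(np.arange(10.0)).size == 0

    def test_plateau_yields_first_sample(self):
        assert list(md.extract_gfp_peaks(np.array([0.0, 2.0, 2.0, 2.0, 0.0]))) == [1]

    def test_min_separation_keeps_larger(self):
        g = np.array([0, 5.0, 0, 4.0, 0, 6.0, 0])
        peaks = md.extract_gfp_peaks(g, min_separation_ms=6.0, fs=500.0)
        assert list(peaks) == [1, 5]


class TestSpatialCorrelation:
    def test_self_is_one(self):
        a = np.array([1.0, -2.0, 0.5, 0.5])
        assert md.spatial_correlation(a, a) == pytest.approx(1.0)

    def test_polarity_invariance(self):
        a = np.array([1.0, -2.0, 0.5, 0.5])
        assert md.spatial_correlation(a, -a) == pytest.approx(1.0)
        assert md.spatial_correlation(a, -a, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_patterns(self):
        assert md.spatial_correlation(
            np.array([1.0, -1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0, -1.0])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            md.spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestAahc:
    def test_recovers_planted_templates_noise_free(self, canonical19):
        maps, _ = planted_peak_maps(canonical19.maps, n_per=60)
        ts = md.aahc_cluster(maps, 4)
        c = np.abs(correlation_matrix(ts.maps, canonical19.maps))
        # each planted template matched by exactly one recovered map
        assert np.allclose(np.sort(c.max(axis=0)), 1.0, atol=1e-3)
        assert c.max(axis=0).min() >= 0.999
        assert ts.gev_percent == pytest.approx(100.0, abs=1e-6)

    def test_k_equals_n_gives_full_gev(self, canonical19):
        rng = np.random.default_rng(1)
        maps = demean(rng.standard_normal((8, 19)))
        ts = md.aahc_cluster(maps, 8)
        assert ts.gev_percent == pytest.approx(100.0, abs=1e-6)

    def test_gev_monotone_along_agglomeration_path(self, canonical19):
        maps, _ = planted_peak_maps(canonical19.maps, n_per=30, seed=3)
        rng = np.random.default_rng(4)
        maps = maps + 0.3 * rng.standard_normal(maps.shape)
        _, _, path = aahc(maps, 2)
        ks = sorted(path)
        gevs = [path[k] for k in ks]
        assert all(a <= b + 1e-9 for a, b in zip(gevs, gevs[1:]))

    def test_invalid_k_rejected(self, canonical19):
        maps, _ = planted_peak_maps(canonical19.maps, n_per=3)
        with pytest.raises(ValueError, match="k must be"):
            aahc(maps, 0)
        with pytest.raises(ValueError, match="k must be"):
            aahc(maps, maps.shape[0] + 1)

    def test_deterministic_for_fixed_ordering(self, canonical19):
        maps, _ = planted_peak_maps(canonical19.maps, n_per=20, seed=5)
        t1, a1, _ = aahc(maps, 4)
        t2, a2, _ = aahc(maps, 4)
        assert np.array_equal(t1, t2) and np.array_equal(a1, a2)


class TestGev:
    def test_ground_truth_labels_give_100_percent(self, canonical19):
        maps, labels = planted_peak_maps(canonical19.maps, n_per=40, seed=6)
        assert gev_from_samples(maps, canonical19.maps, labels) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_permuted_labels_strictly_lower(self, canonical19):
        maps, labels = planted_peak_maps(canonical19.maps, n_per=40, seed=7)
        rng = np.random.default_rng(8)
        perm = rng.permutation(labels)
        assert gev_from_samples(maps, canonical19.maps, perm) < 100.0 - 1e-3

    def test_best_assignment_maximal(self, canonical19):
        rng = np.random.default_rng(9)
        maps = demean(rng.standard_normal((60, 19)))
        T = canonical19.maps
        best = np.argmax(np.abs(correlation_matrix(maps, T)), axis=1)
        g_best = gev_from_samples(maps, T, best)
        for _ in range(5):
            other = rng.integers(0, 4, size=60)
            assert g_best >= gev_from_samples(maps, T, other) - 1e-9

    def test_sign_flip_invariance(self, canonical19):
        maps, labels = planted_peak_maps(canonical19.maps, n_per=20, seed=10)
        rng = np.random.default_rng(11)
        flipped = maps * rng.choice([-1.0, 1.0], size=len(maps))[:, None]
        a = gev_from_samples(maps, canonical19.maps, labels)
        b = gev_from_samples(flipped, -canonical19.maps, labels)
        assert a == pytest.approx(b, abs=1e-9)

    def test_empty_assignment_rejected(self, canonical19):
        with pytest.raises(ValueError, match="empty assignment"):
            gev_from_samples(np.zeros((3, 19)), canonical19.maps,
                             np.full(3, -1))


class TestAggregation:
    def test_identical_subjects_reproduce_templates(self, canonical19):
        sets = [canonical19] * 6
        out = md.aggregate_templates(sets, 4)
        c = np.abs(correlation_matrix(out.maps, canonical19.maps))
        assert np.allclose(c.max(axis=0), 1.0, atol=1e-9)

    def test_invariant_under_subject_shuffling(self, canonical19):
        rng = np.random.default_rng(12)
        sets = []
        for s in range(8):
            noisy = canonical19.maps + 0.15 * rng.standard_normal((4, 19))
            noisy = demean(noisy)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            sets.append(md.TemplateSet(maps=noisy, labels=md.CLASSES, level="subject"))
        a = md.aggregate_templates(sets, 4)
        b = md.aggregate_templates(sets[::-1], 4)
        c = np.abs(correlation_matrix(a.maps, b.maps))
        assert (c.max(axis=1) >= 0.99).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no template sets"):
            md.aggregate_templates([], 4)


class TestSorting:
    def test_identity_when_already_ordered(self, canonical19):
        out = md.sort_templates(canonical19, canonical19)
        assert np.allclose(out.maps, canonical19.maps)
        assert out.labels == canonical19.labels

    def test_swapped_maps_swapped_back(self, canonical19):
        swapped = md.TemplateSet(
            maps=canonical19.maps[[1, 0, 2, 3]], labels=md.CLASSES, level="subject"
        )
        out = md.sort_templates(swapped, canonical19)
        assert np.allclose(out.maps, canonical19.maps)

    def test_sign_flips_aligned(self, canonical19):
        flipped = md.TemplateSet(
            maps=canonical19.maps * np.array([[-1.0], [1.0], [-1.0], [1.0]]),
            labels=md.CLASSES, level="subject",
        )
        out = md.sort_templates(flipped, canonical19)
        assert np.allclose(out.maps, canonical19.maps)

    def test_agrees_with_exhaustive_search_on_random_problems(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            ref = demean(rng.standard_normal((4, 12)))
            ref /= np.linalg.norm(ref, axis=1, keepdims=True)
            cand = demean(rng.standard_normal((4, 12)))
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            ts = md.TemplateSet(maps=cand, labels=md.CLASSES, level="subject")
            rts = md.TemplateSet(maps=ref, labels=md.CLASSES, level="grand")
            out = md.sort_templates(ts, rts)
            got = sum(
                abs(md.spatial_correlation(out.maps[j], ref[j])) for j in range(4)
            )
            # brute-force oracle over all 24 permutations
            c = np.abs(correlation_matrix(cand, ref))
            best = max(
                sum(c[p[j], j] for j in range(4))
                for p in itertools.permutations(range(4))
            )
            assert got == pytest.approx(best, abs=1e-10)
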