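"""MCR-ALS tests: SIMPLISMA initialisation, ALS recovery with ground
truth, contrast step algebra, signal fractions and component matching."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

import erythrospec as es
from erythrospec.mcr import (MCRConfig, contrast_step,
                             high_intensity_fraction, init_purest_variables,
                             match_components, mcr_als, signal_fractions)


def _cosine(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestInitPurestVariables:
    def test_pure_pixel_two_component_cube(self):
        rng = np.random.default_rng(0)
        s1 = np.r_[np.ones(10), np.zeros(10)] + 0.01
        s2 = np.r_[np.zeros(10), np.ones(10)] + 0.01
        C = np.vstack([np.eye(2)[rng.integers(0, 2, 200)]
                       * rng.uniform(0.5, 2, (200, 1))])
        D = C @ np.vstack([s1, s2])
        S0, _ = init_purest_variables(D, 2)
        best = [max(_cosine(S0[i], s) for s in (s1, s2)) for i in range(2)]
        assert min(best) >= 0.99

    def test_k1_matches_bruteforce_purity_criterion(self):
        rng = np.random.default_rng(1)
        D = rng.random((50, 30)) + 0.2
        noise_percent = 5.0
        _, selected = init_purest_variables(D, 1, noise_percent)
        mu, sigma = D.mean(axis=0), D.std(axis=0)
        offset = noise_percent / 100 * mu.max()
        assert selected[0] == int(np.argmax(sigma / (mu + offset)))

    def test_duplicate_channel_never_reselected(self):
        rng = np.random.default_rng(2)
        D = rng.random((40, 10))
        D[:, 7] = D[:, 3]                 # exact duplicate
        _, selected = init_purest_variables(D, 2)
        assert not (set(selected) == {3, 7})

    def test_k_exceeds_channels_rejected(self):
        with pytest.raises(ValueError):
            init_purest_variables(np.ones((5, 3)), 4)


class TestMCRALS:
    def test_noiseless_three_component_recovery(self, pure_cube3):
        cube, truth, _ = pure_cube3
        res = mcr_als(cube, MCRConfig(n_components=3, max_iter=100,
                                      tol_lof=1e-8))
        assert res.lof_percent < 1.0
        perm, cos = match_components(res.S, truth.S)
        assert cos.min() >= 0.98
        C_true = truth.C.reshape(-1, 3)
        for i, j in enumerate(perm):
            assert pearsonr(res.C[:, i], C_true[:, j])[0] >= 0.95

    def test_rank_one_cube_exact(self):
        rng = np.random.default_rng(3)
        c = rng.random(100)
        s = rng.random(40)
        D = np.outer(c, s)
        res = mcr_als(D, MCRConfig(n_components=1, max_iter=50))
        assert _cosine(res.S[0], s) >= 0.999

    def test_huge_tolerance_stops_after_one_iteration(self, pure_cube3):
        cube, _, _ = pure_cube3
        res = mcr_als(cube, MCRConfig(n_components=3, tol_lof=1e6))
        assert res.iterations_run == 1

    def test_residual_monotone_nonincreasing(self, pure_cube3):
        cube, _, _ = pure_cube3
        res = mcr_als(cube, MCRConfig(n_components=3, max_iter=40,
                                      tol_lof=1e-12))
        assert np.all(np.diff(res.lof_history) <= 1e-9)

    def test_nonnegativity_and_unit_spectra(self, pure_cube3):
        cube, _, _ = pure_cube3
        res = mcr_als(cube, MCRConfig(n_components=3, max_iter=30))
        assert res.C.min() >= 0
        assert res.S.min() >= 0
        np.testing.assert_allclose(np.linalg.norm(res.S, axis=1), 1.0,
                                   atol=1e-9)

    def test_more_components_than_pixels_rejected(self):
        with pytest.raises(ValueError):
            mcr_als(np.random.default_rng(0).random((4, 10)),
                    MCRConfig(n_components=5))

    def test_nonfinite_cube_rejected(self):
        D = np.ones((10, 5))
        D[0, 0] = np.nan
        with pytest.raises(ValueError):
            mcr_als(D, MCRConfig(n_components=2))


class TestContrastStep:
    def test_weight_zero_identity(self):
        rng = np.random.default_rng(4)
        C = rng.random((30, 4))
        np.testing.assert_array_equal(contrast_step(C, 0.0), C)

    def test_full_contrast_limit(self):
        C = np.array([[0.6, 0.4]])
        np.testing.assert_allclose(contrast_step(C, 1.0), [[1.0, 0.0]])

    def test_pixel_sums_preserved(self):
        rng = np.random.default_rng(5)
        C = rng.random((200, 5))
        for w in (0.1, 0.5, 0.9):
            np.testing.assert_allclose(contrast_step(C, w).sum(axis=1),
                                       C.sum(axis=1), atol=1e-12)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            contrast_step(np.ones((2, 2)), 1.5)


class TestSignalFractions:
    def test_single_component_exact_factorization(self):
        rng = np.random.default_rng(6)
        c = rng.random(50)
        s = rng.random(20)
        s /= np.linalg.norm(s)
        D = np.outer(c, s)
        res = mcr_als(D, MCRConfig(n_components=1, max_iter=30))
        fractions, residual = signal_fractions(res, D)
        assert fractions[0] == pytest.approx(100.0, abs=1e-6)

    def test_disjoint_support_fractions_sum(self):
        # components with disjoint spatial support: cross terms vanish
        s1 = np.r_[np.ones(10), np.zeros(10)]
        s2 = np.r_[np.zeros(10), np.ones(10)]
        c1 = np.r_[np.ones(30), np.zeros(30)]
        c2 = np.r_[np.zeros(30), np.ones(30)]
        D = np.outer(c1, s1) + np.outer(c2, s2)
        res = mcr_als(D, MCRConfig(n_components=2, max_iter=50))
        fractions, residual = signal_fractions(res, D)
        assert fractions.sum() == pytest.approx(100.0 - residual, abs=1e-9)

    def test_zero_cube_rejected(self, pure_cube3):
        cube, _, _ = pure_cube3
        res = mcr_als(cube, MCRConfig(n_components=3, max_iter=5))
        with pytest.raises(ValueError):
            signal_fractions(res, np.zeros((10, len(cube.axis))))


class TestHighIntensityFraction:
    def test_uniformly_above_absolute_threshold(self):
        cmap = np.full((20, 20), 5.0)
        mask = np.ones((20, 20), bool)
        assert high_intensity_fraction(cmap, mask, "absolute",
                                       value=1.0) == 100.0

    def test_pooled_percentile_definition(self):
        rng = np.random.default_rng(7)
        pooled = rng.random(10000)
        cmap = pooled.reshape(100, 100)
        mask = np.ones((100, 100), bool)
        got = high_intensity_fraction(cmap, mask, "percentile", value=60,
                                      pooled=pooled)
        assert got == pytest.approx(40.0, abs=0.1)

    def test_otsu_all_equal_rejected(self):
        with pytest.raises(ValueError):
            high_intensity_fraction(np.ones((5, 5)), np.ones((5, 5), bool),
                                    "otsu")

    def test_hemoglobin_fraction_tracks_class_contrast(self, profiles,
                                                       fingerprint_axis):
        # raising hemoglobin abundance raises the high-intensity pixel
        # percentage: strict sign consistency over several seeds
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            ph = es.make_phantom(2, (80, 80), seed=seed)
            fracs = {}
            for label in ("precursor", "erythrocyte_like"):
                cube, truth = es.simulate_hs_image(
                    ph, profiles[label], axis=fingerprint_axis,
                    noise=es.NoiseParams(read_sigma=0.02), seed=100 + seed)
                hb = truth.endmember_names.index("hemoglobin")
                cell = ph[0].mask_cell | ph[1].mask_cell
                fracs[label] = (truth.C[:, :, hb], cell)
            pooled = np.concatenate([
                fracs["precursor"][0][fracs["precursor"][1]],
                fracs["erythrocyte_like"][0][fracs["erythrocyte_like"][1]]])
            vals = {
                label: high_intensity_fraction(cmap, cell, "percentile",
                                               value=60, pooled=pooled)
                for label, (cmap, cell) in fracs.items()
            }
            if vals["erythrocyte_like"] > vals["precursor"]:
                wins += 1
        assert wins == n_seeds


class TestMatchComponents:
    def test_row_permutation_recovered(self):
        rng = np.random.default_rng(8)
        S = rng.random((4, 25))
        perm_true = np.array([2, 0, 3, 1])
        perm, cos = match_components(S[perm_true], S)
        np.testing.assert_array_equal(perm, perm_true)
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        S = rng.random((3, 15))
        S_scaled = S.copy()
        S_scaled[1] *= 5.0
        _, cos = match_components(S_scaled, S)
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_matches_bruteforce_over_permutations(self):
        rng = np.random.default_rng(10)
        k = 4
        S_true = np.linalg.qr(rng.standard_normal((20, k)))[0].T
        S_true = np.abs(S_true) + 0.05
        S_est = S_true + 0.1 * rng.standard_normal(S_true.shape)
        perm, cos = match_components(S_est, S_true)

        def total(p):
            return sum(
                (S_est[i] @ S_true[p[i]])
                / (np.linalg.norm(S_est[i]) * np.linalg.norm(S_true[p[i]]))
                for i in range(k))

        best = max(itertools.permutations(range(k)), key=total)
        assert total(perm) == pytest.approx(total(best), abs=1e-12)

    def test_unequal_counts_reports_unmatched(self):
        rng = np.random.default_rng(11)
        S_true = rng.random((2, 10))
        S_est = rng.random((4, 10))
        perm, cos = match_components(S_est, S_true)
        assert (perm == -1).sum() == 2
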