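"""Bivariate screen, correlation filter, FDR, stepwise AIC, stability."""

import numpy as np
import pytest

from ensemblesdm.glmfit import expit, fit_logistic
from ensemblesdm.occurrences import PixelDataset
from ensemblesdm.selection import (BivariateScreen, correlation_filter,
                                   derive_repeat_seed, fdr_screen,
                                   screen_bivariate, select_variables,
                                   stability_selection, stepwise_aic)


def _dataset(X, y, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    ids = [(0, i) for i in range(len(y))]
    return PixelDataset(ids, np.asarray(X, float), np.asarray(y, int), names)


class TestScreenBivariate:
    def test_strong_signal_is_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        y = (rng.random(500) < expit(3 * x)).astype(int)
        s = screen_bivariate(x[:, None], y, ["x"])[0]
        assert s.p_value < 1e-3
        assert s.deviance_explained > 0.2

    def test_constant_variable(self):
        y = np.array([0, 1, 0, 1, 1])
        s = screen_bivariate(np.ones((5, 1)), y, ["c"])[0]
        assert s.p_value == 1.0
        assert s.deviance_explained == 0.0

    def test_type_one_error_calibration_under_permutation(self):
        rng = np.random.default_rng(1)
        n, reps = 200, 1000
        x = rng.standard_normal(n)
        y = np.zeros(n, dtype=int)
        y[:60] = 1
        hits = 0
        for _ in range(reps):
            yp = rng.permutation(y)
            hits += screen_bivariate(x[:, None], yp, ["x"])[0].p_value < 0.05
        # binomial(1000, 0.05): ~3.5 sd band
        assert 0.05 * reps - 25 <= hits <= 0.05 * reps + 25


class TestCorrelationFilter:
    def _screens(self, ps, d2s=None):
        d2s = d2s or [0.0] * len(ps)
        return [BivariateScreen(f"x{j}", p, d)
                for j, (p, d) in enumerate(zip(ps, d2s))]

    def test_duplicate_variable_keeps_informative_copy(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x])
        kept = correlation_filter(X, self._screens([0.001, 0.5]),
                                  ["x0", "x1"])
        assert kept == ["x0"]

    def test_uncorrelated_variables_all_kept(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        kept = correlation_filter(X, self._screens([0.1] * 4),
                                  [f"x{j}" for j in range(4)])
        assert kept == ["x0", "x1", "x2", "x3"]

    def test_chain_drops_middle_member(self):
        # x0~x1 and x1~x2 over the threshold, x0 and x2 independent;
        # x1 least informative -> dropping x1 resolves both pairs.
        # (with independent endpoints the chain correlations are capped
        # at 1/sqrt(2), so the threshold is set below that)
        rng = np.random.default_rng(4)
        n = 4000
        x0 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x1 = (x0 + x2) / np.sqrt(2) + 0.1 * rng.standard_normal(n)
        X = np.column_stack([x0, x1, x2])
        corr = np.corrcoef(X, rowvar=False)
        assert corr[0, 1] > 0.6 and corr[1, 2] > 0.6  # construction sanity
        assert abs(corr[0, 2]) < 0.6
        kept = correlation_filter(X, self._screens([0.01, 0.6, 0.02]),
                                  ["x0", "x1", "x2"], threshold=0.6)
        assert kept == ["x0", "x2"]


class TestFdrScreen:
    def test_benjamini_hochberg_by_hand(self):
        screens = [BivariateScreen("a", 0.001, 0.3),
                   BivariateScreen("b", 0.002, 0.2),
                   BivariateScreen("c", 0.9, 0.0)]
        assert fdr_screen(screens, q=0.05) == ["a", "b"]

    def test_all_null_none_kept(self):
        screens = [BivariateScreen(f"x{j}", 1.0, 0.0) for j in range(5)]
        assert fdr_screen(screens, q=0.05) == []

    def test_single_variable_below_q_kept(self):
        assert fdr_screen([BivariateScreen("a", 0.04, 0.1)], q=0.05) == ["a"]

    def test_matches_brute_force_bh_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 15)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            screens = [BivariateScreen(f"x{j}", float(pj), 0.0)
                       for j, pj in enumerate(p)]
            got = set(fdr_screen(screens, q=0.05))
            # independent BH: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            ps = p[order]
            ks = np.flatnonzero(ps <= (np.arange(1, m + 1) * 0.05 / m))
            expected = set() if len(ks) == 0 else \
                {f"x{j}" for j in order[:ks[-1] + 1]}
            assert got == expected


class TestStepwiseAIC:
    def test_recovers_single_driver_among_noise(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            X = rng.standard_normal((1000, 6))
            y = (rng.random(1000) < expit(-1 + 2.0 * X[:, 0])).astype(int)
            subset, _, _ = stepwise_aic(X, y, [f"x{j}" for j in range(6)],
                                        [f"x{j}" for j in range(6)])
            hits += "x0" in subset
        assert hits >= 95

    def test_zero_candidates_gives_intercept_only(self):
        y = np.array([0, 1, 0, 1])
        subset, model, aic = stepwise_aic(np.zeros((4, 0)), y, [], [])
        assert subset == []
        assert model.n_params == 1

    def test_aic_matches_definition(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) < expit(X[:, 0])).astype(int)
        subset, model, aic = stepwise_aic(X, y, ["a", "b", "c"],
                                          ["a", "b", "c"])
        assert aic == pytest.approx(-2 * model.loglik + 2 * model.n_params,
                                    rel=1e-12)

    def test_never_worse_than_intercept_only(self):
        rng = np.random.default_rng(10)
        for seed in range(10):
            X = rng.standard_normal((150, 4))
            y = rng.integers(0, 2, 150)
            _, model, aic = stepwise_aic(X, y, [f"x{j}" for j in range(4)],
                                         [f"x{j}" for j in range(4)])
            null_aic = fit_logistic(np.empty((150, 0)), y.astype(float)).aic
            assert aic <= null_aic + 1e-9


class TestSelectVariables:
    def test_recovers_true_drivers_with_collinear_decoy(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(20):
            n = 800
            x0 = rng.standard_normal(n)
            decoy = 0.9 * x0 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            noise = rng.standard_normal((n, 3))
            X = np.column_stack([x0, decoy, x2, noise])
            y = (rng.random(n) < expit(-2 + 1.8 * x0 - 1.5 * x2)).astype(int)
            res = select_variables(_dataset(X, y))
            wins += sorted(res.final_subset) == ["x0", "x2"]
        assert wins >= 12

    def test_nesting_invariant(self, strong_pixels):
        from ensemblesdm.occurrences import sample_absences
        ds = sample_absences(strong_pixels, ratio=10, seed=1)
        res = select_variables(ds)
        assert set(res.final_subset) <= set(res.kept_after_fdr)
        assert set(res.kept_after_fdr) <= set(res.kept_after_correlation)

    def test_type_one_control_with_pure_noise(self):
        rng = np.random.default_rng(12)
        empty = 0
        for _ in range(50):
            X = rng.standard_normal((800, 8))
            y = np.zeros(800, dtype=int)
            y[rng.choice(800, 80, replace=False)] = 1
            res = select_variables(_dataset(X, y))
            empty += len(res.final_subset) == 0
        assert empty >= 45  # >= 90% of replicates


class TestStabilitySelection:
    def test_single_repeat(self, strong_pixels):
        tally = stability_selection(strong_pixels, n_repeats=1, ratio=10,
                                    master_seed=5)
        assert tally.n_repeats == 1
        assert sum(tally.subset_frequencies.values()) == 1
        assert tally.representative_seed == derive_repeat_seed(5, 0)

    def test_counts_sum_and_reproducibility(self, strong_pixels):
        a = stability_selection(strong_pixels, n_repeats=20, ratio=10,
                                master_seed=3)
        b = stability_selection(strong_pixels, n_repeats=20, ratio=10,
                                master_seed=3)
        assert sum(a.subset_frequencies.values()) == 20
        assert a.subset_frequencies == b.subset_frequencies
        assert a.modal_subset == b.modal_subset

    def test_modal_subset_reproducible_from_representative_seed(
            self, strong_pixels):
        from ensemblesdm.occurrences import sample_absences
        tally = stability_selection(strong_pixels, n_repeats=10, ratio=10,
                                    master_seed=7)
        sample = sample_absences(strong_pixels, ratio=10,
                                 seed=tally.representative_seed)
        res = select_variables(sample)
        assert tuple(sorted(res.final_subset)) == tally.modal_subset

    def test_strong_signal_modal_share(self, strong_pixels):
        # dominant subset echoes the concentrated tally seen in practice
        tally = stability_selection(strong_pixels, n_repeats=200, ratio=10,
                                    master_seed=1)
        share = tally.subset_frequencies[tally.modal_subset] / 200
        assert share > 0.4
        assert "env00" in tally.modal_subset or "env01" in tally.modal_subset
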