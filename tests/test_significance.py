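import warnings

import numpy as np
import pytest

from sastra import (
    barcode_frame, estimate_lambda_thresholds, estimate_num_processes,
    fit_significance, generate_cohort, significant_proteins, surprisal_decompose,
)

from conftest import make_decomposition, make_matrix
from test_decompose import planted_matrix


class TestEstimateNumProcesses:
    def test_noiseless_exact_rank(self):
        matrix, _, _ = planted_matrix(n=12, m=8, r=2, seed=0)
        with pytest.warns(UserWarning, match="rank deficient"):
            d = surprisal_decompose(matrix)
        assert estimate_num_processes(d, method="noise_floor") == 2

    def test_planted_three_processes_recovered(self):
        for seed in range(1, 6):
            m, _ = generate_cohort(seed=seed)
            d = surprisal_decompose(m)
            assert estimate_num_processes(d, method="noise_floor") == 3
            if seed <= 2:
                assert estimate_num_processes(
                    d, method="permutation", n_resamples=60, seed=seed) == 3

    def test_pure_noise_permutation_returns_zero(self):
        zeros = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(5000 + seed)
            vals = rng.normal(5, 1, size=100)[None, :] + rng.normal(0, 0.3, size=(60, 100))
            d = surprisal_decompose(make_matrix(vals))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zeros += estimate_num_processes(
                    d, method="permutation", n_resamples=60, seed=seed) == 0
        assert zeros >= 0.9 * n_seeds

    def test_permutation_needs_enough_resamples(self):
        matrix, _, _ = planted_matrix(n=8, m=6, r=1, seed=1, noise_sd=0.2)
        d = surprisal_decompose(matrix)
        with pytest.raises(ValueError, match="n_resamples"):
            estimate_num_processes(d, method="permutation", n_resamples=5)


class TestLambdaThresholds:
    def test_trailing_noise_formula(self):
        # 2 retained processes; trailing amplitudes with pooled SD exactly 0.5
        lam = np.zeros((4, 4))
        lam[:, 2] = [0.5, -0.5, 0.5, -0.5]
        lam[:, 3] = [0.5, 0.5, -0.5, -0.5]
        d = make_decomposition(np.eye(4), lam, singular_values=np.array([3.0, 2.0, 1.0, 1.0]))
        T = estimate_lambda_thresholds(d, 2, method="trailing_noise", multiplier=2.0)
        np.testing.assert_allclose(T, [1.0, 1.0])

    def test_noise_edge_uses_strongest_trailing_process(self):
        lam = np.zeros((4, 4))
        lam[:, 2] = [1.0, -1.0, 1.0, -1.0]   # edge component, SD 1
        lam[:, 3] = [0.1, 0.1, -0.1, -0.1]   # bulk, SD 0.1
        d = make_decomposition(np.eye(4), lam, singular_values=np.array([3.0, 2.5, 2.0, 0.2]))
        T = estimate_lambda_thresholds(d, 2, method="noise_edge", multiplier=2.0)
        np.testing.assert_allclose(T, [2.0, 2.0])

    def test_zero_multiplier_activates_everything(self):
        m, _ = generate_cohort(n_samples=40, n_analytes=30, seed=2)
        d = surprisal_decompose(m)
        sig = fit_significance(d, multiplier=0.0, n_processes=3)
        codes = barcode_frame(d, sig)
        assert (codes != 0).all().all()

    def test_resample_method_positive_thresholds(self):
        m, _ = generate_cohort(n_samples=40, n_analytes=30, seed=3)
        d = surprisal_decompose(m)
        T = estimate_lambda_thresholds(d, 3, method="resample", n_resamples=50, seed=0)
        assert T.shape == (3,) and (T > 0).all()

    def test_amplitudes_above_noise_called_at_theoretical_rate(self):
        """Samples with |lambda| = 3 x noise SD against a 2-sigma bulk threshold.

        The per-sample amplitude estimate carries error ~ the noise SD s, so
        the active-call rate is Phi(1) ~ 0.84 by the normal-tail oracle
        (NOT ~1: a 3-sigma planted amplitude is only 1 sigma above a
        2-sigma threshold).
        """
        rng = np.random.default_rng(7)
        n, m, s = 300, 150, 0.25
        g = np.zeros(m); g[:20] = rng.normal(size=20); g /= np.linalg.norm(g)
        active = rng.random(n) < 0.3
        lam = np.where(active, 3 * s, 0.0) * rng.choice([-1, 1], size=n)
        vals = rng.uniform(4, 6, size=m)[None, :] + np.outer(lam, g) + rng.normal(0, s, (n, m))
        d = surprisal_decompose(make_matrix(vals))
        T = estimate_lambda_thresholds(d, 1, method="trailing_noise", multiplier=2.0)
        assert T[0] == pytest.approx(2 * s, rel=0.15)
        called = np.abs(d.lambdas[active, 0]) > T[0]
        oracle_rate = 0.84
        assert called.mean() == pytest.approx(oracle_rate, abs=0.10)

    def test_monotone_in_multiplier(self):
        m, _ = generate_cohort(n_samples=60, n_analytes=50, seed=4)
        d = surprisal_decompose(m)
        n_active = []
        for mult in (0.5, 1.0, 2.0, 4.0):
            sig = fit_significance(d, multiplier=mult, n_processes=3)
            n_active.append(int((barcode_frame(d, sig) != 0).sum().sum()))
        assert all(a >= b for a, b in zip(n_active, n_active[1:]))


class TestSignificantProteins:
    def test_quantile_counts_and_dominant_included(self):
        rng = np.random.default_rng(5)
        G = rng.normal(scale=0.01, size=(200, 2))
        G[17, 0] = 0.9
        d = make_decomposition(G, np.zeros((4, 2)))
        sets, thr = significant_proteins(d, 1, g_method="quantile", g_param=0.05)
        assert len(sets[0]) == 10
        assert sets[0][0] == d.analyte_ids[17]
        assert thr[0] > 0

    def test_all_equal_loadings_tie_break_by_analyte_order(self):
        G = np.full((6, 2), 0.5)
        d = make_decomposition(G, np.zeros((3, 2)))
        sets, _ = significant_proteins(d, 1, g_method="quantile", g_param=0.5)
        assert sets[0] == ["a1", "a2", "a3"]

    def test_noise_sd_recovers_planted_support(self):
        m, truth = generate_cohort(seed=6)
        d = surprisal_decompose(m)
        sets, _ = significant_proteins(d, 3, g_method="noise_sd", g_param=1.5)
        # match est processes to planted ones by |G| correlation
        jaccards = []
        for t in range(3):
            corr = [abs(np.corrcoef(truth.true_G[:, t], d.G[:, e])[0, 1]) for e in range(3)]
            e = int(np.argmax(corr))
            est = set(sets[e])
            true_sup = {d.analyte_ids[i] for i in truth.true_supports[t]}
            jaccards.append(len(est & true_sup) / len(est | true_sup))
        assert np.mean(jaccards) >= 0.8

    def test_invalid_quantile_rejected(self):
        d = make_decomposition(np.eye(3), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            significant_proteins(d, 1, g_method="quantile", g_param=1.5)


class TestThresholdInvariances:
    def test_threshold_invariant_to_sample_order(self):
        m, _ = generate_cohort(n_samples=50, n_analytes=40, seed=8)
        d1 = surprisal_decompose(m)
        perm = np.random.default_rng(0).permutation(m.n_samples)
        m2 = m.subset_samples([m.sample_ids[i] for i in perm])
        d2 = surprisal_decompose(m2)
        T1 = estimate_lambda_thresholds(d1, 3)
        T2 = estimate_lambda_thresholds(d2, 3)
        np.testing.assert_allclose(T1, T2, rtol=1e-8)
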