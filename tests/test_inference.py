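"""Variational EM: E-step updates, ELBO, M-step regressions, full fits."""

import copy
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import digamma, gammaln, logsumexp

from mutopo.binning import FeatureMatrix
from mutopo.ingest import WeightedCountTensor
from mutopo.inference import (FitConfig, VariationalState, e_step, elbo,
                              cell_log_topographies, fit, m_step,
                              random_search, update_alpha)
from mutopo.model import (MacroEffect, ModelState, ProcessTopography,
                          SpectraEffect, TreeParams,
                          topography_log_distribution)


def tiny_tensor(weights, bins, types, samples, sample_ids, n_bins):
    return WeightedCountTensor(sample_ids, n_bins,
                               np.array(samples), np.array(bins),
                               np.array(types), np.array(weights, float))


def uniform_model(K, n_bins, seed=0):
    rng = np.random.default_rng(seed)
    procs = []
    for k in range(K):
        base = rng.normal(0, 0.5, 192)
        procs.append(ProcessTopography(MacroEffect("constant", ["x"]),
                                       SpectraEffect(baseline=base)))
    return ModelState(procs, np.ones(K), ["x"])


def flat_X_t(n_bins):
    X = FeatureMatrix(np.linspace(0, 1, n_bins)[:, None], ["x"], ["macro"])
    t = np.ones((n_bins, 192))
    return X, t


class TestEStep:
    def test_single_process_gives_unit_phi(self):
        Y = tiny_tensor([1.5, 0.5], [0, 1], [3, 40], [0, 0], ["s"], 2)
        model = uniform_model(1, 2)
        X, t = flat_X_t(2)
        _, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, model.dirichlet_alpha, cells)
        assert np.allclose(st.phi, 1.0)
        assert np.allclose(st.beta, 1.0 + 2.0)  # alpha + burden

    def test_identical_processes_split_symmetrically(self):
        Y = tiny_tensor([1.0, 2.0], [0, 1], [3, 40], [0, 0], ["s"], 2)
        base = np.linspace(-0.5, 0.5, 192)
        procs = [ProcessTopography(MacroEffect("constant", ["x"]),
                                   SpectraEffect(baseline=base.copy()))
                 for _ in range(2)]
        model = ModelState(procs, np.ones(2), ["x"])
        X, t = flat_X_t(2)
        _, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, model.dirichlet_alpha, cells)
        assert np.allclose(st.phi, 0.5)

    def test_single_iteration_matches_hand_update(self):
        # 2 samples, 2 bins, K=2 with hand-set topographies
        Y = tiny_tensor([2.0, 1.0, 3.0], [0, 1, 1], [3, 3, 40],
                        [0, 0, 1], ["a", "b"], 2)
        model = uniform_model(2, 2, seed=9)
        alpha = model.dirichlet_alpha
        X, t = flat_X_t(2)
        logP, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, alpha, cells, max_iters=1)
        # hand: initial beta = alpha + burden/K
        burdens = np.array([3.0, 3.0])
        beta0 = np.tile(alpha, (2, 1)) + burdens[:, None] / 2
        el = digamma(beta0) - digamma(beta0.sum(1, keepdims=True))
        logits = el[Y.sample_idx] + cells
        phi = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
        beta = np.tile(alpha, (2, 1))
        np.add.at(beta, Y.sample_idx, Y.weight[:, None] * phi)
        assert np.allclose(st.phi, phi, atol=1e-12)
        assert np.allclose(st.beta, beta, atol=1e-12)

    def test_fixed_point_idempotence(self):
        Y = tiny_tensor([2.0, 1.0, 3.0], [0, 1, 1], [3, 3, 40],
                        [0, 0, 1], ["a", "b"], 2)
        model = uniform_model(2, 2, seed=9)
        X, t = flat_X_t(2)
        _, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, model.dirichlet_alpha, cells, max_iters=500,
                    tol=1e-14)
        st2 = e_step(Y, model.dirichlet_alpha, cells, st, max_iters=1)
        assert np.allclose(st2.beta, st.beta, atol=1e-10)
        assert np.allclose(st2.phi, st.phi, atol=1e-10)

    def test_phi_rows_on_simplex(self):
        Y = tiny_tensor([1.0] * 5, [0, 1, 0, 1, 0], [3, 40, 50, 3, 40],
                        [0, 0, 1, 1, 1], ["a", "b"], 2)
        model = uniform_model(3, 2, seed=2)
        X, t = flat_X_t(2)
        _, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, model.dirichlet_alpha, cells)
        assert np.allclose(st.phi.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(st.beta > 0)


class TestElbo:
    def test_lower_bounds_k1_closed_form_marginal(self):
        # with K=1 the marginal likelihood factorizes over cells
        Y = tiny_tensor([1.0, 2.0], [0, 1], [3, 40], [0, 0], ["s"], 2)
        model = uniform_model(1, 2)
        X, t = flat_X_t(2)
        logP, cells = cell_log_topographies(model, Y, X, t)
        st = e_step(Y, model.dirichlet_alpha, cells)
        bound = elbo(Y, model.dirichlet_alpha, cells, st)
        exact = float(np.sum(Y.weight * cells[:, 0]))
        assert bound <= exact + 1e-9

    def test_duplicating_samples_doubles_elbo(self):
        Y = tiny_tensor([1.0, 2.0, 1.5], [0, 1, 0], [3, 40, 50],
                        [0, 0, 0], ["s"], 2)
        Y2 = tiny_tensor([1.0, 2.0, 1.5] * 2, [0, 1, 0] * 2,
                         [3, 40, 50] * 2, [0, 0, 0, 1, 1, 1],
                         ["s", "s2"], 2)
        model = uniform_model(2, 2, seed=3)
        X, t = flat_X_t(2)
        _, c1 = cell_log_topographies(model, Y, X, t)
        _, c2 = cell_log_topographies(model, Y2, X, t)
        s1 = e_step(Y, model.dirichlet_alpha, c1, max_iters=400, tol=1e-13)
        s2 = e_step(Y2, model.dirichlet_alpha, c2, max_iters=400, tol=1e-13)
        assert np.isclose(elbo(Y2, model.dirichlet_alpha, c2, s2),
                          2 * elbo(Y, model.dirichlet_alpha, c1, s1),
                          rtol=1e-9)

    def test_invariant_to_bin_reordering(self):
        Y = tiny_tensor([1.0, 2.0], [0, 1], [3, 40], [0, 0], ["s"], 2)
        Yp = tiny_tensor([1.0, 2.0], [1, 0], [3, 40], [0, 0], ["s"], 2)
        model = uniform_model(2, 2, seed=5)
        X, t = flat_X_t(2)
        perm = np.array([1, 0])
        Xp = FeatureMatrix(X.values[perm], X.feature_names,
                           X.feature_classes)
        _, c = cell_log_topographies(model, Y, X, t)
        _, cp = cell_log_topographies(model, Yp, Xp, t[perm])
        s = e_step(Y, model.dirichlet_alpha, c)
        sp = e_step(Yp, model.dirichlet_alpha, cp)
        assert np.isclose(elbo(Y, model.dirichlet_alpha, c, s),
                          elbo(Yp, model.dirichlet_alpha, cp, sp),
                          rtol=1e-12)


class TestMStep:
    def test_recovers_step_function_rate(self):
        # single process, rate = exp(2) where x > 0.5
        n_bins = 40
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, n_bins)
        rate = np.exp(2.0 * (x > 0.5))
        X = FeatureMatrix(x[:, None], ["x"], ["macro"])
        t = np.ones((n_bins, 192))
        bins, types, weights = [], [], []
        for b in range(n_bins):
            for m in range(0, 192, 16):
                bins.append(b)
                types.append(m)
                weights.append(rate[b] * 10)
        Y = tiny_tensor(weights, bins, types, [0] * len(bins), ["s"], n_bins)
        model = ModelState([ProcessTopography(
            MacroEffect("boosted_trees", ["x"]),
            SpectraEffect(baseline=np.zeros(192)))], np.ones(1), ["x"])
        st = VariationalState(np.array([[1.0 + sum(weights)]]),
                              np.ones((len(bins), 1)))
        cfg = FitConfig(K=1)
        logP = model.log_topographies(X, t)
        m_step(Y, st, model, X, t, cfg, logP=logP)
        f = model.processes[0].macro.log_rate(X)
        gap = f[x > 0.5].mean() - f[x <= 0.5].mean()
        assert abs(gap - 2.0) < 0.2

    def test_zero_responsibility_process_is_frozen(self):
        Y = tiny_tensor([1.0, 2.0], [0, 1], [3, 40], [0, 0], ["s"], 2)
        model = uniform_model(2, 2, seed=7)
        frozen_before = copy.deepcopy(model.processes[1])
        phi = np.zeros((2, 2))
        phi[:, 0] = 1.0
        st = VariationalState(np.array([[4.0, 1.0]]), phi)
        X, t = flat_X_t(2)
        cfg = FitConfig(K=2, guard_m_step=False)
        m_step(Y, st, model, X, t, cfg)
        assert np.array_equal(model.processes[1].spectra.baseline,
                              frozen_before.spectra.baseline)

    def test_alpha_update_satisfies_mle_stationarity(self):
        # at the Dirichlet MLE: digamma(a_k) - digamma(sum a) = mean E[log pi]
        rng = np.random.default_rng(8)
        beta = rng.gamma(2.0, 2.0, size=(500, 3))
        a = update_alpha(np.ones(3), beta, iters=500)
        s = (digamma(beta) - digamma(beta.sum(1, keepdims=True))).mean(axis=0)
        assert np.allclose(digamma(a) - digamma(a.sum()), s, atol=1e-8)


class TestFit:
    def test_elbo_monotone_and_seed_reproducible(self, small_tensor,
                                                 small_binning):
        cfg = FitConfig(K=2, seed=123, max_epochs=8, tol=0.0)
        m1, s1 = fit(small_tensor, small_binning, cfg)
        diffs = np.diff(s1.elbo_trace)
        assert np.all(diffs >= -1e-6)
        m2, s2 = fit(small_tensor, small_binning, cfg)
        assert np.array_equal(s1.elbo_trace, s2.elbo_trace)
        assert np.array_equal(s1.beta, s2.beta)

    def test_full_batch_equals_explicit_coordinate_ascent(self, small_tensor,
                                                          small_binning):
        from mutopo.inference import _initial_model

        cfg = FitConfig(K=2, seed=3, max_epochs=3, tol=0.0,
                        batch_fraction=1.0)
        model_fit, state_fit = fit(small_tensor, small_binning, cfg)
        # explicit loop with the same seed-derived initialization
        rng = np.random.default_rng(cfg.seed)
        model = _initial_model(small_tensor, small_binning, cfg, rng)
        X = small_binning.feature_matrix
        t = small_binning.availability.counts
        state = None
        for _ in range(3):
            logP, cells = cell_log_topographies(model, small_tensor, X, t)
            state = e_step(small_tensor, model.dirichlet_alpha, cells, state,
                           cfg.e_step_iters, cfg.e_step_tol)
            model = m_step(small_tensor, state, model, X, t, cfg, None, logP)
        assert np.allclose(state.beta, state_fit.beta, atol=1e-10)

    def test_stochastic_batches_still_learn(self, small_tensor,
                                            small_binning):
        cfg = FitConfig(K=2, seed=11, max_epochs=12, tol=0.0,
                        batch_fraction=0.5, guard_m_step=False)
        model, state = fit(small_tensor, small_binning, cfg)
        assert state.elbo_trace[-1] > state.elbo_trace[0]

    def test_exposures_on_simplex_every_config(self, fitted_small):
        _, state, _ = fitted_small
        pi = state.beta / state.beta.sum(1, keepdims=True)
        assert np.allclose(pi.sum(axis=1), 1.0)
        assert np.allclose(state.phi.sum(axis=1), 1.0, atol=1e-9)

    def test_spectra_seeding_starts_at_given_spectra(self, small_tensor,
                                                     small_binning,
                                                     ref_model):
        from mutopo.model import marginal_spectrum

        X = small_binning.feature_matrix
        t = small_binning.availability.counts
        seeds = np.stack([marginal_spectrum(p, X, t)
                          for p in ref_model.processes])
        cfg = FitConfig(K=3, seed=1, max_epochs=1, tol=0.0,
                        init_spectra=seeds)
        model, _ = fit(small_tensor, small_binning, cfg)
        assert model.K == 3

    def test_heavy_l1_zeroes_all_adjustments(self, small_tensor,
                                             small_binning):
        cfg = FitConfig(K=2, seed=2, max_epochs=4, tol=0.0,
                        spectra_adjustments=True, l1_meso=1e9,
                        l1_strand_uniform=1e9, l1_strand_dev=1e9)
        model, _ = fit(small_tensor, small_binning, cfg)
        for p in model.processes:
            assert np.all(p.spectra.meso_coef == 0.0)
            assert np.all(p.spectra.strand_uniform == 0.0)
            assert np.all(p.spectra.strand_dev == 0.0)


class TestRandomSearch:
    def test_single_point_space_returns_it(self, small_tensor,
                                           small_binning):
        base = FitConfig(K=2, max_epochs=3, tol=0.0)
        table, best = random_search(small_tensor, small_binning,
                                    {"K": [2]}, n_trials=1, seed=0,
                                    heldout_chrom="chr3", base_config=base)
        assert best.K == 2 and len(table) == 1

    def test_reproducible_scores(self, small_tensor, small_binning):
        base = FitConfig(max_epochs=3, tol=0.0)
        t1, _ = random_search(small_tensor, small_binning,
                              {"K": [1, 2]}, n_trials=2, seed=9,
                              heldout_chrom="chr3", base_config=base)
        t2, _ = random_search(small_tensor, small_binning,
                              {"K": [1, 2]}, n_trials=2, seed=9,
                              heldout_chrom="chr3", base_config=base)
        assert np.array_equal(t1["pseudo_r2"].to_numpy(),
                              t2["pseudo_r2"].to_numpy())

    def test_empty_space_errors(self, small_tensor, small_binning):
        with pytest.raises(ValueError):
            random_search(small_tensor, small_binning, {}, 1, 0, "chr3")
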