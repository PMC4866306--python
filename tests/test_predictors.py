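"""Model-zoo tests: closed-form examples, brute-force oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from diallelpred import predictors as pr
from diallelpred import simulate as sim
from diallelpred.relatedness import compute_grm
from diallelpred.simulate import PhenotypeTable


def _random_psd(n, seed, jitter=0.5):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    return A @ A.T / n + jitter * np.eye(n)


class TestPhenotypeRegression:
    def test_exact_line(self):
        reg = pr.fit_phenotype_regression(np.array([[0.0], [1.0], [2.0]]),
                                          np.array([1.0, 2.0, 3.0]))
        assert reg.weights[0] == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(1.0)

    def test_duplicated_covariate_recovers_identity(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        P = np.column_stack([y, rng.standard_normal((50, 2))])
        reg = pr.fit_phenotype_regression(P, y)
        pred = reg.predict(P)
        assert np.allclose(pred, y, atol=1e-8)

    def test_independent_covariates_no_out_of_sample_signal(self):
        # permutation oracle: shuffling y removes all predictive signal
        rng = np.random.default_rng(1)
        P = rng.standard_normal((400, 5))
        y = rng.standard_normal(400)
        reg = pr.fit_phenotype_regression(P[:200], y[:200])
        resid = y[200:] - reg.predict(P[200:])
        sst = np.sum((y[200:] - y[200:].mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / sst
        assert abs(r2) < 0.08

    def test_rank_deficient_warns(self):
        P = np.ones((10, 2))
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            pr.fit_phenotype_regression(P, y)


class TestVarianceComponents:
    def test_pure_noise_has_near_zero_h2(self, medium_diallel):
        _, G = medium_diallel
        K = compute_grm(G)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(G.n_individuals)
        vc = pr.fit_variance_components(K.K, y)
        assert vc.h2 < 0.1

    def test_constant_y(self):
        K = _random_psd(10, 4)
        with pytest.warns(UserWarning, match="constant"):
            vc = pr.fit_variance_components(K, np.ones(10))
        assert vc.sigma_g2 == 0.0

    def test_optimum_beats_grid_oracle(self):
        # profile likelihood at the optimizer's delta >= 100-point grid
        rng = np.random.default_rng(5)
        n = 80
        K = _random_psd(n, 6)
        K *= n / np.trace(K)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        y = 1.5 + L @ rng.standard_normal(n) + 0.7 * rng.standard_normal(n)
        vc = pr.fit_variance_components(K, y)
        s, U = linalg.eigh(K)
        s = np.clip(s, 0, None)
        yt, ot = U.T @ y, U.T @ np.ones(n)

        def ll(delta):
            w = 1 / (s + delta)
            mu = np.sum(w * ot * yt) / np.sum(w * ot * ot)
            r = yt - mu * ot
            sg = np.sum(w * r * r) / n
            return -0.5 * (n * np.log(2 * np.pi * sg) + np.sum(np.log(s + delta)) + n)

        grid = np.exp(np.linspace(np.log(1e-6), np.log(1e6), 100))
        assert vc.loglik >= max(ll(d) for d in grid) - 1e-6

    def test_h2_recovery_consistency(self, medium_diallel):
        # bias shrinks as n grows on a fully additive trait (h2 = 0.8)
        _, G_big = medium_diallel
        errs = {}
        for n_panel, seed in ((8, 10), (20, 11)):
            m = sim.simulate_genetic_map(16, 20, 100.0, seed=seed)
            pa, pb = sim.simulate_segregant_panel(m, n_panel, n_panel, 12,
                                                  seed=seed + 1)
            _, G = sim.mate_diallel(pa, pb)
            K = compute_grm(G)
            s, U = linalg.eigh(K.K)
            ests = []
            for r in range(3):
                arch = sim.sample_architecture(G, n_traits=1, v_add=0.8,
                                               H2_mean=1.0, n_rep=1,
                                               seed=100 + r)
                ph = sim.simulate_phenotypes(G, arch, n_rep=1, seed=200 + r)
                vc = pr.fit_variance_components(
                    K.K, ph.means()["trait1"].to_numpy(), eig=(s, U))
                ests.append(vc.h2)
            errs[n_panel] = abs(np.mean(ests) - 0.8)
        assert errs[20] < 0.08


class TestBlup:
    def test_no_relatedness_predicts_the_mean(self):
        n = 8
        K = np.eye(n)
        vc = pr.VarianceComponents(sigma_g2=1.0, sigma_e2=0.5, mu=2.0)
        y = np.arange(5, dtype=float)
        out = pr.blup_predict(K, y, np.arange(5), np.arange(5, 8), vc)
        assert np.allclose(out.mean, 2.0)
        assert np.allclose(out.sd**2, 1.5, atol=1e-6)

    def test_perfect_correlation_limit(self):
        # a test individual genetically identical to a training one, with
        # sigma_e2 -> 0, inherits that training phenotype
        K = np.ones((2, 2))
        vc = pr.VarianceComponents(sigma_g2=1.0, sigma_e2=1e-12, mu=0.0)
        out = pr.blup_predict(K, np.array([3.7]), [0], [1], vc)
        assert out.mean[0] == pytest.approx(3.7, abs=1e-4)
        assert out.sd[0] == pytest.approx(0.0, abs=1e-3)

    def test_matches_dense_conditioning_oracle(self):
        # brute-force Schur complement on an explicit 6x6 joint covariance
        K = _random_psd(6, 7)
        vc = pr.VarianceComponents(sigma_g2=1.3, sigma_e2=0.4, mu=-0.6)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(4)
        out = pr.blup_predict(K, y, np.arange(4), np.array([4, 5]), vc)
        S = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(6)
        Soo = S[:4, :4]
        Spo = S[4:, :4]
        Spp = S[4:, 4:]
        mean = vc.mu + Spo @ np.linalg.inv(Soo) @ (y - vc.mu)
        cov = Spp - Spo @ np.linalg.inv(Soo) @ Spo.T
        assert np.allclose(out.mean, mean, rtol=1e-8)
        assert np.allclose(out.sd**2, np.diag(cov), rtol=1e-8)

    def test_predictive_sd_bounded_by_marginal(self):
        K = _random_psd(10, 9)
        K *= 10 / np.trace(K)
        vc = pr.VarianceComponents(sigma_g2=1.0, sigma_e2=0.3, mu=0.0)
        y = np.random.default_rng(10).standard_normal(7)
        out = pr.blup_predict(K, y, np.arange(7), np.arange(7, 10), vc)
        marginal = np.sqrt(vc.sigma_g2 * np.diag(K)[7:] + vc.sigma_e2)
        assert (out.sd <= marginal + 1e-8).all()

    def test_overlapping_train_test_rejected(self):
        K = np.eye(4)
        vc = pr.VarianceComponents(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            pr.blup_predict(K, np.zeros(2), [0, 1], [1, 2], vc)


class TestRepeatability:
    def test_hand_worked_example(self):
        # A: (1,3), B: (2,2) -> sigma^2 = 0.5, Var(r) = 0.5, H2_single = 0
        df = pd.DataFrame(
            {
                "hybrid_id": ["A", "A", "B", "B"],
                "trait": "t",
                "replicate": [1, 2, 1, 2],
                "value": [1.0, 3.0, 2.0, 2.0],
            }
        )
        h2_mean, h2_single = pr.estimate_repeatability(PhenotypeTable(df), "t")
        assert h2_single == pytest.approx(0.0)
        assert h2_mean == pytest.approx(0.0)

    def test_identical_replicates(self):
        df = pd.DataFrame(
            {
                "hybrid_id": ["A", "A", "B", "B"],
                "trait": "t",
                "replicate": [1, 2, 1, 2],
                "value": [1.0, 1.0, 5.0, 5.0],
            }
        )
        h2_mean, h2_single = pr.estimate_repeatability(PhenotypeTable(df), "t")
        assert h2_single == 1.0
        assert h2_mean == 1.0

    def test_pure_noise_replicates(self):
        # the population-denominator residual variance understates sigma^2 by
        # the factor (1 - 1/n_rep), so the null expectation of H2_single is
        # 1/n_rep; with many replicates it approaches zero
        rng = np.random.default_rng(11)
        n, n_rep = 150, 50
        df = pd.DataFrame(
            {
                "hybrid_id": np.repeat([f"h{i}" for i in range(n)], n_rep),
                "trait": "t",
                "replicate": np.tile(np.arange(1, n_rep + 1), n),
                "value": rng.standard_normal(n_rep * n),
            }
        )
        _, h2_single = pr.estimate_repeatability(PhenotypeTable(df), "t")
        assert abs(h2_single - 1 / n_rep) < 0.03
        assert h2_single < 0.06

    def test_single_replicate_rejected(self):
        df = pd.DataFrame(
            {"hybrid_id": ["A", "B"], "trait": "t", "replicate": [1, 1],
             "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            pr.estimate_repeatability(PhenotypeTable(df), "t")

    def test_designed_repeatability_recovered(self, medium_diallel):
        _, G = medium_diallel
        arch = sim.sample_architecture(G, n_traits=1, v_add=0.8, H2_mean=0.94,
                                       n_rep=4, seed=12)
        ph = sim.simulate_phenotypes(G, arch, n_rep=4, seed=13)
        h2_mean, _ = pr.estimate_repeatability(ph, "trait1")
        assert h2_mean == pytest.approx(0.94, abs=0.03)


class TestForwardSelection:
    def test_single_causal_noiseless(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 3, (40, 6)).astype(float)
        y = 2.0 * X[:, 3] + 1.0
        D = {("add", j): X[:, j] for j in range(6)}
        path = pr.forward_select_terms(D, y, max_terms=5)
        assert path.terms[0] == ("add", 3)
        assert path.rss[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_candidates_ranked_by_marginal_correlation(self):
        rng = np.random.default_rng(15)
        Q, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        Q = Q - Q.mean(axis=0)  # orthogonal to the intercept too
        y = rng.standard_normal(50)
        D = {j: Q[:, j] for j in range(5)}
        path = pr.forward_select_terms(D, y, max_terms=5)
        scores = [abs(np.corrcoef(Q[:, j], y)[0, 1]) for j in range(5)]
        assert path.terms == sorted(range(5), key=lambda j: -scores[j])

    def test_matches_exhaustive_per_step_oracle(self):
        rng = np.random.default_rng(16)
        X = rng.integers(0, 3, (30, 5)).astype(float)
        beta = np.array([1.0, 0.0, -0.7, 0.3, 0.0])
        y = X @ beta + 0.3 * rng.standard_normal(30)
        D = {("add", j): X[:, j] for j in range(5)}
        path = pr.forward_select_terms(D, y, max_terms=5)
        # oracle: exhaustive RSS search at each step via lstsq
        chosen = []
        for _ in range(5):
            best, best_rss = None, np.inf
            for j in range(5):
                if ("add", j) in chosen:
                    continue
                cols = [D[t] for t in chosen] + [X[:, j]]
                A = np.column_stack([np.ones(30)] + cols)
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = float(np.sum((y - A @ coef) ** 2))
                if rss < best_rss - 1e-12:
                    best, best_rss = ("add", j), rss
            chosen.append(best)
        assert path.terms == chosen[: len(path.terms)]

    def test_stops_early_with_few_candidates(self):
        rng = np.random.default_rng(17)
        X = rng.integers(0, 3, (20, 2)).astype(float)
        y = rng.standard_normal(20)
        D = {("add", j): X[:, j] for j in range(2)}
        path = pr.forward_select_terms(D, y, max_terms=50)
        assert len(path.terms) <= 2


class TestModelSize:
    def test_monogenic_noiseless_chooses_one_term(self):
        rng = np.random.default_rng(18)
        X = rng.integers(0, 3, (60, 8)).astype(float)
        y = 1.5 * X[:, 2]
        qtl = pr.fit_qtl_model(X, y, max_terms=5, seed=0)
        assert qtl.n_terms == 1
        assert qtl.terms[0] == ("add", 2)

    def test_pure_noise_keeps_model_small(self):
        rng = np.random.default_rng(19)
        X = rng.integers(0, 3, (500, 40)).astype(float)
        y = rng.standard_normal(500)
        C = X[:, :10]
        best, curve = pr.select_model_size(C, y, n_folds=4, seed=1)
        assert curve[best] <= 0.05
        # never chooses a size scoring below the empty model
        assert curve[best] >= curve[0]

    def test_curve_matches_fold_loop_oracle(self):
        rng = np.random.default_rng(20)
        n = 48
        C = rng.standard_normal((n, 3))
        y = C[:, 0] + 0.5 * rng.standard_normal(n)
        best, curve = pr.select_model_size(C, y, n_folds=4, seed=2)
        # independent oracle: rebuild the fold assignment and loop
        assign = np.empty(n, dtype=int)
        perm = np.random.default_rng(2).permutation(n)
        for f in range(4):
            assign[perm[f::4]] = f
        expected = np.zeros(4)
        for t in range(4):
            scores = []
            for f in range(4):
                tr, te = assign != f, assign == f
                A = np.column_stack([np.ones(tr.sum()), C[tr, :t]])
                coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                pred = np.column_stack([np.ones(te.sum()), C[te, :t]]) @ coef
                sst = np.sum((y[te] - y[te].mean()) ** 2)
                scores.append(1 - np.sum((y[te] - pred) ** 2) / sst)
            expected[t] = np.mean(scores)
        assert np.allclose(curve, expected, atol=1e-10)
        assert best == int(np.argmax(expected))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            pr.select_model_size(np.ones((3, 1)), np.ones(3), n_folds=5)


class TestInteractionCandidates:
    def test_enumeration_with_single_selected_site(self):
        cand = pr.expand_interaction_candidates([0], n_sites=2)
        assert cand == [("int", 0, 0), ("int", 0, 1)]

    def test_self_pair_is_squared_dosage(self):
        X = np.array([[0.0], [1.0], [2.0]])
        col = pr.term_column(X, ("int", 0, 0))
        assert np.array_equal(col, np.array([0.0, 1.0, 4.0]))

    def test_no_selection_rejected(self):
        with pytest.raises(ValueError):
            pr.expand_interaction_candidates([], n_sites=5)

    def test_overdominant_locus_needs_self_pair(self):
        # heterozygote advantage: adding (j, j) strictly reduces RSS
        rng = np.random.default_rng(21)
        X = rng.integers(0, 3, (200, 4)).astype(float)
        y = 1.0 * (X[:, 1] == 1) + 0.1 * rng.standard_normal(200)

        def rss(terms):
            A = np.column_stack([np.ones(200), pr.design_from_terms(X, terms)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(np.sum((y - A @ coef) ** 2))

        assert rss([("add", 1), ("int", 1, 1)]) < 0.6 * rss([("add", 1)])


class TestLmm:
    def test_without_fixed_effects_reduces_to_blup(self):
        K = _random_psd(12, 22)
        K *= 12 / np.trace(K)
        rng = np.random.default_rng(23)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(12))
        y = L @ rng.standard_normal(12) + 0.3 * rng.standard_normal(12)
        lmm = pr.fit_lmm(None, K, y[:9], np.arange(9))
        direct = pr.blup_predict(K, y[:9], np.arange(9), np.arange(9, 12),
                                 lmm.vc)
        out = lmm.predict(K, None, np.arange(9, 12))
        assert np.allclose(out.mean, direct.mean)
        assert np.allclose(out.sd, direct.sd)

    def test_no_genetic_variance_reduces_to_ols(self):
        # independent noise phenotype: the polygenic component shrinks and
        # predictions approach the fixed-effect (QTL) means
        rng = np.random.default_rng(24)
        X = rng.integers(0, 3, (150, 10)).astype(float)
        y = 2.0 * X[:, 4] + 0.05 * rng.standard_normal(150)
        K = np.eye(150)
        qtl = pr.fit_qtl_model(X[:100], y[:100], max_terms=3, seed=3)
        lmm = pr.fit_lmm(qtl, K, y[:100], np.arange(100), X_train=X[:100])
        out = lmm.predict(K, X[100:], np.arange(100, 150))
        assert np.allclose(out.mean, qtl.predict_mean(X[100:]), atol=0.05)

    def test_dominant_qtl_plus_polygenic_beats_components(self, medium_diallel):
        # one strong (over)dominant QTL on a polygenic background: the LMM
        # should beat both the QTLs-only and BLUP-only models out of sample
        ped, G = medium_diallel
        from diallelpred import evaluation as ev

        arch = sim.sample_architecture(
            G, n_traits=1, n_qtl=3, v_add=0.40, v_dom=0.30, H2_mean=1.0,
            n_rep=1, seed=25,
        )
        ph = sim.simulate_phenotypes(G, arch, n_rep=1, seed=26)
        ds = ev.DiallelDataset(G, ped, ph)
        plan = ev.build_cv_folds(ped, seed=27)
        opts = {"max_terms": 10, "interactions_max": 6, "inner_folds": 4}
        r2 = {}
        for model in ("QTL", "BLUP", "LMM"):
            res = ev.run_crossval(ds, model, plan, "random", seed=28,
                                  model_opts=opts)
            r2[model] = res.pooled_r2()["trait1"]
        assert r2["LMM"] > r2["QTL"]
        assert r2["LMM"] > r2["BLUP"]


class TestLmmPlusP:
    def test_uncorrelated_covariates_reduce_to_lmm(self):
        rng = np.random.default_rng(29)
        n = 300
        K = _random_psd(n, 30)
        K *= n / np.trace(K)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.4 * rng.standard_normal(n)
        P = rng.standard_normal((n, 3))  # independent of y
        m = pr.fit_lmm_plus_p(P[:250], y[:250], K, np.arange(250))
        lmm = pr.fit_lmm(None, K, y[:250], np.arange(250))
        out = m.predict(K, P[250:], None, np.arange(250, n))
        ref = lmm.predict(K, None, np.arange(250, n))
        # stage-1 weights on independent covariates are near zero, so the
        # composite prediction approaches the plain LMM's
        assert np.corrcoef(out.mean, ref.mean)[0, 1] > 0.98
        assert np.allclose(out.mean, ref.mean, atol=0.3)

    def test_leaked_focal_trait_makes_stage_two_inert(self):
        rng = np.random.default_rng(31)
        n = 60
        K = _random_psd(n, 32)
        y = rng.standard_normal(n)
        P = y[:, None].copy()
        m = pr.fit_lmm_plus_p(P[:40], y[:40], K, np.arange(40))
        out = m.predict(K, P[40:], None, np.arange(40, 60))
        assert np.allclose(out.mean, y[40:], atol=1e-3)

    def test_missing_test_covariates_rejected(self):
        K = np.eye(5)
        y = np.arange(4.0)
        P = np.ones((4, 2))
        m = pr.fit_lmm_plus_p(P, y, K, np.arange(4))
        P_te = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            m.predict(K, P_te, None, [4])


class TestMidparent:
    def test_noiseless_additive_layout_is_exact(self):
        ped = sim.diallel_pedigree([f"A{i}" for i in range(4)],
                                   [f"b{j}" for j in range(4)])
        a_val = {f"A{i}": float(i) for i in range(4)}
        b_val = {f"b{j}": 2.0 * j for j in range(4)}
        ids = list(ped.hybrid_id)
        y = np.array([(a_val[a] + b_val[b]) / 2
                      for a, b in zip(ped.parent_a, ped.parent_alpha)])
        # hold out a diagonal so every parent still appears in training
        held = {f"A{i}xb{i}" for i in range(4)}
        train = [h for h in ids if h not in held]
        tr_mask = np.array([h not in held for h in ids])
        model = pr.fit_midparent(ped, y[tr_mask], train)
        preds = pr.predict_midparent(model, ped, sorted(held))
        expected = np.array([y[ids.index(h)] for h in sorted(held)])
        assert np.allclose(preds, expected, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        # 2x2 layout y = [[0, 2], [2, 4]]; train on 3 cells, predict the 4th
        ped = sim.diallel_pedigree(["A1", "A2"], ["b1", "b2"])
        ids = list(ped.hybrid_id)  # A1xb1, A1xb2, A2xb1, A2xb2
        y = np.array([0.0, 2.0, 2.0])
        model = pr.fit_midparent(ped, y, ids[:3])
        pred = pr.predict_midparent(model, ped, [ids[3]])[0]
        D = np.array([[0.5, 0.0, 0.5, 0.0],
                      [0.5, 0.0, 0.0, 0.5],
                      [0.0, 0.5, 0.5, 0.0]])
        coef = np.linalg.pinv(D) @ y
        expected = 0.5 * (coef[1] + coef[3])
        assert pred == pytest.approx(expected, abs=1e-8)

    def test_unseen_parent_gives_missing_prediction(self):
        ped = sim.diallel_pedigree(["A1", "A2"], ["b1", "b2"])
        ids = list(ped.hybrid_id)
        model = pr.fit_midparent(ped, np.array([1.0]), [ids[0]])  # only A1, b1
        with pytest.warns(UserWarning, match="unseen"):
            out = pr.predict_midparent(model, ped, [ids[3]])
        assert np.isnan(out[0])

    def test_tracks_blup_on_additive_diallel(self, additive_dataset):
        # on a fully additive trait midparent and BLUP predictions agree
        ped, G, _, ph = additive_dataset
        from diallelpred import evaluation as ev

        ds = ev.DiallelDataset(G, ped, ph)
        plan = ev.build_cv_folds(ped, seed=33)
        test_ids = plan.fold_members(1)
        train_ids = ev.build_training_scenario(plan, ped, 1, "random")
        blup = ev.fit_and_predict("BLUP", ds, "trait1", train_ids, test_ids)
        mp = ev.fit_and_predict("midparent", ds, "trait1", train_ids, test_ids)
        r = np.corrcoef(blup.mean, mp.mean)[0, 1]
        assert r**2 > 0.95


class TestMultiTrait:
    def test_diagonal_covariances_reduce_to_single_trait(self):
        # with diagonal C and Sigma, joint conditioning equals per-trait BLUP
        K = _random_psd(8, 34)
        K *= 8 / np.trace(K)
        rng = np.random.default_rng(35)
        Y = rng.standard_normal((8, 2))
        F = np.zeros((8, 2))
        model = pr.MultiTraitModel(
            trait_names=["a", "b"],
            C=np.diag([1.2, 0.8]), Sigma=np.diag([0.4, 0.6]),
            mu=np.zeros(2), train_idx=np.arange(6), R_train=Y[:6],
            loglik=0.0,
        )
        out = pr.predict_mtlmm(model, K, np.arange(6, 8), 0, Y[6:],
                               np.zeros((2, 2)))
        vc = pr.VarianceComponents(sigma_g2=1.2, sigma_e2=0.4, mu=0.0)
        ref = pr.blup_predict(K, Y[:6, 0], np.arange(6), np.arange(6, 8), vc)
        assert np.allclose(out.mean, ref.mean, atol=1e-8)
        assert np.allclose(out.sd, ref.sd, atol=1e-8)

    def test_matches_dense_joint_mvn_oracle(self):
        # 2 traits x 8 individuals: conditional mean/var from the explicit
        # 16x16 covariance built and inverted independently
        K = _random_psd(8, 36)
        K *= 8 / np.trace(K)
        rng = np.random.default_rng(37)
        C = np.array([[1.0, 0.5], [0.5, 0.9]])
        Sig = np.array([[0.5, 0.2], [0.2, 0.7]])
        Y = rng.standard_normal((8, 2))
        model = pr.MultiTraitModel(
            trait_names=["a", "b"], C=C, Sigma=Sig, mu=np.zeros(2),
            train_idx=np.arange(6), R_train=Y[:6], loglik=0.0,
        )
        out = pr.predict_mtlmm(model, K, np.arange(6, 8), 0, Y[6:],
                               np.zeros((2, 2)))
        # oracle: trait-major flattened covariance, numpy inverse
        full = np.kron(C, K) + np.kron(Sig, np.eye(8))
        obs = [t * 8 + i for t in range(2) for i in range(6)] + [1 * 8 + 6, 1 * 8 + 7]
        prd = [0 * 8 + 6, 0 * 8 + 7]
        vals = np.concatenate([Y[:6, 0], Y[:6, 1], Y[6:, 1]])
        Soo = full[np.ix_(obs, obs)]
        Spo = full[np.ix_(prd, obs)]
        Spp = full[np.ix_(prd, prd)]
        mean = Spo @ np.linalg.inv(Soo) @ vals
        cov = Spp - Spo @ np.linalg.inv(Soo) @ Spo.T
        assert np.allclose(out.mean, mean, rtol=1e-8, atol=1e-10)
        assert np.allclose(out.sd**2, np.diag(cov), rtol=1e-8, atol=1e-10)

    def test_fit_recovers_strong_trait_correlation(self, medium_diallel):
        ped, G = medium_diallel
        arch = sim.sample_architecture(
            G, n_traits=2, n_qtl=10, v_add=0.4, v_shared=0.4,
            shared_add_frac=0.0, H2_mean=1.0, n_rep=1, seed=38,
        )
        ph = sim.simulate_phenotypes(G, arch, n_rep=1, seed=39)
        Y = ph.means().to_numpy()
        K = compute_grm(G)
        model = pr.fit_mtlmm(Y, np.zeros_like(Y), K.K, np.arange(len(Y)))
        rho_sigma = model.Sigma[0, 1] / np.sqrt(model.Sigma[0, 0]
                                                * model.Sigma[1, 1])
        # the shared latent factor (non-genetic component) is strongly
        # correlated across the two traits
        assert rho_sigma > 0.4
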