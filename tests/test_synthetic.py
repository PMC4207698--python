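import numpy as np
import pandas as pd
import pytest

from paramodiv.pgls import lambda_transform
from paramodiv.simulate import (RegressionTruth, SimConfig, TraitTruth,
                                simulate_bisse_tree, simulate_painted_bm,
                                simulate_regression_data, simulate_study,
                                simulate_tree_sample, stream_rng,
                                subsample_tips)
from paramodiv.traitrate import PaintedTree, painted_covariance
from paramodiv.trees import check_ultrametric


class TestBisseTreeSim:
    def test_yule_expected_tip_count(self):
        """Pure birth from 2 crown lineages for time T: E[N] = 2e^{λT}."""
        rng = stream_rng(123, "tree")
        n = [simulate_bisse_tree([1, 1, 0, 0, 0, 0], stop_time=1.0,
                                 root_state=0, rng=rng)[0].n_tips
             for _ in range(2000)]
        n = np.asarray(n, dtype=float)
        expect = 2.0 * np.e
        se = n.std(ddof=1) / np.sqrt(len(n))
        assert abs(n.mean() - expect) < 3 * se

    def test_no_transitions_keeps_root_state(self):
        tree, states = simulate_bisse_tree([1, 1, 0.2, 0.2, 0, 0],
                                           stop_taxa=30, root_state=0, rng=3)
        assert set(states.values) == {0}

    def test_state1_dominates_when_favoured(self):
        fracs = []
        for rep in range(30):
            _, states = simulate_bisse_tree([0.5, 1.0, 0.1, 0.1, 0.01, 0.01],
                                            stop_taxa=80, rng=700 + rep)
            fracs.append(states.mean())
        assert np.mean(fracs) > 0.5

    def test_event_balance_per_replicate(self):
        for rep in range(20):
            tree, states, hist = simulate_bisse_tree(
                [1, 1.2, 0.3, 0.2, 0.1, 0.1], stop_taxa=25, rng=50 + rep,
                return_history=True)
            assert (hist["n_start"] + hist["births"] - hist["deaths"]
                    == hist["extant"])
            assert tree.n_tips == hist["extant"]

    def test_trees_are_ultrametric_and_binary(self):
        tree, _ = simulate_bisse_tree([1, 1, 0.3, 0.3, 0.1, 0.1],
                                      stop_taxa=40, rng=8)
        ok, dev = check_ultrametric(tree, tol=1e-9)
        assert ok and tree.is_binary

    def test_reproducible_under_seed(self):
        a = simulate_bisse_tree([1, 1, 0.1, 0.1, 0.05, 0.05], stop_taxa=15, rng=77)
        b = simulate_bisse_tree([1, 1, 0.1, 0.1, 0.05, 0.05], stop_taxa=15, rng=77)
        assert a[0].to_newick() == b[0].to_newick()
        assert (a[1] == b[1]).all()


class TestSubsample:
    def test_full_fractions_identity(self):
        tree, states = simulate_bisse_tree([1, 1, 0, 0, 0.1, 0.1],
                                           stop_taxa=20, rng=5)
        sub, st = subsample_tips(tree, states, 1.0, 1.0, rng=1)
        assert sorted(sub.tip_labels) == sorted(tree.tip_labels)

    def test_study_fractions_recovered(self):
        """f1=22/43, f0=4/12: retained per-state fractions match within
        3σ binomial error on a large tree."""
        tree, states = simulate_bisse_tree([1, 1, 0, 0, 0.3, 0.3],
                                           stop_taxa=600, rng=9)
        f0, f1 = 4 / 12, 22 / 43
        kept0 = kept1 = tot0 = tot1 = 0
        for rep in range(8):
            sub, st = subsample_tips(tree, states, f0, f1, rng=rep)
            kept1 += int((st == 1).sum())
            kept0 += int((st == 0).sum())
        tot1 = 8 * int((states == 1).sum())
        tot0 = 8 * int((states == 0).sum())
        for kept, tot, f in ((kept0, tot0, f0), (kept1, tot1, f1)):
            se = np.sqrt(f * (1 - f) / tot)
            assert abs(kept / tot - f) < 3 * se

    def test_deterministic_given_seed(self):
        tree, states = simulate_bisse_tree([1, 1, 0, 0, 0.2, 0.2],
                                           stop_taxa=50, rng=2)
        a = subsample_tips(tree, states, 0.5, 0.5, rng=11)
        b = subsample_tips(tree, states, 0.5, 0.5, rng=11)
        assert a[0].to_newick() == b[0].to_newick()


class TestPaintedBmSim:
    def test_covariance_matches_target(self):
        """Sample covariance over 5000 draws on a fixed 5-tip painting
        matches σ²·C elementwise within 3 MC SE."""
        tree, _ = simulate_bisse_tree([1, 1, 0, 0, 0.1, 0.1], stop_taxa=5, rng=4)
        rng = np.random.default_rng(6)
        painted = PaintedTree(tree, rng.integers(0, 2, tree.n_nodes).astype(np.int8))
        truth = TraitTruth(mean0=0.0, mean1=0.0, sigma2=0.7, rate_ratio=1.0,
                           lam=1.0)
        draws = np.array([simulate_painted_bm(painted, truth, rng=r)
                          for r in range(5000)])
        S = np.cov(draws.T, bias=True)
        pc = painted_covariance(painted)
        target = truth.sigma2 * pc.total
        # MC SE of a sample covariance entry ~ sqrt((Cii*Cjj + Cij^2)/n)
        for i in range(5):
            for j in range(5):
                se = np.sqrt((target[i, i] * target[j, j] + target[i, j] ** 2)
                             / 5000)
                assert abs(S[i, j] - target[i, j]) < 3.5 * se

    def test_zero_variance_hits_state_means(self):
        tree, _ = simulate_bisse_tree([1, 1, 0, 0, 0.1, 0.1], stop_taxa=6, rng=2)
        es = np.zeros(tree.n_nodes, np.int8)
        es[: 3] = 1
        painted = PaintedTree(tree, es)
        y = simulate_painted_bm(painted, TraitTruth(mean0=-1.0, mean1=2.0,
                                                    sigma2=0.0), rng=0)
        assert np.allclose(y, np.where(painted.tip_states == 1, 2.0, -1.0))


class TestRegressionSim:
    def test_zero_noise_exact_betas(self):
        tree, states = simulate_bisse_tree([1, 1, 0, 0, 0.2, 0.2],
                                           stop_taxa=30, rng=10)
        truth = RegressionTruth(resid_sigma2=0.0)
        tab = simulate_regression_data(tree, states, rng=3, pinnae_truth=truth)
        from paramodiv.pgls import fit_pgls_models
        fits = fit_pgls_models(tree, tab, "pinnae_length")
        fit = fits["altitude*habitat"]
        assert fit.degenerate or np.allclose(
            [fit.coef("intercept"), fit.coef("altitude"), fit.coef("habitat"),
             fit.coef("altitude:habitat")],
            [truth.beta0, truth.beta1, truth.beta2, truth.beta3],
            rtol=1e-5, atol=1e-8)

    def test_interaction_sign_recovery(self):
        """β1<0, β3<0: the fitted interaction model recovers the sign of β3
        nearly always (scaled to 20 replicates of the >90%/100-rep world)."""
        truth = RegressionTruth(beta1=-6e-4, beta3=-4e-4)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            tree, states = simulate_bisse_tree([1, 1, 0.1, 0.1, 0.3, 0.3],
                                               stop_taxa=55, rng=rep)
            tab = simulate_regression_data(tree, states, rng=100 + rep,
                                           pinnae_truth=truth)
            from paramodiv.pgls import fit_pgls_models
            fit = fit_pgls_models(tree, tab, "pinnae_length")["altitude*habitat"]
            hits += fit.coef("altitude:habitat") < 0
        assert hits / n_rep >= 0.9

    def test_wald_type_one_error_calibrated(self):
        """All β=0: the altitude Wald test at α=0.05 rejects at a rate in
        [0.02, 0.10] (scaled to 300 replicates of the stated 500)."""
        from scipy import stats as sps
        from paramodiv.pgls import fit_pgls_models
        truth = RegressionTruth(beta0=3.0, beta1=0.0, beta2=0.0, beta3=0.0,
                                resid_sigma2=1.0, resid_lambda=1.0)
        tree, states = simulate_bisse_tree([1, 1, 0.1, 0.1, 0.3, 0.3],
                                           stop_taxa=55, rng=1234)
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            tab = simulate_regression_data(tree, states, rng=5000 + rep,
                                           pinnae_truth=truth)
            fit = fit_pgls_models(tree, tab, "pinnae_length",
                                  log_transform=True)["altitude"]
            tstat = fit.coef("altitude") / fit.se[fit.names.index("altitude")]
            pval = 2 * sps.t.sf(abs(tstat), df=fit.n - len(fit.names))
            rejections += pval < 0.05
        assert 0.02 <= rejections / n_rep <= 0.10


class TestStudySim:
    def test_posterior_sample_shares_tips_and_is_ultrametric(self):
        cfg = SimConfig(seed=5, n_trees=6, stop_taxa=40)
        sample, table, states, full_tree = simulate_study(cfg)
        tips = set(sample[0].tip_labels)
        for t in sample:
            assert set(t.tip_labels) == tips
            assert check_ultrametric(t, tol=1e-8)[0]
        assert set(table["specimen_id"]) == tips
        assert full_tree.n_tips == 40
        # reproducibility
        sample2, table2, _, _ = simulate_study(cfg)
        assert sample2[0].to_newick() == sample[0].to_newick()
        pd.testing.assert_frame_equal(table, table2)
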