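import numpy as np
import pandas as pd
import pytest

from paramodiv.bisse import (BisseParams, MODEL_SPECS, bisse_loglik, fit_bisse,
                             marginal_asr, paint_branches)
from paramodiv.simulate import simulate_bisse_tree
from paramodiv.trees import Phylogeny, SamplingFractions

from _reference import ref_bisse_loglik

P_GENERIC = [0.8, 1.2, 0.2, 0.1, 0.1, 0.07]


class TestLoglik:
    def test_pure_birth_closed_form(self):
        """2-tip cherry, both state 0, no extinction: logL = ln(λ e^{-2λT})."""
        tree = Phylogeny.from_newick("(A:1.0,B:1.0);")
        p = BisseParams(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        ll = bisse_loglik(tree, {"A": 0, "B": 0}, p)
        assert ll == pytest.approx(np.log(1.0 * np.exp(-2.0)), abs=1e-8)

    def test_extinction_free_E_stays_zero(self, eight_tip):
        """With μ=0 and complete sampling, E≡0, so conditioning divides by
        the plain root speciation term only."""
        tree, states = eight_tip
        p = BisseParams(0.7, 1.1, 0.0, 0.0, 0.1, 0.1)
        plain = bisse_loglik(tree, states, p, root_mode="equal")
        cond = bisse_loglik(tree, states, p, root_mode="equal",
                            condition_on_survival=True)
        # E(root)=0 => conditioning term = 0.5·λ0 + 0.5·λ1
        assert plain - cond == pytest.approx(np.log(0.5 * 0.7 + 0.5 * 1.1),
                                             abs=1e-7)

    @pytest.mark.parametrize("f0,f1,root_mode,cond", [
        (1.0, 1.0, "obs", False),
        (4 / 12, 22 / 43, "obs", True),
        (0.5, 0.9, "equal", False),
        (0.7, 0.4, "stationary", False),
    ])
    def test_matches_scipy_reference(self, eight_tip, f0, f1, root_mode, cond):
        tree, states = eight_tip
        a = bisse_loglik(tree, states, BisseParams(*P_GENERIC),
                         SamplingFractions(f0, f1), root_mode=root_mode,
                         condition_on_survival=cond)
        b = ref_bisse_loglik(tree, states, P_GENERIC, f0, f1, root_mode, cond)
        assert a == pytest.approx(b, abs=1e-6)

    def test_label_symmetry(self, eight_tip):
        """With λ and μ state-independent, swapping tip labels 0↔1 together
        with q01↔q10 leaves the likelihood unchanged."""
        tree, states = eight_tip
        p = [0.9, 0.9, 0.2, 0.2, 0.13, 0.05]
        p_sw = [0.9, 0.9, 0.2, 0.2, 0.05, 0.13]
        a = bisse_loglik(tree, states, BisseParams(*p), root_mode="equal")
        b = bisse_loglik(tree, 1 - states, BisseParams(*p_sw),
                         root_mode="equal")
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_sampling_fractions(self, eight_tip):
        tree, states = eight_tip
        p = BisseParams(*P_GENERIC)
        lls = [bisse_loglik(tree, states, p, SamplingFractions(f, f))
               for f in (1.0, 0.8, 0.5, 0.3)]
        assert np.all(np.isfinite(lls))

    def test_lambda_to_zero_diverges(self):
        """With transitions negligible, a state whose tips require a
        speciation event drives the likelihood to -inf as its λ→0."""
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        states = {"A": 1, "B": 1, "C": 0}
        lls = [bisse_loglik(tree, states,
                            BisseParams(0.5, la1, 0.0, 0.0, 1e-6, 1e-6))
               for la1 in (1.0, 1e-2, 1e-4)]
        assert lls[0] > lls[1] > lls[2]
        assert lls[2] < lls[0] - 5

    def test_rejects_polytomy(self):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="binary"):
            bisse_loglik(tree, {"A": 0, "B": 0, "C": 0},
                         BisseParams(1, 1, 0, 0, 0.1, 0.1))


class TestFit:
    def test_nesting_and_parsimony_under_null(self):
        """Data generated under the 3-parameter model: the full model can
        never fit worse (nesting) but AICc should usually prefer the
        simpler truth. Scaled-down version of the larger study the
        acceptance suite runs (15 replicates, 100 tips)."""
        wins = 0
        n_rep = 15
        for rep in range(n_rep):
            tree, st = simulate_bisse_tree([1, 1, 0.1, 0.1, 0.05, 0.05],
                                           stop_taxa=100, rng=300 + rep)
            f_full = fit_bisse(tree, st, spec="full6", seed=rep)
            f_null = fit_bisse(tree, st, spec="null3", seed=rep)
            assert f_full.loglik >= f_null.loglik - 1e-4
            wins += f_null.aicc < f_full.aicc
        assert wins > n_rep / 2

    def test_aicc_consistent(self, eight_tip):
        tree, st = eight_tip
        fit = fit_bisse(tree, st, spec="null3", seed=1)
        from paramodiv.modelselect import aicc
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n))
        assert fit.k == 3 and fit.n == 8

    @pytest.mark.parametrize("name,k", [("full6", 6), ("eq_rates4", 4),
                                        ("sdd_speciation4", 4), ("null3", 3)])
    def test_spec_free_parameter_counts(self, name, k):
        assert MODEL_SPECS[name].k == k


class TestMarginalASR:
    def test_symmetric_two_tip_root(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        p = BisseParams(1.0, 1.0, 0.1, 0.1, 0.2, 0.2)
        m = marginal_asr(tree, {"A": 0, "B": 1}, p, root_mode="equal")
        assert m[tree.root] == pytest.approx([0.5, 0.5], abs=1e-9)

    @pytest.mark.parametrize("root_mode,cond", [
        ("obs", False), ("equal", False), ("obs", True), ("stationary", False),
    ])
    def test_matches_clamped_likelihood_oracle(self, eight_tip, root_mode, cond):
        """Marginals must equal the ratio of from-scratch clamped
        likelihood evaluations at every internal node."""
        tree, states = eight_tip
        f = SamplingFractions(4 / 12, 22 / 43)
        m = marginal_asr(tree, states, BisseParams(*P_GENERIC), f,
                         root_mode=root_mode, condition_on_survival=cond)
        for n in range(tree.n_tips, tree.n_nodes):
            l0 = ref_bisse_loglik(tree, states, P_GENERIC, f.f0, f.f1,
                                  root_mode, cond, clamp=(n, 0))
            l1 = ref_bisse_loglik(tree, states, P_GENERIC, f.f0, f.f1,
                                  root_mode, cond, clamp=(n, 1))
            p0 = 1.0 / (1.0 + np.exp(l1 - l0))
            assert m[n, 0] == pytest.approx(p0, abs=1e-6)
            assert m[n, 0] + m[n, 1] == pytest.approx(1.0, abs=1e-9)

    def test_no_change_limit(self):
        """q→0⁺ with all tips state 0 forces every node to state 0."""
        tree, _ = simulate_bisse_tree([1, 1, 0, 0, 0.1, 0.1],
                                      stop_taxa=6, rng=2)
        states = pd.Series(0, index=tree.tip_labels)
        m = marginal_asr(tree, states, BisseParams(1, 1, 0.1, 0.1, 1e-9, 1e-9))
        assert np.allclose(m[tree.n_tips:, 0], 1.0, atol=1e-6)


class TestPainting:
    def test_argmax_and_pendant_rule(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        marg = np.full((tree.n_nodes, 2), np.nan)
        inner = [n for n in range(3, 5)]
        root = tree.root
        other = [n for n in inner if n != root][0]
        marg[other] = [0.9, 0.1]
        marg[root] = [0.2, 0.8]
        painted = paint_branches(tree, marg, {"A": 1, "B": 0, "C": 1})
        assert painted.edge_state[other] == 0      # argmax of (0.9, 0.1)
        assert painted.edge_state[root] == 1
        # pendant edges take observed tip states
        assert painted.edge_state[tree.tip_index("A")] == 1
        assert painted.edge_state[tree.tip_index("B")] == 0

    def test_all_state_one(self, eight_tip):
        tree, _ = eight_tip
        marg = np.tile([0.1, 0.9], (tree.n_nodes, 1))
        states = pd.Series(1, index=tree.tip_labels)
        painted = paint_branches(tree, marg, states)
        assert np.all(painted.edge_state == 1)

    def test_tie_breaks_to_parent_then_root_zero(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        marg = np.full((tree.n_nodes, 2), np.nan)
        root = tree.root
        inner = [n for n in range(4, 7) if n != root]
        marg[root] = [0.5, 0.5]            # root tie -> state 0
        marg[inner[0]] = [0.5, 0.5]        # tie -> parent (root) state 0
        marg[inner[1]] = [0.3, 0.7]
        painted = paint_branches(tree, marg, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert painted.edge_state[root] == 0
        assert painted.edge_state[inner[0]] == 0
        assert painted.edge_state[inner[1]] == 1
        assert set(painted.tie_nodes) == {root, inner[0]}
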