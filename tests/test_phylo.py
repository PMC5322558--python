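"""Substitution models, pruning likelihoods, fitting, conservation tests."""

import numpy as np
import pytest
from oracles import pruning_oracle

from ucekit import phylo, simulate
from ucekit.phylo import (
    PhyloModel,
    deceleration_lrt,
    fit_background_model,
    parse_newick,
    prob_perfect_conservation,
    transition_matrix,
)
from ucekit.pipeline import _sample_columns


class TestNewick:
    def test_two_leaves(self):
        t = parse_newick("(A:0.1,B:0.2);")
        assert t.n_leaves == 2
        assert t.total_length == pytest.approx(0.3)

    def test_internal_node(self):
        t = parse_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert t.n_leaves == 3
        assert t.n_nodes - t.n_leaves == 2  # root + one internal

    def test_roundtrip(self):
        text = "((A:0.1,B:0.1):0.05,C:0.2);"
        t = parse_newick(text)
        t2 = parse_newick(t.to_newick())
        assert sorted(t2.leaf_names) == sorted(t.leaf_names)
        assert t2.total_length == pytest.approx(t.total_length)

    @pytest.mark.parametrize("bad", ["((A,B;", "", "   "])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)


class TestTransitionMatrix:
    def test_jc_zero_is_identity(self, jc6):
        assert np.allclose(transition_matrix(jc6, 0.0), np.eye(4))

    def test_jc_stationary_limit(self, jc6):
        assert np.allclose(transition_matrix(jc6, 100.0), 0.25, atol=1e-8)

    def test_jc_closed_form(self, jc6):
        for t in (0.01, 0.3, 1.5):
            P = transition_matrix(jc6, t)
            off = (1 - np.exp(-4 * t / 3)) / 4
            expected = np.full((4, 4), off)
            np.fill_diagonal(expected, 1 - 3 * off)
            assert np.allclose(P, expected, atol=1e-12)

    def test_rows_sum_and_chapman_kolmogorov(self, tree6, rng):
        model = PhyloModel(tree=tree6, kind="HKY", kappa=3.0,
                           pi=[0.3, 0.2, 0.2, 0.3])
        for _ in range(5):
            s, t = rng.uniform(0.01, 1.0, 2)
            Ps, Pt, Pst = (transition_matrix(model, x) for x in (s, t, s + t))
            assert np.allclose(Ps.sum(1), 1.0, atol=1e-12)
            assert np.allclose(Ps @ Pt, Pst, atol=1e-10)

    def test_negative_time_error(self, jc6):
        with pytest.raises(ValueError):
            transition_matrix(jc6, -0.1)


class TestColumnLikelihood:
    def test_jc_pair_identity_closed_form(self):
        d = 0.75
        model = PhyloModel(tree=parse_newick(f"(A:{d/2},B:{d/2});"), kind="JC")
        # P(pair identical) = 1/4 (1 + 3 e^{-4d/3}); a specific identical pair
        # has probability that value / 4
        expected = 0.25 * (1 + 3 * np.exp(-4 * d / 3)) / 4
        got = np.exp(phylo.column_log_likelihood({"A": "C", "B": "C"}, model))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_distance_identical_leaves(self):
        model = PhyloModel(tree=parse_newick("(A:0,B:0);"), kind="HKY",
                           kappa=2.0, pi=[0.4, 0.1, 0.2, 0.3])
        for k, b in enumerate("ACGT"):
            got = np.exp(phylo.column_log_likelihood({"A": b, "B": b}, model))
            assert got == pytest.approx(model.pi[k], abs=1e-12)

    def test_pruning_equals_state_enumeration(self, rng):
        """Pruning == brute-force sum over internal states, 4-leaf trees."""
        for _ in range(10):
            b = rng.uniform(0.01, 0.8, 6)
            tree = parse_newick(
                "((A:%f,B:%f):%f,(C:%f,D:%f):%f);" % tuple(b)
            )
            model = PhyloModel(tree=tree, kind="HKY",
                               kappa=rng.uniform(1, 6), pi=rng.dirichlet([5] * 4))
            for _ in range(10):
                bases = rng.integers(0, 4, 4)
                col = {n: "ACGT"[x] for n, x in zip(tree.leaf_names, bases)}
                assert phylo.column_log_likelihood(col, model) == pytest.approx(
                    pruning_oracle(tree, model, bases), abs=1e-10
                )

    def test_missing_leaf_marginalized(self, jc6):
        full = sum(
            np.exp(phylo.column_log_likelihood(
                {"A": "A", "B": "C", "C": "G", "D": "T", "E": "A", "F": b}, jc6))
            for b in "ACGT"
        )
        marg = np.exp(phylo.column_log_likelihood(
            {"A": "A", "B": "C", "C": "G", "D": "T", "E": "A"}, jc6))
        assert marg == pytest.approx(full, rel=1e-12)

    def test_unknown_leaf_error(self, jc6):
        with pytest.raises(ValueError, match="not in tree"):
            phylo.column_log_likelihood({"NOPE": "A"}, jc6)


class TestFit:
    def _columns(self, model, n, seed):
        cfg = simulate.SimulationConfig(seed=seed, model=model, genome_length=n,
                                        ref_species=model.tree.leaf_names[0])
        blocks, _ = simulate.simulate_alignment(cfg)
        return _sample_columns(blocks, model.tree, n, 0)

    def test_jc_scale_recovery(self, tree6):
        truth = PhyloModel(tree=tree6, kind="JC")
        cols = self._columns(truth, 50_000, seed=3)
        fit = fit_background_model(cols, tree6, model_kind="JC")
        assert fit.scale == pytest.approx(1.0, rel=0.05)
        # reported log-likelihood reproducible from returned parameters
        ll = phylo.alignment_log_likelihood(cols, fit)
        assert ll == pytest.approx(fit.log_likelihood, abs=1e-6)

    def test_hky_kappa_recovery(self, tree6):
        truth = PhyloModel(tree=tree6, kind="HKY", kappa=4.0,
                           pi=[0.3, 0.2, 0.2, 0.3])
        cols = self._columns(truth, 50_000, seed=4)
        fit = fit_background_model(cols, tree6, model_kind="HKY")
        assert fit.kappa == pytest.approx(4.0, rel=0.10)
        assert np.allclose(fit.pi, truth.pi, atol=0.02)

    def test_all_identical_columns_hits_lower_bound(self, tree6):
        cols = np.zeros((6, 500), dtype=np.int8)
        fit = fit_background_model(cols, tree6, model_kind="JC",
                                   scale_bounds=(1e-4, 100.0))
        assert fit.scale == pytest.approx(1e-4, rel=0.01)

    def test_no_usable_columns_error(self, tree6):
        with pytest.raises(ValueError, match="usable"):
            fit_background_model(np.full((6, 0), -1, dtype=np.int8), tree6)


class TestPerfectConservation:
    def test_star_tree_zero_lengths(self):
        model = PhyloModel(tree=parse_newick("(A:0,B:0,C:0);"), kind="JC")
        res = prob_perfect_conservation(model, 10)
        assert res["q_identity"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_jc_pair_closed_form(self):
        model = PhyloModel(tree=parse_newick("(A:0.375,B:0.375);"), kind="JC")
        res = prob_perfect_conservation(model, 1)
        assert res["q_identity"] == pytest.approx(0.25 * (1 + 3 * np.exp(-1)),
                                                  abs=1e-12)

    def test_zero_event_below_identity_on_random_models(self, rng):
        for _ in range(25):
            b = rng.uniform(0.01, 0.6, 6)
            tree = parse_newick("((A:%f,B:%f):%f,(C:%f,D:%f):%f);" % tuple(b))
            model = PhyloModel(tree=tree, kind="HKY", kappa=rng.uniform(1, 5),
                               pi=rng.dirichlet([5] * 4))
            res = prob_perfect_conservation(model, 1)
            assert res["q_zero_event"] <= res["q_identity"] + 1e-12

    def test_monotone_in_branch_length_and_L(self):
        qs = []
        for d in (0.1, 0.5, 1.0, 2.0):
            model = PhyloModel(tree=parse_newick(f"(A:{d},B:{d});"), kind="JC")
            qs.append(prob_perfect_conservation(model, 1)["q_identity"])
        assert all(a > b for a, b in zip(qs, qs[1:]))
        model = PhyloModel(tree=parse_newick("(A:0.2,B:0.2);"), kind="JC")
        ps = [prob_perfect_conservation(model, L)["p_value"] for L in (1, 10, 80)]
        assert ps[0] > ps[1] > ps[2]

    def test_length_80_bound(self):
        """q < 0.866 per column forces p below 1e-5 at L = 80."""
        assert 0.866**80 == pytest.approx(1e-5, rel=0.15)
        model = simulate.default_model()
        res = prob_perfect_conservation(model, 80)
        assert res["q_identity"] < 0.866
        assert res["p_value"] < 1e-5


class TestDecelerationLrt:
    def test_perfect_element_hits_bound(self, jc6):
        cols = np.zeros((6, 192), dtype=np.int8)
        res = deceleration_lrt(cols, jc6, "perfect")
        assert res.lambda_hat == pytest.approx(1e-6, rel=0.1)
        assert res.lrt_p < 1e-5
        assert res.lrt_stat >= 0

    def test_single_column_finite(self, jc6):
        cols = np.zeros((6, 1), dtype=np.int8)
        res = deceleration_lrt(cols, jc6)
        assert np.isfinite(res.lrt_stat) and res.lrt_stat >= 0

    def test_null_pvalues_conservative(self, jc6):
        """Under the null the boundary-mixture p-values are stochastically
        at least uniform: low rejection rate, lambda_hat concentrated near 1."""
        lams, ps = [], []
        for rep in range(200):
            cfg = simulate.SimulationConfig(seed=10_000 + rep, model=jc6,
                                            genome_length=60, ref_species="A")
            blocks, _ = simulate.simulate_alignment(cfg)
            cols = _sample_columns(blocks, jc6.tree, 60, 0)
            res = deceleration_lrt(cols, jc6)
            lams.append(res.lambda_hat)
            ps.append(res.lrt_p)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.10
        assert np.median(lams) > 0.8
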