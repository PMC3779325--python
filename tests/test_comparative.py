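"""ASR, depth discretization, Pagel, phylogenetic ANOVA, PGLS, Mann-Whitney."""

import numpy as np
import pytest
from scipy import stats

from bathyrad import parse_newick
from bathyrad.comparative import (
    DepthStateSet,
    _dependent_Q,
    _joint_loglik,
    _tree_cache,
    bm_asr,
    discretize_depth,
    mann_whitney_depth,
    mk_asr,
    mk_loglik,
    pagel_correlation_test,
    pgls_fit,
    phylo_anova,
    pooled_habitat,
)
from bathyrad.simulate import (
    ContinuousTraitSpec,
    DiscreteTraitSpec,
    constant_rate_config,
    simulate_branching_times,
    simulate_continuous_trait,
    simulate_discrete_trait,
    symmetric_binary_spec,
    tree_from_branching_times,
)

from oracles import enumeration_mk


FIVE_TIP = "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);"


class TestMkAsr:
    def test_two_tip_symmetric_root(self):
        tree = parse_newick("(A:1,B:1);")
        res = mk_asr(tree, {"A": 0, "B": 1})
        root_row = res.node_probs.iloc[0]
        assert root_row["p_0"] == pytest.approx(0.5, abs=1e-9)

    def test_single_state_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="2 observed states"):
            mk_asr(tree, {"A": 0, "B": 0})

    def test_marginals_match_enumeration(self):
        """Fixed-rate marginal probabilities and lnL equal brute-force
        enumeration over all internal-state assignments."""
        from bathyrad.comparative import _mk_pruning, _mk_marginals

        tree = parse_newick(FIVE_TIP)
        states = {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}
        Q = np.array([[-0.3, 0.3], [0.3, -0.3]])
        prior = np.array([0.5, 0.5])
        tips = {k: np.eye(2)[v] for k, v in states.items()}
        lnl, caches = _mk_pruning(tree, tips, Q, prior)
        marg = _mk_marginals(tree, caches, prior)
        want_lnl, want_marg = enumeration_mk(tree, states, Q)
        assert lnl == pytest.approx(want_lnl, abs=1e-8)
        for node, probs in want_marg.items():
            assert np.allclose(marg[node], probs, atol=1e-8)

    def test_probabilities_sum_to_one(self, yule_tree, rng):
        states = simulate_discrete_trait(yule_tree, symmetric_binary_spec(0.06), rng)
        if len(set(states.values())) < 2:
            states[next(iter(states))] = 1 - next(iter(states.values()))
        res = mk_asr(yule_tree, states)
        total = res.node_probs[["p_0", "p_1"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_multistate_ambiguous_tips(self):
        """Tips occupying several depth bins enter as ambiguity and pull the
        reconstruction toward their occupied states."""
        tree = parse_newick(FIVE_TIP)
        states = {"A": {1, 2}, "B": 1, "C": 2, "D": 2, "E": {2, 3}}
        res = mk_asr(tree, states)
        assert res.states == [1, 2, 3]
        # oracle works on 0-based indices; translate the category labels
        remap = {1: 0, 2: 1, 3: 2}
        idx_states = {
            k: {remap[s] for s in v} if isinstance(v, set) else remap[v]
            for k, v in states.items()
        }
        want_lnl, _ = enumeration_mk(tree, idx_states, res.Q, np.full(3, 1 / 3))
        assert res.lnl == pytest.approx(want_lnl, abs=1e-6)


class TestBmAsr:
    def test_star_tree_root_mean(self):
        star = parse_newick("(A:1,B:1,C:1);")
        res = bm_asr(star, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert res.root_value == pytest.approx(2.0, abs=1e-9)

    def test_sigma2_recovery(self, rng):
        bt = simulate_branching_times(constant_rate_config(85, 0.05, n_tips=62), rng)
        tree = tree_from_branching_times(bt, rng)
        est = []
        for _ in range(200):
            vals = simulate_continuous_trait(tree, ContinuousTraitSpec(0.1, 0.0), rng)
            est.append(bm_asr(tree, vals).sigma2)
        assert np.mean(est) == pytest.approx(0.1, rel=0.15)

    def test_root_mean_invariant_to_relabeling(self, rng):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        vals = {"A": 0.3, "B": 1.1, "C": -0.4, "D": 0.9}
        swapped = {"A": vals["C"], "B": vals["D"], "C": vals["A"], "D": vals["B"]}
        assert bm_asr(tree, vals).root_value == pytest.approx(
            bm_asr(tree, swapped).root_value, abs=1e-9
        )

    def test_log_input_requires_positive(self):
        star = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="positive"):
            bm_asr(star, {"A": 10.0, "B": -2.0, "C": 5.0}, log_input=True)


class TestDepthDiscretization:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (300, 1200, {1, 2, 3}),
            (700, 700, {2}),
            (0, 499, {1}),
            (0, 500, {1}),       # boundary maximum closes the bin below
            (500, 1500, {2, 3}),
            (4400, 4500, {9}),   # a 0-4500 m table spans nine states
        ],
    )
    def test_bins(self, lo, hi, expected):
        assert set(discretize_depth(lo, hi).bins) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            discretize_depth(-5, 100)

    def test_contiguity_enforced(self):
        with pytest.raises(AssertionError):
            DepthStateSet(bins=frozenset({1, 3}))


class TestPagel:
    def test_dependent_likelihood_matches_enumeration(self):
        """The 8-rate joint-chain likelihood agrees with brute force over the
        4-state chain on a 4-taxon tree."""
        tree = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        x = {"A": 0, "B": 1, "C": 1, "D": 0}
        y = {"A": 0, "B": 0, "C": 1, "D": 1}
        rates = np.array([0.02, 0.05, 0.01, 0.03, 0.04, 0.02, 0.06, 0.01])
        Q = _dependent_Q(rates)
        cache, labels = _tree_cache(tree)
        joint = np.array([2 * x[l] + y[l] for l in labels])
        got = _joint_loglik(cache, joint, Q)
        states = {l: 2 * x[l] + y[l] for l in labels}
        want, _ = enumeration_mk(tree, states, Q, np.full(4, 0.25))
        assert got == pytest.approx(want, abs=1e-6)

    def test_power_under_dependent_evolution(self, rng):
        """Traits simulated under a strongly dependent joint chain give a
        positive statistic and small Monte-Carlo p."""
        bt = simulate_branching_times(constant_rate_config(40, 0.09, n_tips=24), rng)
        tree = tree_from_branching_times(bt, rng)
        # y switches fast toward matching x, x evolves freely
        rates = np.array([0.03, 0.03, 0.03, 0.03, 0.005, 0.5, 0.5, 0.005])
        spec = DiscreteTraitSpec(Q=_dependent_Q(rates),
                                 root_probs=np.full(4, 0.25))
        hits = 0
        nrep = 6
        done = 0
        while done < nrep:
            joint = simulate_discrete_trait(tree, spec, rng)
            x = {k: v // 2 for k, v in joint.items()}
            y = {k: v % 2 for k, v in joint.items()}
            if len(set(x.values())) < 2 or len(set(y.values())) < 2:
                continue
            res = pagel_correlation_test(tree, x, y, restarts=1, sims=19,
                                         seed=rng)
            hits += (res.statistic["delta_logL"] > 0
                     and res.p_phylo <= 0.05)
            done += 1
        assert hits >= 4

    def test_constant_trait_rejected(self, yule_tree):
        tips = [l.taxon.label for l in yule_tree.leaf_node_iter()]
        x = {t: 0 for t in tips}
        y = {t: i % 2 for i, t in enumerate(tips)}
        with pytest.raises(ValueError, match="constant"):
            pagel_correlation_test(yule_tree, x, y)


class TestPhyloAnova:
    def test_star_tree_matches_parametric(self, rng):
        star = parse_newick("(" + ",".join(f"t{i}:1" for i in range(40)) + ");")
        y = {f"t{i}": float(rng.normal()) for i in range(40)}
        g = {f"t{i}": "a" if i < 20 else "b" for i in range(40)}
        res = phylo_anova(star, y, g, sims=5000, seed=rng)
        assert abs(res.p_phylo - res.p_value) < 0.02

    def test_power_with_group_shift(self, yule_tree, rng):
        tips = [l.taxon.label for l in yule_tree.leaf_node_iter()]
        g = {t: "a" if i % 2 else "b" for i, t in enumerate(tips)}
        hits = 0
        for _ in range(15):
            y = simulate_continuous_trait(yule_tree, ContinuousTraitSpec(0.02, 0.0), rng)
            y = {t: v + (3.0 if g[t] == "a" else 0.0) for t, v in y.items()}
            res = phylo_anova(yule_tree, y, g, sims=199, seed=rng)
            hits += res.p_phylo < 0.05
        assert hits >= 14

    def test_singleton_group_rejected(self, yule_tree, rng):
        tips = [l.taxon.label for l in yule_tree.leaf_node_iter()]
        y = {t: float(i) for i, t in enumerate(tips)}
        g = {t: "a" for t in tips}
        g[tips[0]] = "b"
        with pytest.raises(ValueError, match="singleton"):
            phylo_anova(yule_tree, y, g, sims=100, seed=rng)


class TestPgls:
    def test_star_tree_equals_ols(self, rng):
        import statsmodels.api as sm

        star = parse_newick("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        x = {f"t{i}": float(i) for i in range(12)}
        y = {f"t{i}": 2.0 * i + float(rng.normal(0, 0.3)) for i in range(12)}
        res = pgls_fit(star, y, x)
        ols = sm.OLS(
            np.array([y[f"t{i}"] for i in range(12)]),
            sm.add_constant(np.array([x[f"t{i}"] for i in range(12)])),
        ).fit()
        assert res.statistic["slope"] == pytest.approx(ols.params[1], abs=1e-8)
        assert res.statistic["t_slope"] == pytest.approx(ols.tvalues[1], abs=1e-8)
        assert res.df["resid"] == 10

    def test_slope_recovery_under_bm(self, yule_tree, rng):
        slopes = []
        for _ in range(100):
            x = simulate_continuous_trait(yule_tree, ContinuousTraitSpec(0.05, 0.0), rng)
            noise = simulate_continuous_trait(yule_tree, ContinuousTraitSpec(0.02, 0.0), rng)
            y = {t: 2.0 * x[t] + noise[t] for t in x}
            slopes.append(pgls_fit(yule_tree, y, x).statistic["slope"])
        assert np.mean(slopes) == pytest.approx(2.0, abs=0.1)

    def test_null_slope_size(self, yule_tree, rng):
        nrep, hits = 150, 0
        for _ in range(nrep):
            x = simulate_continuous_trait(yule_tree, ContinuousTraitSpec(0.05, 0.0), rng)
            y = simulate_continuous_trait(yule_tree, ContinuousTraitSpec(0.05, 0.0), rng)
            hits += pgls_fit(yule_tree, y, x).p_value <= 0.05
        lo, hi = stats.binom.interval(0.95, nrep, 0.05)
        assert lo <= hits <= hi

    def test_singular_design_rejected(self, yule_tree):
        tips = [l.taxon.label for l in yule_tree.leaf_node_iter()]
        x = {t: 1.0 for t in tips}
        y = {t: float(i) for i, t in enumerate(tips)}
        with pytest.raises(ValueError, match="singular"):
            pgls_fit(yule_tree, y, x)


class TestMannWhitney:
    def test_enumerated_small_sample(self):
        res = mann_whitney_depth([1, 2, 3], [4, 5, 6])
        assert res.statistic["U"] == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-9)

    def test_identical_groups(self):
        res = mann_whitney_depth([1.0, 2.0, 3.5], [1.5, 2.5, 3.0])
        assert res.p_value > 0.5

    def test_power_with_shift(self, rng):
        hits = 0
        for _ in range(40):
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)
            hits += mann_whitney_depth(a, b).p_value < 0.01
        assert hits >= 38

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_depth([], [1.0])


def test_pooled_habitat():
    import pandas as pd

    s = pd.Series(["vent", "seep", "organic-fall"], index=list("abc"))
    assert pooled_habitat(s).tolist() == ["vent+seep", "vent+seep", "organic-fall"]
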