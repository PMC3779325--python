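"""Statistical laws of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from bathyrad.phylo import branching_times, crown_age
from bathyrad.simulate import (
    ContinuousTraitSpec,
    DiscreteTraitSpec,
    RateInterval,
    SimConfig,
    constant_rate_config,
    mussel_preset,
    mussel_trait_table,
    simulate_bisse_tree,
    simulate_branching_times,
    simulate_continuous_trait,
    simulate_discrete_trait,
    simulate_tree,
    subsample_tips,
    symmetric_binary_spec,
    tree_from_branching_times,
    yule_conditioned_branching_times,
)
from bathyrad.bisse import BisseParams


class TestTreeSimulation:
    def test_zero_rate_gives_cherry(self, rng):
        tree = simulate_tree(constant_rate_config(40.0, 0.0), rng)
        assert sum(1 for _ in tree.leaf_node_iter()) == 2
        assert crown_age(tree) == pytest.approx(40.0, abs=1e-12)

    def test_yule_mean_tip_count(self, rng):
        # E[N] = 2 e^{lambda T} for a crown-conditioned pure birth process
        cfg = constant_rate_config(40.0, 0.05)
        tips = [
            sum(1 for _ in simulate_tree(cfg, rng).leaf_node_iter())
            for _ in range(1000)
        ]
        expected = 2 * np.exp(0.05 * 40)
        se = np.std(tips) / np.sqrt(len(tips))
        assert abs(np.mean(tips) - expected) < 3.5 * se

    def test_conditioning_is_exact(self, rng):
        bt = simulate_branching_times(
            constant_rate_config(85.0, 0.05, n_tips=62), rng
        )
        assert bt.crown == 85.0
        assert bt.n == 62

    def test_same_seed_reproducible(self):
        a = simulate_branching_times(mussel_preset(40), 7)
        b = simulate_branching_times(mussel_preset(40), 7)
        assert np.array_equal(a.ages, b.ages)

    def test_survival_one_mass_extinction_is_noop(self, rng):
        # identical dynamics: rho = 1 event cannot change the law
        plain = constant_rate_config(40.0, 0.07, mass_extinctions=[])
        noop = constant_rate_config(40.0, 0.07, mass_extinctions=[(20.0, 1.0)])
        tips_a = [
            sum(1 for _ in simulate_tree(plain, rng).leaf_node_iter())
            for _ in range(500)
        ]
        tips_b = [
            sum(1 for _ in simulate_tree(noop, rng).leaf_node_iter())
            for _ in range(500)
        ]
        assert stats.ks_2samp(tips_a, tips_b).pvalue > 0.01

    def test_exact_conditioned_sampler_matches_rejection(self, rng):
        """The iid-kernel sampler and brute-force forward rejection must give
        the same branching-time distribution."""
        exact = np.concatenate([
            yule_conditioned_branching_times(
                constant_rate_config(40.0, 0.05, n_tips=8), rng
            ).ages[1:]
            for _ in range(300)
        ])
        # a rho=1 event forces the forward-simulation path
        fwd_cfg = SimConfig(
            crown_age=40.0, schedule=[RateInterval(40.0, 0.0, 0.05)],
            n_tips=8, mass_extinctions=[(20.0, 1.0)],
        )
        fwd = np.concatenate([
            simulate_branching_times(fwd_cfg, rng).ages[1:]
            for _ in range(300)
        ])
        assert stats.ks_2samp(exact, fwd).pvalue > 0.01

    def test_unattainable_conditioning(self, rng):
        with pytest.raises(ValueError):
            SimConfig(crown_age=10.0, schedule=[RateInterval(10, 0, 0.1)],
                      n_tips=1)

    def test_mussel_preset_burst_visible(self, rng):
        """The preset's LTT slope inside the 41-34 Ma window exceeds twice the
        slope outside it (on average over replicates)."""
        from bathyrad.diversification import _segment_stats

        ratios = []
        for _ in range(20):
            bt = simulate_branching_times(mussel_preset(62), rng)
            # log-LTT slope within a window = events / lineage-time there
            E, LT = _segment_stats(bt, np.array([41.2, 33.8]))
            ratios.append((E[1] / LT[1]) / (E[2] / LT[2]))
        assert np.median(ratios) > 2


class TestSubsampling:
    def test_identity_when_nothing_missing(self, yule_tree, rng):
        out = subsample_tips(yule_tree, 0.0, rng)
        assert sum(1 for _ in out.leaf_node_iter()) == 30

    def test_exact_retained_count(self, rng):
        bt = simulate_branching_times(constant_rate_config(60, 0.06, n_tips=100), rng)
        tree = tree_from_branching_times(bt, rng)
        out = subsample_tips(tree, 0.25, rng)
        assert sum(1 for _ in out.leaf_node_iter()) == 75
        branching_times(out)  # still ultrametric

    def test_uniformity_over_draws(self, rng):
        bt = simulate_branching_times(constant_rate_config(30, 0.1, n_tips=10), rng)
        tree = tree_from_branching_times(bt, rng)
        counts = {l.taxon.label: 0 for l in tree.leaf_node_iter()}
        ndraw = 1000
        for _ in range(ndraw):
            kept = subsample_tips(tree, 0.3, rng)
            for l in kept.leaf_node_iter():
                counts[l.taxon.label] += 1
        observed = np.array(list(counts.values()))
        expected = np.full(10, ndraw * 0.7)
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=9) > 0.001

    def test_too_few_tips(self, toy_tree, rng):
        with pytest.raises(ValueError):
            subsample_tips(toy_tree, 0.5, rng)


class TestTraitSimulation:
    def test_zero_rate_inherits_root(self, yule_tree, rng):
        spec = DiscreteTraitSpec(Q=np.zeros((2, 2)),
                                 root_probs=np.array([0.0, 1.0]))
        states = simulate_discrete_trait(yule_tree, spec, rng)
        assert set(states.values()) == {1}

    def test_fast_symmetric_chain_reaches_stationarity(self, yule_tree, rng):
        spec = symmetric_binary_spec(5.0)
        freqs = []
        for _ in range(60):
            states = simulate_discrete_trait(yule_tree, spec, rng)
            freqs.append(np.mean(list(states.values())))
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)

    def test_bm_degenerate_and_variance_law(self, yule_tree, rng):
        flat = simulate_continuous_trait(
            yule_tree, ContinuousTraitSpec(sigma2=0.0, root_value=3.0), rng
        )
        assert set(flat.values()) == {3.0}
        depth = crown_age(yule_tree)
        sims = np.array([
            list(simulate_continuous_trait(
                yule_tree, ContinuousTraitSpec(0.1, 0.0), rng).values())
            for _ in range(400)
        ])
        tip_var = sims.var(axis=0).mean()
        assert tip_var == pytest.approx(0.1 * depth, rel=0.15)

    def test_bm_covariance_law(self, rng):
        from bathyrad import parse_newick

        tree = parse_newick("((A:1,B:1):3,C:4);")  # A,B share 3 Myr of path
        sims = []
        for _ in range(3000):
            vals = simulate_continuous_trait(tree, ContinuousTraitSpec(0.5, 0.0), rng)
            sims.append([vals["A"], vals["B"]])
        sims = np.array(sims)
        cov = np.cov(sims.T)[0, 1]
        assert cov == pytest.approx(0.5 * 3, rel=0.15)

    def test_trait_table_schema(self, yule_tree, rng):
        from bathyrad.phylo import validate_traits

        df = mussel_trait_table(yule_tree, rng)
        validate_traits(df.drop(columns=["species"]).assign(species=df["species"]))
        assert len(df) == 30


class TestBisseSimulation:
    def test_state_independent_is_yule(self, rng):
        params = BisseParams(0.08, 0.08, q01=0.05, q10=0.05)
        freqs, bt_sim, bt_yule = [], [], []
        for _ in range(150):
            tree, states = simulate_bisse_tree(params, 30.0, rng)
            freqs.append(np.mean(list(states.values())))
            bt_sim.extend(branching_times(tree).ages[1:])
        for _ in range(150):
            bt_yule.extend(
                simulate_branching_times(
                    constant_rate_config(30.0, 0.08), rng
                ).ages[1:]
            )
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.07)
        assert stats.ks_2samp(bt_sim, bt_yule).pvalue > 0.01

    def test_no_extinction_keeps_all_lineages(self, rng):
        params = BisseParams(0.1, 0.15, mu0=0.0, mu1=0.0, q01=0.03, q10=0.03)
        tree, states = simulate_bisse_tree(params, 25.0, rng)
        bt = branching_times(tree)
        # every birth is observed: n - 1 branching events, all ages distinct
        assert bt.ages.size == len(states) - 1
        assert not bt.ties
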