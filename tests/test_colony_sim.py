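"""Agent-based colony simulator: growth, snapshots, pooled statistics, trees."""

import math

import numpy as np
import pytest

from burstpop import (
    BurstFeedbackParams,
    CycleModel,
    PartitionModel,
    Perspective,
    StationaryLaw,
    StopRule,
    colony_ensemble,
    estimate_growth_rate,
    export_lineage_newick,
    ks_distance,
    partitioning_endpoint_ensemble,
    population_stats,
    predicted_partition_cv2,
    simulate_colony,
    summary_stats,
)

LN2 = math.log(2.0)


def partition_setup(mean=20.0, beta=10.0, eps=1.0):
    params = BurstFeedbackParams(lam=LN2 * mean / beta, beta=beta, gamma=LN2, k=0.0)
    return params, PartitionModel(epsilon=eps)


class TestStopRule:
    def test_exactly_one_criterion(self):
        with pytest.raises(ValueError):
            StopRule()
        with pytest.raises(ValueError):
            StopRule(time=1.0, generations=2)
        with pytest.raises(ValueError):
            StopRule(generations=0)


class TestColonyBasics:
    def test_deterministic_timer_gives_exact_binary_tree(self):
        """6 generations with a deterministic timer: exactly 2^6 = 64 cells."""
        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=6),
            partition=part, seed=0, expression="deterministic", track_tree=True,
        )
        assert snap.cell_count == 64
        assert len(snap.concentrations) == 64
        assert not snap.truncated
        assert np.all(snap.concentrations >= 0)

    def test_perfect_partitioning_from_fixed_point_is_noiseless(self):
        params, _ = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=5),
            partition=PartitionModel(epsilon=0.0), seed=1, expression="deterministic",
        )
        stats = population_stats([snap], n_boot=0)
        assert stats.mean == pytest.approx(20.0, rel=1e-9)
        assert stats.cv2 == 0.0
        assert stats.skew == 0.0

    def test_max_cells_truncation_is_flagged(self):
        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=8),
            partition=part, seed=2, expression="deterministic", max_cells=32,
        )
        assert snap.truncated

    def test_empty_snapshot_list_rejected(self):
        with pytest.raises(ValueError):
            population_stats([])


class TestGrowthRate:
    def test_no_feedback_hazard_growth_equals_gamma(self):
        """k=0 hazard divisions: a standard branching process growing at gamma."""
        p = BurstFeedbackParams(lam=10.0, beta=10.0, gamma=1.0, k=0.0)
        law = StationaryLaw(p, Perspective.SINGLE_CELL)
        snaps = colony_ensemble(
            p, CycleModel(kind="hazard_feedback"), StopRule(time=6.0), 250,
            seed=3, track_tree=True, x0_sampler=law.sample_one,
        )
        est = estimate_growth_rate(snaps)
        assert est.rate == pytest.approx(1.0, rel=0.05)


class TestFeedbackColonies:
    def test_pooled_statistics_match_population_law(self, feedback_mean100):
        """Feedback at fixed mean 100: pooled colonies reproduce the population-law moments."""
        law_sc = StationaryLaw(feedback_mean100, Perspective.SINGLE_CELL)
        law_pop = StationaryLaw(feedback_mean100, Perspective.POPULATION)
        snaps = colony_ensemble(
            feedback_mean100, CycleModel(kind="hazard_feedback"), StopRule(time=10.0),
            400, seed=4, x0_sampler=law_sc.sample_one,
        )
        st = population_stats(snaps, seed=0)
        ref = law_pop.stats()
        assert st.mean == pytest.approx(ref.mean, abs=3 * st.se_mean)
        assert st.mean < 100.0
        assert st.cv2 == pytest.approx(ref.cv2, abs=3 * st.se_cv2)
        pooled = np.concatenate([s.concentrations for s in snaps])
        assert ks_distance(pooled, law_pop) < 0.05


class TestPartitioningColonies:
    def test_grand_mean_is_fixed_point(self):
        """Partition-noise colonies keep the mean at the deterministic fixed point."""
        params, part = partition_setup()
        snaps = colony_ensemble(
            params, CycleModel(kind="timer", cv2_tau=1.0), StopRule(generations=6),
            500, partition=part, seed=5, expression="deterministic",
        )
        st = population_stats(snaps, seed=0)
        assert st.mean == pytest.approx(20.0, abs=3 * st.se_mean)

    def test_population_noise_rises_with_cycle_noise(self):
        """Pooled CV^2 is non-decreasing in CVtau^2 while the single-cell CV^2 is flat."""
        params, part = partition_setup()
        cv2s = []
        for i, c in enumerate((0.0, 0.25, 1.0)):
            snaps = colony_ensemble(
                params, CycleModel(kind="timer", cv2_tau=c),
                StopRule(generations=6), 400, partition=part, seed=(6, i),
                expression="deterministic",
            )
            st = population_stats(snaps, seed=0)
            cv2s.append((st.cv2, st.se_cv2))
        assert cv2s[0][0] < cv2s[1][0] < cv2s[2][0]
        # exponential cycle times roughly double the single-cell noise
        pred_sc = predicted_partition_cv2(20.0, 1.0)
        assert cv2s[2][0] / pred_sc == pytest.approx(2.0, abs=0.2)

    def test_equal_noise_with_deterministic_timer(self):
        """Fixed cycle duration: both perspectives show the same noise."""
        params, part = partition_setup()
        snaps = colony_ensemble(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=6),
            800, partition=part, seed=7, expression="deterministic",
        )
        pop = population_stats(snaps, seed=0)
        ends = partitioning_endpoint_ensemble(
            params, part, CycleModel(kind="timer", cv2_tau=0.0), 4000,
            n_generations=6, seed=8,
        )
        sc = summary_stats(ends, n_boot=100, seed=0)
        diff = abs(pop.cv2 - sc.cv2)
        assert diff < 3.0 * math.hypot(pop.se_cv2, sc.se_cv2)

    def test_bursty_dominant_intrinsic_noise_equalizes_perspectives(self):
        """beta >> eps with bursty expression: population noise ~ single-cell noise."""
        params, part = partition_setup(beta=5.0)
        snaps = colony_ensemble(
            params, CycleModel(kind="timer", cv2_tau=1.0), StopRule(generations=6),
            300, partition=part, seed=9, expression="bursty",
        )
        pop = population_stats(snaps, seed=0)
        pred = predicted_partition_cv2(20.0, 1.0, 5.0)
        assert pop.cv2 == pytest.approx(pred, rel=0.15)


class TestEquivalenceConstantDilution:
    def test_xdep_bursts_constant_dilution_same_law_in_both_perspectives(self):
        """Concentration-dependent burst rate with constant dilution/division:
        the lineage and pooled-colony distributions coincide."""
        from scipy.stats import ks_2samp

        from burstpop import feedback_endpoint_ensemble

        p = BurstFeedbackParams(
            lam=3.0, beta=10.0, gamma=1.0, k=0.05,
            burst_mode="growth_coupled", dilution_mode="constant",
        )
        sc = feedback_endpoint_ensemble(p, 2500, t_end=25.0, seed=10, x0=0.0)
        snaps = colony_ensemble(
            p, CycleModel(kind="hazard_feedback"), StopRule(time=6.0), 600,
            seed=11, x0_sampler=lambda r: float(sc[r.integers(0, sc.size)]),
        )
        pooled = np.concatenate([s.concentrations for s in snaps])
        assert abs(sc.mean() - pooled.mean()) / sc.mean() < 0.1
        assert ks_2samp(sc, pooled).statistic < 0.05


class TestDivergenceRegime:
    def test_population_mean_plateaus_while_lineage_grows(self):
        """Population-only regime: the pooled mean stabilizes near the
        population-law value even though the lineage mean diverges."""
        from burstpop import feedback_endpoint_ensemble, moments

        p = BurstFeedbackParams(lam=1.2, beta=10.0, gamma=1.0, k=0.2)
        pop_th = moments(p, Perspective.POPULATION).mean  # = 60
        means = {}
        for i, T in enumerate((10.0, 20.0)):
            snaps = colony_ensemble(
                p, CycleModel(kind="hazard_feedback"), StopRule(time=T), 400,
                seed=(12, i),
            )
            means[T] = population_stats(snaps, seed=0)
        sc10 = feedback_endpoint_ensemble(p, 300, t_end=10.0, seed=13, x0=0.0).mean()
        sc20 = feedback_endpoint_ensemble(p, 300, t_end=20.0, seed=14, x0=0.0).mean()
        pop_growth = means[20.0].mean - means[10.0].mean
        assert pop_growth < (sc20 - sc10) / 2.0  # plateau vs steady growth
        assert means[20.0].mean == pytest.approx(
            pop_th, abs=max(3 * means[20.0].se_mean, 0.1 * pop_th)
        )


class TestAdder:
    def test_population_noise_grows_with_added_size_noise(self):
        """Adder size control: population CV^2 rises with added-size CV^2 and
        exceeds the (approximately flat) single-cell CV^2."""
        params, part = partition_setup()
        pop, sc = {}, {}
        for i, c in enumerate((0.02, 1.0, 2.0)):
            cyc = CycleModel(kind="adder", cv2_added=c, mean_added=1.0)
            snaps = colony_ensemble(
                params, cyc, StopRule(generations=6), 600, partition=part,
                seed=(15, i), expression="deterministic",
            )
            pop[c] = population_stats(snaps, seed=0)
            ends = partitioning_endpoint_ensemble(
                params, part, cyc, 1500, n_generations=12, seed=(16, i)
            )
            sc[c] = summary_stats(ends, n_boot=100, seed=0)
        assert pop[0.02].cv2 < pop[1.0].cv2 < pop[2.0].cv2
        for c in (1.0, 2.0):
            assert pop[c].cv2 > sc[c].cv2 + 2 * math.hypot(pop[c].se_cv2, sc[c].se_cv2)


class TestNewickExport:
    def test_single_leaf(self):
        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0, mean_tau=1.0),
            StopRule(time=1e-9), partition=part, seed=17,
            expression="deterministic", track_tree=True,
        )
        assert snap.cell_count == 1
        nwk = export_lineage_newick(snap)
        assert nwk == "c0:1e-09;"

    def test_one_division_cherry_roundtrip(self):
        import dendropy

        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=1),
            partition=part, seed=18, expression="deterministic", track_tree=True,
        )
        assert snap.cell_count == 2
        nwk = export_lineage_newick(snap)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        # daughters born together at the root division: equal ages
        ages = [lf.edge.length for lf in leaves]
        assert ages[0] == pytest.approx(ages[1], rel=1e-9)

    def test_roundtrip_leaf_count_matches_cell_count(self):
        import dendropy

        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=1.0), StopRule(generations=4),
            partition=part, seed=19, expression="deterministic", track_tree=True,
        )
        tree = dendropy.Tree.get(data=export_lineage_newick(snap), schema="newick")
        assert len(tree.leaf_nodes()) == snap.cell_count

    def test_missing_tree_errors(self):
        params, part = partition_setup()
        snap = simulate_colony(
            params, CycleModel(kind="timer", cv2_tau=0.0), StopRule(generations=2),
            partition=part, seed=20, expression="deterministic",
        )
        with pytest.raises(ValueError):
            export_lineage_newick(snap)
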