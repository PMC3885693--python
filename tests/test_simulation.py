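"""Synthetic-forest generator and AR(1)-on-tree Monte Carlo."""

import math

import numpy as np
import pytest
from scipy import stats

from rdsnet import (
    CategoricalTrait,
    SimulationConfig,
    build_forest,
    fit_negative_binomial,
    generate_dataset,
    generate_forest,
    measures_frame,
    mixture_transition,
    pair_correlation,
    pairs_at_distance,
    simulate_ar1_on_forest,
)
from rdsnet.forest import MAX_COUPONS
from rdsnet.simulation import ar1_values


def deep_forest(n_chains=50, depth=10, seed=1):
    """Chains of fixed depth: the sharpest topology for distance decay."""
    return generate_forest(
        SimulationConfig(n_seeds=n_chains, coupons=1, participation_prob=1.0,
                         max_waves=depth, rng_seed=seed)
    )


class TestGenerateForest:
    def test_zero_participation_yields_seeds_only(self):
        f = generate_forest(SimulationConfig(n_seeds=7, participation_prob=0.0,
                                             rng_seed=0))
        assert len(f) == 7
        assert f.max_wave() == 0

    def test_full_participation_two_waves_gives_21_nodes(self):
        f = generate_forest(
            SimulationConfig(n_seeds=1, coupons=4, participation_prob=1.0,
                             max_waves=2, rng_seed=0)
        )
        assert len(f) == 21  # 1 + 4 + 16

    def test_mean_tree_size_matches_branching_process(self):
        """E[nodes per tree] = sum_w (coupons * p)^w over allowed waves."""
        p, coupons, waves = 0.25, 4, 5
        m = coupons * p
        expected = sum(m**w for w in range(waves + 1))
        sizes = []
        for rep in range(500):
            f = generate_forest(
                SimulationConfig(n_seeds=1, coupons=coupons,
                                 participation_prob=p, max_waves=waves,
                                 rng_seed=rep)
            )
            sizes.append(len(f))
        mc_se = np.std(sizes, ddof=1) / math.sqrt(len(sizes))
        assert abs(np.mean(sizes) - expected) < 3 * mc_se

    def test_generated_forests_satisfy_invariants(self):
        for seed in range(5):
            f = generate_forest(SimulationConfig(n_seeds=10, rng_seed=seed))
            assert all(f.graph.out_degree(n) <= MAX_COUPONS for n in f.nodes)
            assert all(f.graph.in_degree(n) <= 1 for n in f.nodes)
            for n in f.nodes:
                parent = f.recruiter_of(n)
                if parent is not None:
                    assert f.wave[n] == f.wave[parent] + 1
                else:
                    assert f.wave[n] == 0

    def test_reproducible_under_fixed_seed(self):
        a = generate_forest(SimulationConfig(rng_seed=5))
        b = generate_forest(SimulationConfig(rng_seed=5))
        assert set(a.edges) == set(b.edges)


class TestAR1OnForest:
    def test_rho_zero_envelope_centred_at_zero(self):
        forest = deep_forest(n_chains=30, depth=6)
        res = simulate_ar1_on_forest(forest, 0.0, n_reps=400, rng_seed=2)
        row = res["summary"].set_index("distance").loc[1]
        assert row["lo95"] < 0 < row["hi95"]
        assert abs(row["mean"]) < 0.02

    def test_rho_one_gives_identical_components(self):
        forest = deep_forest(n_chains=10, depth=5)
        res = simulate_ar1_on_forest(forest, 1.0, n_reps=50, rng_seed=3)
        summary = res["summary"].set_index("distance")
        for d in summary.index:
            assert summary.loc[d, "median"] == pytest.approx(1.0, abs=1e-9)

    def test_geometric_decay_at_rho_half(self):
        """Mean distance-d correlation near 0.5**d on deep chains (2000 reps)."""
        forest = deep_forest(n_chains=50, depth=12)
        res = simulate_ar1_on_forest(forest, 0.5, n_reps=2000, rng_seed=4,
                                     max_d=5)
        summary = res["summary"].set_index("distance")
        for d in (1, 2, 3, 4):
            assert abs(summary.loc[d, "mean"] - 0.5**d) < 0.03, d

    def test_marginal_stays_standard_normal_at_depth(self):
        """Unit-variance preservation: a fixed node at depth 10, sampled
        across independent replicates, passes a Kolmogorov-Smirnov test
        against N(0, 1).  (Pooling values within one replicate would violate
        the KS independence assumption: chain members are correlated.)"""
        forest = deep_forest(n_chains=2, depth=10, seed=9)
        deepest = max(forest.wave, key=forest.wave.get)
        assert forest.wave[deepest] == 10
        rng = np.random.default_rng(10)
        draws = [ar1_values(forest, 0.8, rng)[deepest] for _ in range(600)]
        stat, p = stats.kstest(np.asarray(draws), "norm")
        assert p > 0.01

    def test_replicates_independent_of_evaluation_order(self):
        forest = deep_forest(n_chains=10, depth=4)
        a = simulate_ar1_on_forest(forest, 0.4, n_reps=30, rng_seed=6)
        b = simulate_ar1_on_forest(forest, 0.4, n_reps=30, rng_seed=6)
        for dist in a["correlations"]:
            np.testing.assert_allclose(
                a["correlations"][dist], b["correlations"][dist]
            )


class TestGenerateDataset:
    def test_null_config_gives_distance1_correlations_near_zero(self):
        cfg = SimulationConfig(
            rho=0.0,
            gender=CategoricalTrait(("female", "male"),
                                    mixture_transition([0.6, 0.4], 0.0)),
            n_seeds=200, rng_seed=13,
        )
        records = generate_dataset(cfg)
        forest = build_forest(records)
        df = measures_frame(records)
        res = pair_correlation(
            pairs_at_distance(forest, 1, "directed"), df["age"].to_dict()
        )
        assert res.ci_low < 0 < res.ci_high

    def test_distance1_age_correlation_recovers_rho(self):
        """Defaults emulate the observed age assortativity ~0.55; the
        pipeline estimate at distance 1 must recover the generating rho
        within Fisher-z Monte-Carlo tolerance."""
        cfg = SimulationConfig(n_seeds=400, rng_seed=21)
        records = generate_dataset(cfg)
        forest = build_forest(records)
        df = measures_frame(records)
        res = pair_correlation(
            pairs_at_distance(forest, 1, "directed"), df["age"].to_dict()
        )
        z_se = 1 / math.sqrt(res.n_pairs - 3)
        assert abs(math.atanh(res.estimate) - math.atanh(cfg.rho)) < 3 * z_se

    def test_degree_column_recovers_nb_parameters(self):
        cfg = SimulationConfig(n_seeds=1600, max_waves=4, rng_seed=8)
        records = generate_dataset(cfg)
        df = measures_frame(records)
        fit = fit_negative_binomial(df["degree"].to_numpy())
        assert abs(fit.mu - cfg.nb_mu) < 3 * fit.se_mu
        assert abs(fit.k - cfg.nb_k) < 3 * fit.se_k

    def test_incomplete_entrants_present_and_leaf_only(self, synthetic_cohort):
        records, forest = synthetic_cohort
        incomplete = [r for r in records if not r.completed]
        assert incomplete  # default noncomplete_prob > 0
        for r in incomplete:
            assert forest.graph.out_degree(r.pid) == 0
            assert r.travel_contacts == {}

    def test_dataset_deterministic_and_forest_valid(self):
        cfg = SimulationConfig(n_seeds=30, rng_seed=99)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert a == b
        build_forest(a)  # invariants enforced internally
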