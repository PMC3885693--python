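"""Pair enumeration by tree distance and correlation statistics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from rdsnet import (
    SimulationConfig,
    build_forest,
    generate_forest,
    linked_pair_report,
    pair_correlation,
    pairs_at_distance,
    distance_profile,
)
from rdsnet.assortativity import UndefinedCorrelationError
from rdsnet.simulation import ar1_values

from conftest import make_record, random_forest_records


def bfs_pairs_oracle(forest, d, lump=False):
    """All ordered within-component pairs at undirected tree distance d,
    computed with networkx shortest paths (independent of the package)."""
    und = nx.Graph(list(forest.graph.edges))
    und.add_nodes_from(forest.graph.nodes)
    out = set()
    lengths = dict(nx.all_pairs_shortest_path_length(und))
    for i, dmap in lengths.items():
        for j, dij in dmap.items():
            if i != j and (dij >= d if lump else dij == d):
                out.add((i, j))
    return out


def directed_pairs_oracle(forest, d):
    """Ancestor-descendant pairs exactly d directed steps apart."""
    g = forest.graph
    out = set()
    for i in g.nodes:
        for j in g.nodes:
            if i != j and nx.has_path(g, i, j):
                if nx.shortest_path_length(g, i, j) == d:
                    out.add((i, j))
    return out


class TestPairsAtDistance:
    def test_path_distance_two_symmetrized(self):
        recs = [make_record("a"), make_record("b", "a"), make_record("c", "b")]
        dp = pairs_at_distance(build_forest(recs), 2)
        assert set(dp.pairs) == {("a", "c"), ("c", "a")}

    def test_star_has_twelve_ordered_sibling_pairs(self, star_records):
        dp = pairs_at_distance(build_forest(star_records), 2)
        assert len(dp.pairs) == 12  # C(4,2) unordered pairs, both orientations

    def test_directed_mode_distance_one_is_recruiter_to_recruit(self, chain_records):
        forest = build_forest(chain_records)
        dp = pairs_at_distance(forest, 1, "directed")
        assert set(dp.pairs) == set(forest.graph.edges)

    def test_matches_bfs_oracle_on_100_random_forests(self):
        rng = np.random.default_rng(17)
        for rep in range(100):
            forest = build_forest(random_forest_records(rng, n=25))
            max_d = max(
                (d for dmap in dict(
                    nx.all_pairs_shortest_path_length(
                        nx.Graph(list(forest.graph.edges)))).values()
                 for d in dmap.values()), default=0)
            for d in range(1, max(2, max_d + 1)):
                got = set(pairs_at_distance(forest, d).pairs)
                assert got == bfs_pairs_oracle(forest, d), (rep, d)

    def test_directed_mode_matches_ancestor_oracle(self, rng):
        forest = build_forest(random_forest_records(rng, n=40))
        for d in (1, 2, 3):
            got = set(pairs_at_distance(forest, d, "directed").pairs)
            assert got == directed_pairs_oracle(forest, d)

    def test_lump_pools_the_tail(self, chain_records):
        forest = build_forest(chain_records)
        lumped = set(pairs_at_distance(forest, 4, lump=True).pairs)
        expected = bfs_pairs_oracle(forest, 4, lump=True)
        assert lumped == expected

    def test_union_over_distances_partitions_within_component_pairs(self, rng):
        forest = build_forest(random_forest_records(rng, n=50))
        seen = []
        for d in range(1, len(forest) + 1):
            seen.extend(pairs_at_distance(forest, d).pairs)
        assert len(seen) == len(set(seen))  # no pair at two distances
        expected = {
            (i, j)
            for i, j in itertools.permutations(forest.graph.nodes, 2)
            if forest.component_id[i] == forest.component_id[j]
        }
        assert set(seen) == expected


class TestPairCorrelation:
    def test_perfect_pair_agreement(self):
        recs = [make_record(f"s{i}") for i in range(5)]
        recs += [make_record(f"c{i}", f"s{i}") for i in range(5)]
        forest = build_forest(recs)
        values = {f"s{i}": float(i) for i in range(5)}
        values.update({f"c{i}": float(i) for i in range(5)})
        res = pair_correlation(pairs_at_distance(forest, 1, "directed"), values)
        assert res.estimate == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_phi_equals_pearson_on_indicator_coding(self, rng):
        forest = build_forest(random_forest_records(rng, n=60))
        values = {p: float(rng.integers(2)) for p in forest.nodes}
        dp = pairs_at_distance(forest, 1, "directed")
        phi = pair_correlation(dp, values, "phi")
        pearson = pair_correlation(dp, values, "pearson")
        assert phi.estimate == pytest.approx(pearson.estimate, abs=1e-12)

    def test_zero_variance_margin_is_undefined(self, star_records):
        forest = build_forest(star_records)
        with pytest.raises(UndefinedCorrelationError):
            pair_correlation(
                pairs_at_distance(forest, 1), {p: 1.0 for p in forest.nodes}
            )

    def test_missing_values_dropped_and_counted(self, chain_records):
        forest = build_forest(chain_records)
        values = {p: float(i) for i, p in enumerate(sorted(forest.nodes))}
        values["b"] = None
        res = pair_correlation(pairs_at_distance(forest, 1), values)
        assert res.n_dropped == 4  # b participates in 2 unordered pairs

    def test_symmetrized_estimate_invariant_under_orientation_swap(self, rng):
        forest = build_forest(random_forest_records(rng, n=40))
        values = {p: float(rng.normal()) for p in forest.nodes}
        dp = pairs_at_distance(forest, 1)
        swapped = type(dp)(
            distance=dp.distance,
            pairs=[(j, i) for i, j in dp.pairs],
            orientation_mode="symmetrized",
        )
        a = pair_correlation(dp, values).estimate
        b = pair_correlation(swapped, values).estimate
        assert a == pytest.approx(b, abs=1e-12)


class TestDistanceProfile:
    def test_constant_attribute_undefined_everywhere(self, chain_records):
        forest = build_forest(chain_records)
        profile = distance_profile(forest, {p: 2.0 for p in forest.nodes})
        assert all(math.isnan(r.estimate) for r in profile)

    def test_ar1_attributes_decay_like_rho_power_d(self):
        """AR(1) values on a deep forest: distance-d correlation near 0.5^d."""
        cfg = SimulationConfig(n_seeds=60, coupons=1, participation_prob=1.0,
                               max_waves=10, rng_seed=1)
        forest = generate_forest(cfg)
        rng = np.random.default_rng(12)
        estimates = {d: [] for d in (1, 2, 3)}
        for _ in range(40):
            values = ar1_values(forest, 0.5, rng)
            prof = distance_profile(forest, values, max_d=4)
            for r in prof:
                if r.distance in estimates and r.defined:
                    estimates[r.distance].append(r.estimate)
        for d in (1, 2, 3):
            mean = np.mean(estimates[d])
            assert abs(mean - 0.5**d) < 0.03, (d, mean)

    def test_ci_width_shrinks_with_pair_count(self):
        small = build_forest(
            [make_record("s")] + [make_record(f"c{i}", "s") for i in range(4)]
        )
        big_recs = [make_record(f"s{i}") for i in range(60)]
        big_recs += [make_record(f"c{i}", f"s{i}") for i in range(60)]
        big = build_forest(big_recs)
        rng = np.random.default_rng(3)
        v_small = {p: float(rng.normal()) for p in small.nodes}
        v_big = {p: float(rng.normal()) for p in big.nodes}
        r_small = pair_correlation(pairs_at_distance(small, 1), v_small)
        r_big = pair_correlation(pairs_at_distance(big, 1, "directed"), v_big)
        assert (r_big.ci_high - r_big.ci_low) < (r_small.ci_high - r_small.ci_low)


class TestLinkedPairReport:
    def test_null_generator_gives_estimates_near_zero(self):
        from rdsnet import generate_dataset
        from rdsnet.simulation import CategoricalTrait, mixture_transition

        cfg = SimulationConfig(
            rho=0.0,
            gender=CategoricalTrait(("female", "male"),
                                    mixture_transition([0.6, 0.4], 0.0)),
            education=CategoricalTrait(
                ("below_bachelor", "bachelor", "master_or_higher"),
                mixture_transition([0.2, 0.6, 0.2], 0.0)),
            n_seeds=150, rng_seed=77,
        )
        records = generate_dataset(cfg)
        forest = build_forest(records)
        report = linked_pair_report(records, forest)
        for _, row in report.iterrows():
            assert row["ci_low"] <= 0.0 <= row["ci_high"] or abs(row["estimate"]) < 0.1

    def test_household_filter_excludes_extreme_reporters(self, synthetic_cohort):
        records, forest = synthetic_cohort
        records = [r.copy() for r in records]
        records[5] = records[5].copy(household_size=600)
        filt = linked_pair_report(records, forest, household_filter_cap=500)
        keep = linked_pair_report(records, forest, household_filter_cap=None)
        row_f = filt[filt["attribute"] == "log_household"].iloc[0]
        row_k = keep[keep["attribute"] == "log_household"].iloc[0]
        assert row_f["n_pairs"] <= row_k["n_pairs"]
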