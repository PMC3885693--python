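"""Volz-Heckathorn estimation and sample-composition diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rdsnet import build_forest, composition_curves, vh_estimate

from conftest import make_record


def cohort(genders_degrees):
    """Seeds only; (gender, degree) per respondent, degree as bus contacts."""
    return [
        make_record(f"p{i:02d}", gender=g,
                    travel_contacts={"bus": d}, location_contacts={})
        for i, (g, d) in enumerate(genders_degrees)
    ]


class TestVHEstimate:
    def test_equal_degrees_reduce_to_raw_proportions(self):
        recs = cohort([("female", 10)] * 6 + [("male", 10)] * 4)
        est = vh_estimate(recs, "gender")
        assert est.vh_proportions == pytest.approx(est.raw_proportions)
        assert est.vh_proportions["female"] == pytest.approx(0.6)

    def test_two_individuals_forced_by_formula(self):
        recs = cohort([("A", 1), ("B", 3)])
        est = vh_estimate(recs, "gender")
        assert est.vh_proportions["A"] == pytest.approx(0.75)
        assert est.vh_proportions["B"] == pytest.approx(0.25)

    def test_proportions_and_weights_sum_to_one(self, synthetic_cohort):
        records, _ = synthetic_cohort
        est = vh_estimate(records, "education")
        assert sum(est.vh_proportions.values()) == pytest.approx(1.0)
        assert sum(est.weights.values()) == pytest.approx(1.0)
        assert all(w > 0 for w in est.weights.values())

    def test_invariant_to_degree_rescaling(self):
        recs = cohort([("A", 2), ("A", 8), ("B", 4), ("B", 16), ("B", 3)])
        base = vh_estimate(recs, "gender").vh_proportions
        scaled_recs = cohort(
            [("A", 10), ("A", 40), ("B", 20), ("B", 80), ("B", 15)]
        )
        scaled = vh_estimate(scaled_recs, "gender").vh_proportions
        assert scaled["A"] == pytest.approx(base["A"])

    def test_zero_degree_excluded_and_counted(self):
        recs = cohort([("A", 0), ("A", 5), ("B", 5)])
        est = vh_estimate(recs, "gender")
        assert est.excluded == 1
        assert est.n_used == 2

    def test_all_degrees_unusable_is_error(self):
        recs = cohort([("A", 0), ("B", 0)])
        with pytest.raises(ValueError, match="degrees"):
            vh_estimate(recs, "gender")

    def test_corrects_degree_biased_sampling(self):
        """Population 50/50 A/B but A has degree 2 and B degree 8; sampling
        proportional to degree over-represents B.  Across 100 replicates the
        VH estimate must sit closer to the true 0.5 than the raw share."""
        rng = np.random.default_rng(424)
        vh_err, raw_err = [], []
        pop_groups = np.array(["A"] * 500 + ["B"] * 500)
        pop_degrees = np.array([2.0] * 500 + [8.0] * 500)
        p_inclusion = pop_degrees / pop_degrees.sum()
        for _ in range(100):
            take = rng.choice(1000, size=120, replace=False,
                              p=p_inclusion)
            recs = cohort(
                [(pop_groups[i], int(pop_degrees[i])) for i in take]
            )
            est = vh_estimate(recs, "gender")
            vh_err.append(abs(est.vh_proportions.get("A", 0) - 0.5))
            raw_err.append(abs(est.raw_proportions.get("A", 0) - 0.5))
        assert np.mean(vh_err) < np.mean(raw_err)
        assert np.mean(vh_err) < 0.05

    @given(st.lists(st.tuples(st.sampled_from("AB"), st.integers(1, 60)),
                    min_size=4, max_size=20))
    def test_vh_sums_to_one_property(self, gd):
        if len({g for g, _ in gd}) < 1:
            return
        est = vh_estimate(cohort(gd), "gender")
        assert sum(est.vh_proportions.values()) == pytest.approx(1.0)


class TestCompositionCurves:
    def test_constant_attribute_flat_at_one(self, star_records):
        forest = build_forest(star_records)
        curves = composition_curves(star_records, forest, "gender")
        assert (curves["by_wave"]["p_female"] == 1.0).all()
        assert (curves["by_sample_size"]["raw_female"] == 1.0).all()

    def test_two_wave_cumulative_is_weighted_average(self):
        recs = [make_record("s1", gender="female"),
                make_record("s2", gender="male"),
                make_record("c1", "s1", gender="male"),
                make_record("c2", "s2", gender="male")]
        forest = build_forest(recs)
        curves = composition_curves(recs, forest, "gender")
        by_size = curves["by_sample_size"]
        assert by_size.iloc[-1]["raw_male"] == pytest.approx(0.75)

    def test_full_sample_cumulative_equals_overall_proportion(self, synthetic_cohort):
        records, forest = synthetic_cohort
        curves = composition_curves(records, forest, "gender")
        last = curves["by_sample_size"].iloc[-1]
        from rdsnet import measures_frame

        mf = measures_frame(records)
        overall = (mf["gender"] == "female").mean()
        assert last["raw_female"] == pytest.approx(overall, abs=1e-9)

    def test_wave_drifting_attribute_tracked_per_wave(self):
        """A trait set deterministically from the wave number must be
        reproduced exactly by the per-wave curve."""
        recs = [make_record("s")]
        parent = "s"
        for w in range(1, 5):
            pid = f"w{w}"
            recs.append(make_record(pid, parent, gender="female" if w % 2 else "male"))
            parent = pid
        forest = build_forest(recs)
        by_wave = composition_curves(recs, forest, "gender")["by_wave"]
        for _, row in by_wave.iterrows():
            w = int(row["wave"])
            if w == 0:
                assert row["p_female"] == 1.0
            else:
                expected = 1.0 if w % 2 else 0.0
                got = row.get("p_female", 0.0)
                got = 0.0 if got != got else got  # absent share = 0
                assert got == pytest.approx(expected)
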