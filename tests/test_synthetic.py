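"""Generator contracts: counts, reproducibility, marginals, planted effects."""

import numpy as np
import pytest

from remcal.synthetic import (
    BinaryFeature,
    CategoricalFeature,
    CohortSpec,
    ContinuousFeature,
    PlantedSubgroup,
    SpecError,
    TargetModel,
    biobank_like_spec,
    generate_cohort,
    separable_recovery_spec,
    split_cohort,
)


def tiny_spec(n=1000, seed=0, subgroups=()):
    return CohortSpec(
        n_records=n,
        features=(
            BinaryFeature("flag", prevalence=0.3),
            ContinuousFeature("x", mean=0.0, sd=1.0),
        ),
        target=TargetModel(intercept=5.0, coeffs={"x": 2.0}, residual_sd=1.0),
        subgroups=subgroups,
        seed=seed,
    )


class TestGenerateCohort:
    def test_exact_record_count_and_completeness(self):
        cohort, _ = generate_cohort(tiny_spec(n=1000))
        assert cohort.n_records == 1000
        assert not cohort.records.isna().any().any()

    def test_identical_seed_gives_byte_identical_tables(self):
        a, _ = generate_cohort(biobank_like_spec(n_records=500, seed=9))
        b, _ = generate_cohort(biobank_like_spec(n_records=500, seed=9))
        assert a.records.to_csv() == b.records.to_csv()

    def test_random_fraction_subgroup_within_binomial_bounds(self):
        sub = PlantedSubgroup("rand", fraction=0.1, mean_shift=1.0, sd_multiplier=1.0)
        _, truth = generate_cohort(tiny_spec(n=10_000, subgroups=(sub,)))
        count = truth.membership["rand"].sum()
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(count - 1000) <= 3 * sd

    def test_residual_spread_multiplier_is_realised(self):
        sub = PlantedSubgroup("noisy", fraction=0.3, mean_shift=0.0, sd_multiplier=3.0)
        cohort, truth = generate_cohort(tiny_spec(n=20_000, subgroups=(sub,)))
        resid = cohort.target_values - truth.linear_predictor
        m = truth.membership["noisy"].to_numpy()
        ratio = resid[m].std() / resid[~m].std()
        assert 2.7 <= ratio <= 3.3

    def test_binary_prevalences_within_binomial_bounds(self):
        cohort, _ = generate_cohort(biobank_like_spec(n_records=10_000, seed=5))
        for name, p in [("sex", 0.46), ("smoking", 0.35), ("asthma", 0.12)]:
            observed = cohort.records[name].mean()
            assert abs(observed - p) <= 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_planted_mean_shift_is_realised(self):
        sub = PlantedSubgroup("shift", fraction=0.5, mean_shift=4.0, sd_multiplier=1.0)
        cohort, truth = generate_cohort(tiny_spec(n=20_000, subgroups=(sub,)))
        m = truth.membership["shift"].to_numpy()
        y = cohort.target_values
        assert y[m].mean() - y[~m].mean() == pytest.approx(4.0, abs=0.1)

    def test_infeasible_rule_raises(self):
        sub = PlantedSubgroup("never", rule=(("flag", "==", 2),), sd_multiplier=1.0)
        with pytest.raises(SpecError, match="never"):
            generate_cohort(tiny_spec(n=100, subgroups=(sub,)))

    def test_default_preset_covers_the_variable_classes(self):
        spec = biobank_like_spec(n_records=10)
        names = set(spec.target_name for _ in [0]) | {f.name for f in spec.features}
        for required in (
            "sex",
            "age",
            "smoking",
            "ethnicity",
            "townsend",
            "haemoglobin",
            "bmi",
            "weight",
            "body_fat_pct",
            "high_blood_pressure",
            "diabetes",
        ):
            assert required in names
        assert spec.target_name == "hba1c"
        assert spec.target_units == "mmol/mol"
        # the diabetes diagnosis is recorded but withheld from prediction
        diabetes = next(f for f in spec.features if f.name == "diabetes")
        assert diabetes.role == "excluded_from_prediction"

    def test_recovery_preset_plants_a_noisier_cluster(self):
        cohort, truth = generate_cohort(separable_recovery_spec(n_records=5000, seed=1))
        m = truth.membership["marked"].to_numpy()
        resid = cohort.target_values - truth.linear_predictor
        assert resid[m].std() / resid[~m].std() > 2.0


class TestSpecValidation:
    def test_level_probabilities_must_sum_to_one(self):
        with pytest.raises(SpecError, match="sum"):
            CohortSpec(
                n_records=10,
                features=(
                    CategoricalFeature("c", probs={"a": 0.5, "b": 0.4}),
                    ContinuousFeature("x", 0, 1),
                ),
                target=TargetModel(0.0, {"x": 1.0}, 1.0),
            )

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(SpecError, match="multiplier"):
            PlantedSubgroup("s", fraction=0.1, sd_multiplier=0.5)

    def test_rule_and_fraction_are_mutually_exclusive(self):
        with pytest.raises(SpecError, match="exactly one"):
            PlantedSubgroup("s", rule=(("x", ">", 0),), fraction=0.1)

    def test_fractions_must_sum_below_one(self):
        subs = tuple(
            PlantedSubgroup(f"s{i}", fraction=0.5, sd_multiplier=1.0) for i in range(2)
        )
        with pytest.raises(SpecError, match="sum"):
            tiny_spec(subgroups=subs)


class TestSplitCohort:
    def test_sizes_and_disjoint_exhaustive(self):
        cohort, _ = generate_cohort(tiny_spec(n=100))
        tr, va = split_cohort(cohort, 0.75, seed=0)
        assert len(tr) == 75 and len(va) == 25
        assert set(tr).isdisjoint(va)
        assert sorted(np.concatenate([tr, va])) == list(range(100))

    def test_three_to_one_split_at_scale(self):
        cohort, _ = generate_cohort(tiny_spec(n=200_000))
        tr, va = split_cohort(cohort, 0.75, seed=1)
        assert len(tr) == 150_000 and len(va) == 50_000

    def test_same_seed_identical_split(self):
        cohort, _ = generate_cohort(tiny_spec(n=100))
        assert np.array_equal(
            split_cohort(cohort, 0.6, seed=4)[0], split_cohort(cohort, 0.6, seed=4)[0]
        )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_fraction_rejected(self, fraction):
        cohort, _ = generate_cohort(tiny_spec(n=10))
        with pytest.raises(ValueError):
            split_cohort(cohort, fraction, seed=0)
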