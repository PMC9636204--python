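"""Fidelity metrics, Gini index, permutation characterisation, FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remcal.calibration import (
    CalibrationConfig,
    analysis_variables,
    benjamini_hochberg,
    characterize_worst_groups,
    equity_summary,
    gini,
    group_calibration,
    nrmse,
    permutation_test,
    rmse,
    stratified_calibration,
)
from remcal.synthetic import (
    BinaryFeature,
    CohortSpec,
    ContinuousFeature,
    PlantedSubgroup,
    TargetModel,
    generate_cohort,
)


class TestRmseNrmse:
    def test_perfect_fit_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert nrmse(y, y) == 0.0

    def test_hand_computed_rmse(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))
        assert rmse([1, 2, 3], [1, 2, 6]) == pytest.approx(np.sqrt(3))

    def test_hand_computed_nrmse(self):
        # rmse=sqrt(8), denominator sqrt(25/2) -> 0.8
        assert nrmse([3, 4], [3, 0]) == pytest.approx(0.8)

    def test_zero_predictor_nrmse_is_exactly_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.normal(30, 10, size=50)
            assert nrmse(y, np.zeros_like(y)) == 1.0

    @given(
        c=st.floats(min_value=0.01, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nrmse_scale_free_but_origin_dependent(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(30, 5, 40)
        yhat = y + rng.normal(0, 2, 40)
        base = nrmse(y, yhat)
        assert nrmse(c * y, c * yhat) == pytest.approx(base, rel=1e-9)
        shifted = nrmse(y + 100.0, yhat + 100.0)
        assert shifted != pytest.approx(base, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            nrmse([0.0, 0.0], [1.0, 1.0])


class TestStratified:
    def test_constant_stratum_reproduces_overall(self):
        rng = np.random.default_rng(1)
        y = rng.normal(30, 5, 100)
        yhat = y + rng.normal(0, 2, 100)
        with pytest.warns(UserWarning, match="single level"):
            table = stratified_calibration(y, yhat, np.repeat("all", 100))
        assert len(table) == 1
        assert table["nrmse"].iloc[0] == pytest.approx(nrmse(y, yhat))

    def test_planted_noisier_stratum_scores_worse_in_9_of_10_seeds(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(
                n_records=4000,
                features=(
                    BinaryFeature("flag", prevalence=0.3),
                    ContinuousFeature("x", 0.0, 1.0),
                ),
                target=TargetModel(30.0, {"x": 2.0}, residual_sd=2.0),
                subgroups=(
                    PlantedSubgroup(
                        "noisy", rule=(("flag", "==", 1),), mean_shift=0.0, sd_multiplier=3.0
                    ),
                ),
                seed=seed,
            )
            cohort, truth = generate_cohort(spec)
            y = cohort.target_values
            yhat = truth.linear_predictor  # oracle conditional mean
            table = stratified_calibration(y, yhat, cohort.records["flag"].to_numpy())
            hits += table["nrmse"][1] > table["nrmse"][0]
        assert hits >= 9

    def test_identical_generating_processes_differ_only_by_noise(self):
        rng = np.random.default_rng(7)
        y = rng.normal(36, 5, 10_000)
        yhat = y + rng.normal(0, 3, 10_000)
        labels = np.repeat(["a", "b"], 5000)
        table = stratified_calibration(y, yhat, labels)
        assert abs(table["nrmse"]["a"] - table["nrmse"]["b"]) < 0.02


class TestGroupCalibration:
    def test_counts_partition_the_records(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 6, 500)
        y = rng.normal(30, 5, 500)
        table = group_calibration(y, y + rng.normal(0, 2, 500), labels)
        assert int(table.table["count"].sum()) == 500

    def test_identically_generated_groups_are_level(self):
        rng = np.random.default_rng(3)
        y = rng.normal(36, 5, 6000)
        yhat = y + rng.normal(0, 3, 6000)
        labels = np.repeat(np.arange(10), 600)
        table = group_calibration(y, yhat, labels)
        spread = table.table["nrmse"].max() - table.table["nrmse"].min()
        assert spread < 0.05

    def test_small_groups_are_flagged_not_dropped(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 490 + [1] * 10)
        y = rng.normal(30, 5, 500)
        table = group_calibration(y, y + rng.normal(0, 1, 500), labels)
        assert not table.table.loc[1, "included"]
        assert table.table.loc[1, "count"] == 10

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            group_calibration([], [], np.array([]))


class TestGini:
    def test_constant_vector_is_perfect_equality(self):
        assert gini([3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_values(self):
        assert gini([0.0, 1.0]) == pytest.approx(0.5)

    def test_uniform_draws_approach_one_third(self):
        v = np.random.default_rng(0).random(100_000)
        assert gini(v) == pytest.approx(1 / 3, abs=0.005)

    def test_pairwise_oracle_matches_lorenz_sort(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            v = rng.random(int(rng.integers(2, 40))) * rng.uniform(0.1, 100)
            assert gini(v, method="pairwise") == pytest.approx(
                gini(v, method="sort"), abs=1e-10
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            gini([])
        with pytest.raises(ValueError):
            gini([-1.0, 2.0])
        with pytest.raises(ValueError):
            gini([0.0, 0.0])

    def test_equity_summary_over_group_fidelities(self):
        rng = np.random.default_rng(5)
        y = rng.normal(36, 5, 3000)
        yhat = y + rng.normal(0, 3, 3000)
        labels = np.repeat(np.arange(6), 500)
        table = group_calibration(y, yhat, labels)
        eq = equity_summary(table)
        assert 0 <= eq.gini_coefficient < 1
        assert eq.n_groups == 6
        assert eq.group_nrmse_min <= eq.group_nrmse_median <= eq.group_nrmse_max
        weighted = equity_summary(table, weighted=True)
        assert 0 <= weighted.gini_coefficient < 1


class TestPermutation:
    def test_strong_separation_saturates_at_the_floor(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(3, 1, 500), rng.normal(0, 1, 5000)])
        mask = np.zeros(5500, dtype=bool)
        mask[:500] = True
        result = permutation_test(v, mask, B=1000, seed=0)
        assert result.p_value == pytest.approx(1 / 1001)
        assert f"{result.p_value:.4f}" == "0.0010"

    def test_p_values_are_multiples_of_the_grid(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            v = rng.normal(0, 1, 200)
            mask = np.zeros(200, dtype=bool)
            mask[:50] = True
            p = permutation_test(v, mask, B=99, seed=seed).p_value
            assert (p * 100) == pytest.approx(round(p * 100))
            assert 1 / 100 <= p <= 1.0

    def test_constant_variable_gives_p_one(self):
        mask = np.zeros(100, dtype=bool)
        mask[:20] = True
        assert permutation_test(np.ones(100), mask, B=50, seed=0).p_value == 1.0

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones(10), np.zeros(10, dtype=bool), B=10)


class TestBenjaminiHochberg:
    def test_hand_worked_step_up_example(self):
        rejected = benjamini_hochberg([0.001, 0.02, 0.04, 0.2], alpha=0.05)
        assert list(rejected) == [True, True, False, False]

    def test_all_ones_rejects_nothing(self):
        assert not benjamini_hochberg([1.0, 1.0, 1.0]).any()

    def test_single_p_at_alpha_is_rejected(self):
        assert benjamini_hochberg([0.05], alpha=0.05)[0]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])


class TestCharacterisation:
    def test_emits_top_n_groups_times_n_variables_tests(self, default_study):
        s = default_study
        tr = s.train_idx
        table = group_calibration(s.prep.y_raw[tr], s.yhat_raw[tr], s.labels[tr])
        cfg = CalibrationConfig(B=200, top_n_groups=5)
        sub = s.cohort.records.iloc[tr].reset_index(drop=True)
        from remcal.cohort import Cohort

        subcohort = Cohort(records=sub, schema=s.cohort.schema)
        result = characterize_worst_groups(subcohort, table, s.labels[tr], cfg, seed=5)
        n_vars = analysis_variables(subcohort).shape[1]
        assert len(result) == 5 * n_vars
        assert set(result.columns) >= {"group", "variable", "statistic", "p_value", "bh_rejected"}

    def test_constant_variable_never_significant(self):
        rng = np.random.default_rng(8)
        n = 600
        y = rng.normal(36, 5, n)
        yhat = y + rng.normal(0, 3, n) * np.where(np.arange(n) < 200, 3.0, 1.0)
        labels = np.repeat(np.arange(3), 200)
        table = group_calibration(y, yhat, labels)
        variables = pd.DataFrame(
            {"informative": rng.normal(size=n), "constant": np.ones(n)}
        )
        result = characterize_worst_groups(
            cohort=_dummy_cohort(n),
            table=table,
            assignment=labels,
            config=CalibrationConfig(B=100, top_n_groups=1, worst_percentile=40),
            seed=2,
            variables=variables,
        )
        const_rows = result[result["variable"] == "constant"]
        assert (const_rows["p_value"] == 1.0).all()
        assert not const_rows["bh_rejected"].any()


def _dummy_cohort(n):
    from remcal.cohort import Cohort, FeatureField, FeatureSchema

    schema = FeatureSchema(
        (FeatureField("x", "continuous"), FeatureField("y", "continuous", role="target"))
    )
    rng = np.random.default_rng(0)
    return Cohort(
        records=pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)}),
        schema=schema,
    )
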