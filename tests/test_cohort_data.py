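"""Schema validation, complete-case loading, and normalisation."""

import numpy as np
import pandas as pd
import pytest

from remcal.cohort import (
    Cohort,
    DegenerateFeatureError,
    EmptyCohortError,
    FeatureField,
    FeatureSchema,
    SchemaError,
    load_cohort,
    mean_split,
    preprocess,
)


@pytest.fixture()
def schema():
    return FeatureSchema(
        (
            FeatureField("x", "continuous"),
            FeatureField("flag", "binary"),
            FeatureField("colour", "categorical", levels=("A", "B")),
            FeatureField("y", "continuous", role="target", units="mmol/mol"),
        )
    )


def _write(tmp_path, text):
    p = tmp_path / "cohort.csv"
    p.write_text(text)
    return str(p)


class TestSchema:
    def test_exactly_one_continuous_target_enforced(self):
        with pytest.raises(SchemaError, match="exactly one target"):
            FeatureSchema((FeatureField("x", "continuous"),))
        with pytest.raises(SchemaError, match="continuous"):
            FeatureSchema((FeatureField("y", "binary", role="target"),))

    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError, match="unique"):
            FeatureSchema(
                (
                    FeatureField("x", "continuous"),
                    FeatureField("x", "binary"),
                    FeatureField("y", "continuous", role="target"),
                )
            )

    def test_categorical_requires_levels(self):
        with pytest.raises(SchemaError, match="levels"):
            FeatureField("c", "categorical")

    def test_from_dict_round_trip(self, schema):
        spec = {
            "features": [
                {"name": "x", "kind": "continuous"},
                {"name": "flag", "kind": "binary"},
                {"name": "colour", "kind": "categorical", "levels": ["A", "B"]},
                {"name": "y", "kind": "continuous", "role": "target", "units": "mmol/mol"},
            ]
        }
        assert FeatureSchema.from_dict(spec) == schema


class TestLoadCohort:
    def test_all_values_present_loads_identically(self, tmp_path, schema):
        path = _write(tmp_path, "x,flag,colour,y\n1,0,A,10\n2,1,B,11\n3,0,A,12\n4,1,B,13\n5,0,A,14\n")
        cohort = load_cohort(path, schema)
        assert cohort.n_records == 5
        assert list(cohort.records["x"]) == [1, 2, 3, 4, 5]

    def test_rows_with_missing_values_are_dropped(self, tmp_path, schema):
        path = _write(tmp_path, "x,flag,colour,y\n1,0,A,10\n2,1,B,11\n3,,A,12\n4,1,B,13\n5,0,A,14\n")
        cohort = load_cohort(path, schema)
        assert cohort.n_records == 4
        assert 3 not in set(cohort.records["x"])  # survivor order preserved
        assert list(cohort.records["x"]) == [1, 2, 4, 5]

    def test_missing_target_column_is_schema_mismatch(self, tmp_path, schema):
        path = _write(tmp_path, "x,flag,colour\n1,0,A\n")
        with pytest.raises(SchemaError, match="y"):
            load_cohort(path, schema)

    def test_all_rows_incomplete_raises_empty_cohort(self, tmp_path, schema):
        path = _write(tmp_path, "x,flag,colour,y\n1,0,A,\n2,1,B,\n")
        with pytest.raises(EmptyCohortError):
            load_cohort(path, schema)

    def test_optional_target_bounds_filter(self, tmp_path, schema):
        path = _write(tmp_path, "x,flag,colour,y\n1,0,A,10\n2,1,B,900\n3,0,A,12\n")
        cohort = load_cohort(path, schema, target_bounds=(0, 100))
        assert cohort.n_records == 2

    def test_undeclared_categorical_level_rejected(self, schema):
        df = pd.DataFrame({"x": [1.0], "flag": [0], "colour": ["Z"], "y": [1.0]})
        with pytest.raises(SchemaError, match="Z"):
            Cohort(records=df, schema=schema)


class TestPreprocess:
    def _cohort(self, schema, x, flag=None, colour=None, y=None):
        n = len(x)
        df = pd.DataFrame(
            {
                "x": x,
                "flag": flag if flag is not None else [0] * n,
                "colour": colour if colour is not None else ["A"] * n,
                "y": y if y is not None else np.linspace(10, 20, n),
            }
        )
        return Cohort(records=df, schema=schema)

    def test_population_form_z_scores(self, schema):
        prep = preprocess(self._cohort(schema, [1.0, 2.0, 3.0]), [0, 1, 2])
        col = prep.X[:, prep.columns.index("x")]
        assert col == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_one_hot_indicators_sum_to_one_per_row(self, schema):
        prep = preprocess(
            self._cohort(schema, [1.0, 2.0, 3.0], colour=["A", "B", "A"]), [0, 1, 2]
        )
        ind = prep.X[:, [prep.columns.index("colour=A"), prep.columns.index("colour=B")]]
        assert np.all(ind.sum(axis=1) == 1.0)
        assert prep.expansion["colour"] == {"A": "colour=A", "B": "colour=B"}

    def test_binary_passes_through_as_0_1(self, schema):
        prep = preprocess(self._cohort(schema, [1.0, 2.0], flag=[0, 1]), [0, 1])
        assert set(prep.X[:, prep.columns.index("flag")]) == {0.0, 1.0}

    def test_zero_spread_feature_is_degenerate(self, schema):
        with pytest.raises(DegenerateFeatureError, match="x"):
            preprocess(self._cohort(schema, [2.0, 2.0, 2.0]), [0, 1, 2])

    def test_target_round_trip_exact(self, schema):
        y = [10.0, 14.5, 13.25, 99.0]
        prep = preprocess(self._cohort(schema, [1.0, 2.0, 3.0, 4.0], y=y), [0, 1, 2, 3])
        assert prep.denormalise_target(prep.y_norm) == pytest.approx(y, rel=1e-10)

    def test_statistics_come_from_fitting_split_only(self, schema):
        # split B is shifted by +10: its z-scores under A's statistics are not centred
        x = [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]
        prep = preprocess(self._cohort(schema, x), [0, 1, 2])
        col = prep.X[:, prep.columns.index("x")]
        assert np.mean(col[:3]) == pytest.approx(0.0, abs=1e-12)
        assert np.mean(col[3:]) > 5  # uses A's mean/spread, not its own

    def test_preprocess_is_deterministic(self, schema):
        c = self._cohort(schema, [1.0, 5.0, 2.0], colour=["B", "A", "B"])
        a = preprocess(c, [0, 1, 2])
        b = preprocess(c, [0, 1, 2])
        assert np.array_equal(a.X, b.X)
        assert a.stats == b.stats

    def test_mean_split_binarisation(self, schema):
        cohort = self._cohort(schema, [-2.0, 0.0, 2.0, 4.0])  # mean 1
        labels = mean_split(cohort, "x", [0, 1, 2, 3])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_mean_split_refuses_non_continuous(self, schema):
        with pytest.raises(SchemaError):
            mean_split(self._cohort(schema, [1.0, 2.0]), "flag", [0, 1])
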