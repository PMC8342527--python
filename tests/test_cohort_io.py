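"""Cohort table parsing, round trips, pairing and edge-list serialization."""

import numpy as np
import pandas as pd
import pytest

from checkupnet import (
    CohortTable,
    VariableDescriptor,
    align_longitudinal_pairs,
    load_schema,
    read_cohort_table,
    read_edge_list,
    save_schema,
    write_cohort_table,
    write_edge_list,
)


def write_csv(tmp_path, text, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestDescriptors:
    def test_categorical_needs_levels(self):
        with pytest.raises(ValueError, match="levels"):
            VariableDescriptor("x", "ordinal")

    def test_binary_needs_exactly_two(self):
        with pytest.raises(ValueError, match="exactly 2"):
            VariableDescriptor("x", "binary", ordinal_levels=("a", "b", "c"))

    def test_numeric_map_keys_must_be_levels(self):
        with pytest.raises(ValueError, match="undeclared"):
            VariableDescriptor(
                "x", "ordinal", ordinal_levels=("a", "b"), numeric_map={"z": 1.0}
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            VariableDescriptor("x", "fancy")


class TestReadCohortTable:
    def test_direct_parse(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,age\ns1,40\ns2,55\ns3,62\n")
        table = read_cohort_table(path, (VariableDescriptor("age", "continuous"),))
        assert table.subject_ids == ("s1", "s2", "s3")
        assert table.missing_mask().to_numpy().sum() == 0
        assert table.data.loc["s2", "age"] == 55.0

    def test_missing_token_flags_cell_keeps_row(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,age\ns1,40\ns2,NA\n")
        table = read_cohort_table(path, (VariableDescriptor("age", "continuous"),))
        assert table.subject_ids == ("s1", "s2")
        assert np.isnan(table.data.loc["s2", "age"])

    def test_unparseable_continuous_becomes_missing(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,age\ns1,forty\ns2,55\n")
        table = read_cohort_table(path, (VariableDescriptor("age", "continuous"),))
        assert np.isnan(table.data.loc["s1", "age"])

    def test_duplicate_subject_id_names_the_id(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,age\ns1,40\ns1,41\ns2,50\n")
        with pytest.raises(ValueError, match="s1"):
            read_cohort_table(path, (VariableDescriptor("age", "continuous"),))

    def test_schema_column_absent_is_hard_error(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,age\ns1,40\ns2,50\n")
        with pytest.raises(ValueError, match="height"):
            read_cohort_table(path, (VariableDescriptor("height", "continuous"),))

    def test_undeclared_level_names_row_and_column(self, tmp_path):
        path = write_csv(tmp_path, "subject_id,sex\ns1,male\ns2,robot\n")
        schema = (VariableDescriptor("sex", "binary", ordinal_levels=("female", "male")),)
        with pytest.raises(ValueError) as err:
            read_cohort_table(path, schema)
        assert "robot" in str(err.value)
        assert "sex" in str(err.value)
        assert "s2" in str(err.value)


class TestRoundTrip:
    def test_write_read_write_is_byte_stable(self, small_table, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_table(small_table, p1)
        again = read_cohort_table(p1, small_table.variables, timepoint="2018")
        write_cohort_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_values_survive_round_trip(self, small_table, tmp_path):
        path = tmp_path / "t.csv"
        write_cohort_table(small_table, path)
        again = read_cohort_table(path, small_table.variables, timepoint="2018")
        pd.testing.assert_frame_equal(again.data, small_table.data, check_exact=False)

    def test_schema_yaml_round_trip(self, basic_schema, tmp_path):
        path = tmp_path / "schema.yaml"
        extended = basic_schema + (
            VariableDescriptor(
                "dose",
                "ordinal",
                units="g/day",
                ordinal_levels=("low", "high"),
                numeric_map={"low": 10.0, "high": 30.0},
            ),
        )
        save_schema(extended, path)
        assert load_schema(path) == extended


class TestAlignLongitudinalPairs:
    def make(self, ids, age, timepoint):
        data = pd.DataFrame(
            {"age": age}, index=pd.Index(ids, name="subject_id")
        )
        return CohortTable(data, (VariableDescriptor("age", "continuous"),), timepoint)

    def test_plain_intersection(self):
        base = self.make(["a", "b", "c"], [1.0, 2.0, 3.0], "2013")
        fol = self.make(["b", "c", "d"], [2.0, 3.0, 4.0], "2018")
        paired = align_longitudinal_pairs(base, fol)
        assert paired.paired_ids == ("b", "c")
        assert paired.exclusions == {
            "baseline_only": 1, "followup_only": 1, "missing_required": 0,
        }

    def test_required_variable_filters_and_counts(self):
        base = self.make(["a", "b", "c"], [1.0, np.nan, 3.0], "2013")
        fol = self.make(["a", "b", "c"], [1.5, 2.5, np.nan], "2018")
        paired = align_longitudinal_pairs(base, fol, ["age"])
        assert paired.paired_ids == ("a",)
        assert paired.exclusions["missing_required"] == 2

    def test_study_flow_counts(self):
        # 1848 subjects at both timepoints, 83 missing a spirometry value
        n = 1848
        ids = [f"s{i}" for i in range(n)]
        age = [50.0] * n
        fvc = [3.5] * n
        for i in range(83):
            fvc[i] = np.nan
        schema = (
            VariableDescriptor("age", "continuous"),
            VariableDescriptor("FVC", "continuous"),
        )
        base = CohortTable(
            pd.DataFrame({"age": age, "FVC": fvc}, index=pd.Index(ids, name="subject_id")),
            schema, "2013",
        )
        fol = CohortTable(
            pd.DataFrame({"age": age, "FVC": [3.4] * n}, index=pd.Index(ids, name="subject_id")),
            schema, "2018",
        )
        paired = align_longitudinal_pairs(base, fol, ["FVC"])
        assert paired.n == 1765
        assert paired.exclusions["missing_required"] == 83

    def test_exclusion_counts_are_conserved(self):
        base = self.make(["a", "b", "c", "e"], [1.0, np.nan, 3.0, 4.0], "2013")
        fol = self.make(["b", "c", "d", "e"], [2.0, 3.0, 4.0, np.nan], "2018")
        paired = align_longitudinal_pairs(base, fol, ["age"])
        n_inter = len({"b", "c", "e"})
        assert paired.n == n_inter - paired.exclusions["missing_required"]

    def test_empty_intersection_is_error(self):
        base = self.make(["a", "b"], [1.0, 2.0], "2013")
        fol = self.make(["c", "d"], [3.0, 4.0], "2018")
        with pytest.raises(ValueError, match="shared"):
            align_longitudinal_pairs(base, fol)

    def test_identical_timepoints_rejected(self):
        base = self.make(["a", "b"], [1.0, 2.0], "2013")
        fol = self.make(["a", "b"], [1.0, 2.0], "2013")
        with pytest.raises(ValueError, match="timepoint"):
            align_longitudinal_pairs(base, fol)


class TestEdgeLists:
    def test_empty_edge_set_writes_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list([], path)
        lines = path.read_text().splitlines()
        assert lines == ["var1\tvar2\tr\trank\tsignificant"]

    def test_equal_rank_breaks_ties_lexicographically(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list(
            [
                {"var1": "b", "var2": "c", "r": 0.5, "rank": 1, "significant": True},
                {"var1": "a", "var2": "d", "r": -0.5, "rank": 1, "significant": True},
            ],
            path,
        )
        df = read_edge_list(path)
        assert list(df["var1"]) == ["a", "b"]

    def test_round_trip_identity(self, tmp_path):
        edges = pd.DataFrame(
            {
                "var1": ["a", "b"],
                "var2": ["b", "c"],
                "r": [0.351234, -0.25],
                "rank": [1, 2],
                "significant": [True, False],
            }
        )
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        write_edge_list(edges, p1)
        back = read_edge_list(p1)
        write_edge_list(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(back, edges)


def test_table_requires_two_subjects():
    data = pd.DataFrame({"age": [40.0]}, index=pd.Index(["a"], name="subject_id"))
    with pytest.raises(ValueError, match="2 subjects"):
        CohortTable(data, (VariableDescriptor("age", "continuous"),))
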