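"""Reading, recoding and inclusion rules for registry microdata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pretermpsw import registry_io as rio
from .conftest import make_raw, raw_frame


def write_raw(tmp_path, rows, name="births.csv", **to_csv_kwargs):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep=";", index=False, **to_csv_kwargs)
    return path


class TestReadBirths:
    def test_complete_rows_round_trip(self, tmp_path):
        rows = [make_raw(), make_raw(gestational_age=30), make_raw(year=2020)]
        res = rio.read_births(write_raw(tmp_path, rows))
        assert len(res.records) == 3
        assert res.report.n_coercion_failures == 0
        # ordering and values preserved
        assert res.records["gestational_age"].tolist() == [39, 30, 39]
        assert res.records["year"].tolist() == [2019, 2019, 2020]

    def test_declared_missing_code(self, tmp_path):
        rows = [make_raw(gestational_age=99), make_raw()]
        res = rio.read_births(
            write_raw(tmp_path, rows), missing_codes={"gestational_age": {"99"}}
        )
        assert pd.isna(res.records.loc[0, "gestational_age"])
        assert res.records.loc[1, "gestational_age"] == 39
        assert res.report.missing_replaced["gestational_age"] == 1
        assert res.report.n_coercion_failures == 0

    def test_unparseable_cell_counted_not_dropped(self, tmp_path):
        rows = [make_raw(birthweight="heavy"), make_raw()]
        res = rio.read_births(write_raw(tmp_path, rows))
        assert len(res.records) == 2
        assert pd.isna(res.records.loc[0, "birthweight"])
        assert res.report.coercion_failures == {"birthweight": 1}

    def test_missing_year_column_is_fatal_and_named(self, tmp_path):
        rows = [{k: v for k, v in make_raw().items() if k != "year"}]
        with pytest.raises(ValueError, match="year"):
            rio.read_births(write_raw(tmp_path, rows))

    def test_missing_file_is_fatal_and_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.csv"):
            rio.read_births(tmp_path / "nowhere.csv")

    def test_schema_mapping(self, tmp_path):
        rows = [dict(make_raw())]
        rows[0]["IDADEGEST"] = rows[0].pop("gestational_age")
        res = rio.read_births(
            write_raw(tmp_path, rows), schema={"gestational_age": "IDADEGEST"}
        )
        assert res.records.loc[0, "gestational_age"] == 39


class TestRecode:
    @pytest.mark.parametrize(
        "field,value,column,expected",
        [
            ("gestational_age", 36, "ga_cat", "preterm"),
            ("gestational_age", 22, "ga_cat", "preterm"),
            ("gestational_age", 37, "ga_cat", "term"),
            ("maternal_age", 18, "age_cat", "<19"),
            ("maternal_age", 19, "age_cat", "19-34"),
            ("maternal_age", 34, "age_cat", "19-34"),
            ("maternal_age", 35, "age_cat", ">34"),
            ("anc_visits", 0, "anc_cat", "none"),
            ("anc_visits", 1, "anc_cat", "1-3"),
            ("anc_visits", 3, "anc_cat", "1-3"),
            ("anc_visits", 4, "anc_cat", "4-6"),
            ("anc_visits", 6, "anc_cat", "4-6"),
            ("anc_visits", 7, "anc_cat", "7+"),
            ("anc_visits", 12, "anc_cat", "7+"),
            ("parity", 0, "parity_cat", "primiparous"),
            ("parity", 3, "parity_cat", "multiparous"),
            ("schooling_years", 7, "schooling_cat", "0-7"),
            ("schooling_years", 8, "schooling_cat", "8-11"),
            ("schooling_years", 12, "schooling_cat", "12+"),
            ("race", 5, "race_cat", "indigenous"),
            ("sex", 1, "sex_cat", "male"),
            ("pregnancy_type", 2, "pregnancy_cat", "twin"),
        ],
    )
    def test_band_membership(self, field, value, column, expected):
        rec = rio.recode(raw_frame([make_raw(**{field: value})]))
        assert rec.loc[0, column] == expected

    def test_preterm_sets_outcome(self):
        rec = rio.recode(raw_frame([make_raw(gestational_age=36)]))
        assert rec.loc[0, "y"] == 1 and rec.loc[0, "eligible"]

    def test_below_lower_bound_ineligible(self):
        rec = rio.recode(raw_frame([make_raw(gestational_age=21)]))
        assert not rec.loc[0, "eligible"]

    def test_unknown_gestational_age_kept_without_outcome(self):
        rec = rio.recode(raw_frame([make_raw(gestational_age=None)]))
        assert rec.loc[0, "ga_cat"] == "unknown"
        assert pd.isna(rec.loc[0, "y"])
        assert rec.loc[0, "eligible"]

    def test_configurable_preterm_threshold(self):
        rec = rio.recode(raw_frame([make_raw(gestational_age=37)]), preterm_upper=37)
        assert rec.loc[0, "ga_cat"] == "preterm"

    def test_unknown_raw_code_maps_to_unknown(self):
        rec = rio.recode(raw_frame([make_raw(race=None, delivery_mode=None)]))
        assert rec.loc[0, "race_cat"] == "unknown"
        assert rec.loc[0, "delivery_cat"] == "unknown"

    def test_state_code_maps_to_region(self):
        rec = rio.recode(raw_frame([make_raw(region="SP"), make_raw(region="North")]))
        assert rec["region"].tolist() == ["Southeast", "North"]


class TestFilterEligible:
    def test_inclusion_rule(self):
        rec = rio.recode(
            raw_frame([make_raw(gestational_age=g) for g in (21, 22, 40)])
        )
        kept = rio.filter_eligible(rec)
        assert kept["gestational_age"].tolist() == [22, 40]

    def test_empty_input(self):
        rec = rio.recode(raw_frame([make_raw()])).iloc[0:0]
        assert len(rio.filter_eligible(rec)) == 0

    def test_all_eligible_identity(self):
        rec = rio.recode(raw_frame([make_raw(), make_raw(gestational_age=30)]))
        pd.testing.assert_frame_equal(rio.filter_eligible(rec), rec)


@given(
    ga=st.one_of(st.none(), st.integers(min_value=0, max_value=50)),
    age=st.one_of(st.none(), st.integers(min_value=8, max_value=60)),
    race=st.one_of(st.none(), st.integers(min_value=0, max_value=9)),
    anc=st.one_of(st.none(), st.integers(min_value=0, max_value=40)),
    parity=st.one_of(st.none(), st.integers(min_value=0, max_value=15)),
    schooling=st.one_of(st.none(), st.integers(min_value=0, max_value=25)),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_recode_is_total(ga, age, race, anc, parity, schooling):
    """Every raw record lands in the closed category sets; the outcome bands
    partition eligible records."""
    rec = rio.recode(
        raw_frame(
            [
                make_raw(
                    gestational_age=ga,
                    maternal_age=age,
                    race=race,
                    anc_visits=anc,
                    parity=parity,
                    schooling_years=schooling,
                )
            ]
        )
    )
    row = rec.iloc[0]
    for col, levels in rio.CATEGORY_LEVELS.items():
        value = row[col]
        assert pd.isna(value) or value in levels
    if row["eligible"]:
        assert row["ga_cat"] in ("term", "preterm", "unknown")
        assert (row["ga_cat"] == "unknown") == pd.isna(row["y"])


def test_recoded_round_trip(tmp_path, confounded_recoded):
    """Writing and re-reading the interchange CSV preserves category labels."""
    sample = confounded_recoded.head(200).reset_index(drop=True)
    path = tmp_path / "recoded.csv"
    rio.write_recoded(sample, path)
    back = rio.read_recoded(path)
    for col in rio.CATEGORY_COLUMNS:
        assert back[col].astype(object).where(back[col].notna(), None).tolist() == \
            sample[col].astype(object).where(sample[col].notna(), None).tolist()


def test_recode_report_counts(confounded_recoded):
    report = rio.recode_report(confounded_recoded)
    ga = report[(report["variable"] == "ga_cat") & (report["year"] == 2019)]
    assert ga["n"].sum() == (confounded_recoded["year"] == 2019).sum()
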