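import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ornameta as om
from ornameta.data import DatasetError, validate_table

from conftest import make_toy_table


class TestSamplingVariance:
    @pytest.mark.parametrize(
        "r, n, expected",
        [
            (0.0, 101, 0.01),  # reduces to 1/(n-1)
            (0.5, 28, 0.5625 / 27),
            (-0.5, 28, 0.5625 / 27),  # depends on |r| only
        ],
    )
    def test_values(self, r, n, expected):
        assert om.r_sampling_variance(r, n) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            om.r_sampling_variance(1.0, 30)
        with pytest.raises(ValueError):
            om.r_sampling_variance(0.2, 3)

    @settings(max_examples=60, derandomize=True)
    @given(
        r=st.floats(0.0, 0.99),
        n=st.integers(4, 10_000),
    )
    def test_monotone_decreasing_in_n_and_abs_r(self, r, n):
        v = om.r_sampling_variance(r, n)
        assert om.r_sampling_variance(r, n + 1) < v
        if r + 0.005 < 1:
            assert om.r_sampling_variance(r + 0.005, n) < v


class TestFisher:
    def test_known_values(self):
        assert om.fisher_transform(0.0) == 0.0
        assert om.fisher_transform(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_variance_attached(self):
        z, var = om.fisher_transform(0.3, n=103)
        assert var == pytest.approx(0.01)

    @settings(max_examples=60, derandomize=True)
    @given(r=st.floats(-0.999, 0.999))
    def test_round_trip_identity(self, r):
        z = om.fisher_transform(r)
        assert om.fisher_transform(z, "inverse") == pytest.approx(r, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            om.fisher_transform(1.0)


class TestConvertStatistic:
    @pytest.mark.parametrize(
        "kind, value, df_or_n, expected",
        [
            ("t", 0.0, 20, 0.0),
            ("t", 2.0, 16, np.sqrt(4 / 20)),
            ("t", -2.0, 16, -np.sqrt(4 / 20)),  # sign carried by t
            ("F1", 4.0, 16, np.sqrt(4 / 20)),
            ("chi2_1", 4.0, 100, 0.2),
            ("d", 0.0, 40, 0.0),
            ("d", 2.0, 40, 2 / np.sqrt(8)),
        ],
    )
    def test_conversions(self, kind, value, df_or_n, expected):
        assert om.convert_statistic(kind, value, df_or_n) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unsupported_kind(self):
        with pytest.raises(NotImplementedError):
            om.convert_statistic("eta2", 0.3, 50)


class TestLoadAndValidate:
    def test_csv_round_trip_with_schema(self, tmp_path):
        t = make_toy_table().rename(columns={"r": "correlation", "n": "sample_size"})
        path = tmp_path / "toy.csv"
        t.to_csv(path, index=False)
        ds = om.load_dataset(path, schema={"r": "correlation", "n": "sample_size"})
        assert ds.k == 8
        assert ds.provenance and "toy.csv" in ds.provenance[0]
        assert np.allclose(ds.table["r"], make_toy_table()["r"])

    def test_out_of_range_r_reports_row(self, tmp_path):
        t = make_toy_table()
        t.loc[2, "r"] = 1.2
        t.loc[2, "v"] = 0.01
        path = tmp_path / "bad.csv"
        t.to_csv(path, index=False)
        with pytest.raises(DatasetError, match=r"row 2.*\|r\| <= 1"):
            om.load_dataset(path)

    def test_duplicate_effect_id_rejected(self, tmp_path):
        t = make_toy_table()
        t.loc[1, "effect_id"] = "e1"
        path = tmp_path / "dup.csv"
        t.to_csv(path, index=False)
        with pytest.raises(DatasetError, match="duplicate effect_id"):
            om.load_dataset(path)

    def test_missing_required_column(self, tmp_path):
        t = make_toy_table().drop(columns=["species"])
        path = tmp_path / "nospecies.csv"
        t.to_csv(path, index=False)
        with pytest.raises(DatasetError, match="species"):
            om.load_dataset(path)

    def test_dynamism_consistency_enforced(self):
        t = make_toy_table()
        t.loc[0, "dynamism_binary"] = "static"  # score stays "2"
        errors = validate_table(t)
        assert any("dynamism" in msg for _, msg in errors)

    def test_labels_normalized(self, tmp_path):
        t = make_toy_table()
        t["uninfected_present"] = [" Yes", "NO ", "yes", "no"] * 2
        path = tmp_path / "case.csv"
        t.to_csv(path, index=False)
        ds = om.load_dataset(path)
        assert set(ds.table["uninfected_present"]) == {"yes", "no"}


class TestImputeDirectionless:
    def test_imputes_r_zero_and_v(self):
        t = make_toy_table()
        t.loc[0, ["r", "v"]] = np.nan
        t.loc[0, "directionless"] = True
        t.loc[0, "n"] = 50
        ds = om.impute_directionless(om.Dataset(t, []))
        assert ds.table.loc[0, "r"] == 0.0
        assert ds.table.loc[0, "v"] == pytest.approx(1 / 49)
        # all other records untouched
        pd.testing.assert_frame_equal(
            ds.table.iloc[1:].reset_index(drop=True),
            t.iloc[1:].reset_index(drop=True),
        )

    def test_noop_without_flags(self, toy_dataset):
        out = om.impute_directionless(toy_dataset)
        pd.testing.assert_frame_equal(out.table, toy_dataset.table)

    def test_missing_n_is_an_error(self):
        t = make_toy_table()
        t["n"] = t["n"].astype(float)
        t.loc[0, ["r", "v", "n"]] = np.nan
        t.loc[0, "directionless"] = True
        with pytest.raises(DatasetError, match="cannot impute"):
            om.impute_directionless(om.Dataset(t, []))


class TestSubset:
    def test_all_is_identity(self, toy_dataset):
        out = om.subset_dataset(toy_dataset, "all")
        pd.testing.assert_frame_equal(out.table, toy_dataset.table)

    def test_directional_only_drops_flagged(self):
        t = make_toy_table()
        t.loc[0, "directionless"] = True
        t.loc[0, "r"] = 0.0
        ds = om.subset_dataset(om.Dataset(t, []), "directional_only")
        assert ds.k == 7 and "e1" not in set(ds.table["effect_id"])

    def test_drop_small_categories_threshold(self):
        # categories sized 12, 10, 3; "ten or fewer" removed
        t = pd.concat([make_toy_table()] * 4, ignore_index=True)
        t["effect_id"] = [f"e{i}" for i in range(len(t))]
        t = t.iloc[:25].copy()
        t["study_type"] = ["big"] * 12 + ["edge"] * 10 + ["small"] * 3
        ds = om.subset_dataset(
            om.Dataset(t, []), "drop_small_categories", moderator="study_type"
        )
        assert set(ds.table["study_type"]) == {"big"}
        assert ds.k == 12

    def test_unknown_filter(self, toy_dataset):
        with pytest.raises(DatasetError):
            om.subset_dataset(toy_dataset, "bogus")

    def test_subset_idempotent(self):
        t = make_toy_table()
        t.loc[0, "directionless"] = True
        t.loc[0, "r"] = 0.0
        ds = om.Dataset(t, [])
        once = om.subset_dataset(ds, "directional_only")
        twice = om.subset_dataset(once, "directional_only")
        pd.testing.assert_frame_equal(once.table, twice.table)
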