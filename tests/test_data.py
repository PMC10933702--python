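"""Twin panel reading, residualisation, difference scores and matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinclpm as t
from twinclpm.data import (Schema, TwinDataError, pair_manifest,
                           trait_columns, validate_twin_panel)


class TestReadValidate:
    def test_round_trip_identity(self, three_pair_csv):
        path, frame = three_pair_csv
        table = t.read_twin_panel(path)
        assert table.n_pairs == 3
        cols = Schema().value_columns()
        assert len(cols) == 18
        np.testing.assert_allclose(table.frame[cols].to_numpy(),
                                   frame[cols].to_numpy())

    def test_missing_code_marks_exactly_one_cell(self, three_pair_csv, tmp_path):
        path, frame = three_pair_csv
        frame = frame.copy()
        frame.loc[1, "ep16_t2"] = np.nan
        p2 = tmp_path / "gap.csv"
        frame.to_csv(p2, index=False)
        table = t.read_twin_panel(p2)
        vals = table.frame[Schema().value_columns()]
        assert vals.isna().sum().sum() == 1
        assert np.isnan(table.frame.loc[1, "ep16_t2"])

    def test_duplicate_pair_id_rejected(self, three_pair_csv, tmp_path):
        path, frame = three_pair_csv
        dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        p2 = tmp_path / "dup.csv"
        dup.to_csv(p2, index=False)
        with pytest.raises(TwinDataError, match="p0"):
            t.read_twin_panel(p2)

    def test_sex_discordant_pair_named(self, three_pair_csv):
        _, frame = three_pair_csv
        frame = frame.rename(columns={"sex": "sex_t1"})
        frame["sex_t2"] = frame["sex_t1"]
        frame.loc[2, "sex_t2"] = 1.0 - frame.loc[2, "sex_t1"]
        schema = Schema(sex=("sex_t1", "sex_t2"))
        with pytest.raises(TwinDataError, match="p2"):
            validate_twin_panel(frame, schema)

    def test_write_read_round_trip(self, small_table, tmp_path):
        p = tmp_path / "out.csv"
        t.write_twin_panel(small_table, p)
        back = t.read_twin_panel(p)
        cols = small_table.schema.value_columns()
        np.testing.assert_allclose(back.frame[cols].to_numpy(),
                                   small_table.frame[cols].to_numpy(),
                                   rtol=1e-12, atol=1e-12)


def _tiny_table(values_by_pair, sex, ages):
    """Build a minimal valid table with identical scores everywhere except
    the given mp9 values (twin 1 and twin 2)."""
    n = len(values_by_pair)
    frame = pd.DataFrame({"pair_id": [f"p{i}" for i in range(n)],
                          "sex": sex, "age9": ages,
                          "age12": [12.0] * n, "age16": [16.0] * n})
    for col in Schema().value_columns():
        frame[col] = 1.0
    frame["mp9_t1"] = [v[0] for v in values_by_pair]
    frame["mp9_t2"] = [v[1] for v in values_by_pair]
    return validate_twin_panel(frame)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        # mp9 equal to age for both twins -> age regression is exact
        tab = _tiny_table([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)],
                          sex=[0.0, 0.0, 0.0], ages=[1.0, 2.0, 3.0])
        res = t.residualize_covariates(tab)
        np.testing.assert_allclose(res.frame[["mp9_t1", "mp9_t2"]], 0.0,
                                   atol=1e-10)

    def test_group_mean_centering_by_sex(self):
        # constant age; scores differ by sex only -> residuals all zero
        tab = _tiny_table([(2.0, 2.0), (2.0, 2.0), (4.0, 4.0), (4.0, 4.0)],
                          sex=[0.0, 0.0, 1.0, 1.0], ages=[9.0] * 4)
        res = t.residualize_covariates(tab)
        np.testing.assert_allclose(res.frame[["mp9_t1", "mp9_t2"]], 0.0,
                                   atol=1e-10)

    def test_orthogonal_covariate_leaves_centered_values(self):
        rng = np.random.default_rng(0)
        age = np.array([8.6, 9.4, 8.6, 9.4, 8.6, 9.4])
        y1 = np.array([1.0, 1.0, -2.0, -2.0, 1.0, 1.0])  # orthogonal to age
        tab = _tiny_table(list(zip(y1, y1)), sex=[0.0] * 6, ages=age)
        res = t.residualize_covariates(tab, covariates=("age",))
        np.testing.assert_allclose(res.frame["mp9_t1"], y1 - y1.mean(),
                                   atol=1e-10)

    def test_idempotent_and_orthogonal(self, small_table):
        once = t.residualize_covariates(small_table)
        twice = t.residualize_covariates(once)
        cols = small_table.schema.value_columns()
        np.testing.assert_allclose(once.frame[cols].to_numpy(),
                                   twice.frame[cols].to_numpy(), atol=1e-8)
        # residuals orthogonal to each covariate, per wave, pooled twins
        for occ in (9, 12, 16):
            age = pd.concat([once.frame[f"age{occ}"]] * 2, ignore_index=True)
            sex = pd.concat([once.frame["sex"]] * 2, ignore_index=True)
            for v in ("mp", "ep", "bp"):
                y = pd.concat([once.frame[f"{v}{occ}_t1"],
                               once.frame[f"{v}{occ}_t2"]], ignore_index=True)
                n = y.notna().sum()
                assert abs(np.nansum(y * age)) < 1e-7 * n
                assert abs(np.nansum(y * sex)) < 1e-7 * n

    def test_missing_cells_stay_missing(self, small_table):
        tab = small_table.copy()
        tab.frame.loc[3, "ep12_t2"] = np.nan
        res = t.residualize_covariates(tab)
        assert np.isnan(res.frame.loc[3, "ep12_t2"])
        assert res.frame["ep12_t1"].notna().all()

    def test_collinear_design_rejected(self):
        tab = _tiny_table([(1.0, 2.0), (2.0, 1.0), (3.0, 4.0), (1.0, 3.0)],
                          sex=[0.0, 1.0, 0.0, 1.0],
                          ages=[9.0, 10.0, 9.0, 10.0])
        # make sex an exact linear function of age -> rank deficient
        tab.frame["sex"] = tab.frame["age9"] - 9.0
        with pytest.raises(TwinDataError, match="rank-deficient"):
            t.residualize_covariates(tab)


class TestDifferenceScores:
    def test_values_and_missing_propagation(self, small_table):
        tab = small_table.copy()
        tab.frame.loc[0, ["mp9_t1", "mp9_t2"]] = [4.0, 4.0]
        tab.frame.loc[1, ["mp9_t1", "mp9_t2"]] = [5.0, 3.0]
        tab.frame.loc[2, "mp9_t2"] = np.nan
        diff = t.make_difference_scores(tab)
        assert diff.frame.loc[0, "mp9"] == 0.0
        assert diff.frame.loc[1, "mp9"] == 2.0
        assert np.isnan(diff.frame.loc[2, "mp9"])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_antisymmetric_under_relabelling(self, seed):
        cfg = t.regime_presets("teds_like", n_pairs=12)
        tab = t.simulate_twin_panel(cfg, seed=seed)
        swapped = tab.copy()
        for stem in trait_columns():
            a = swapped.frame[f"{stem}_t1"].copy()
            swapped.frame[f"{stem}_t1"] = swapped.frame[f"{stem}_t2"]
            swapped.frame[f"{stem}_t2"] = a
        d1 = t.make_difference_scores(tab).frame.drop(columns="pair_id")
        d2 = t.make_difference_scores(swapped).frame.drop(columns="pair_id")
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy(),
                                   equal_nan=True)
        np.testing.assert_allclose(d1.std().to_numpy(), d2.std().to_numpy(),
                                   equal_nan=True)


class TestObservedMatrix:
    def test_pair_unit_matches_manifest(self, small_table):
        m = t.to_observed_matrix(small_table, "pair")
        assert m.columns == pair_manifest()
        assert m.values.shape == (50, 18)
        assert m.values[0, m.columns.index("ep12_t2")] == \
            small_table.frame.loc[0, "ep12_t2"]

    def test_individual_unit_stacks_twins_with_cluster_labels(self, small_table):
        m = t.to_observed_matrix(small_table, "individual")
        assert m.values.shape == (100, 9)
        assert list(m.columns) == trait_columns()
        assert (m.ids[:50] == m.ids[50:]).all()

    def test_difference_unit_matches_difference_scores(self, small_table):
        m = t.to_observed_matrix(small_table, "difference")
        d = t.make_difference_scores(small_table)
        np.testing.assert_allclose(
            m.values, d.frame.drop(columns="pair_id").to_numpy())

    def test_unknown_unit_rejected(self, small_table):
        with pytest.raises(ValueError, match="unknown unit"):
            t.to_observed_matrix(small_table, "household")
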