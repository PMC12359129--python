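import numpy as np
import pandas as pd
import pytest

from hespat import (
    DecisionMatrix,
    cluster_profile,
    compute_entropy_weights,
    rank_shift,
    regional_weight_comparison,
    shift_summary,
    weight_shift,
)
from hespat import reference as ref


class TestWeightShift:
    def test_published_eu_shifts(self):
        table = ref.regional_weights()
        eu = table[table.region == "European Union"]
        wa = eu[eu.period == "2019"].set_index("indicator")["weight"]
        wb = eu[eu.period == "2021"].set_index("indicator")["weight"]
        shifts = weight_shift(wa, wb)
        expected = ref.regional_weight_shifts().loc["European Union"]
        # published shifts come from unrounded weights; printed weights
        # carry 3-dp rounding, hence the 2e-3 agreement band
        np.testing.assert_allclose(
            shifts.shift, expected.to_numpy(), atol=2e-3
        )
        # Health system gained weight after 2019
        idx = shifts.entities.index("Health system")
        assert shifts.shift[idx] == pytest.approx(0.018, abs=2e-3)

    def test_identical_vectors_zero_shift(self):
        w = pd.Series({"a": 0.6, "b": 0.4})
        np.testing.assert_allclose(weight_shift(w, w).shift, 0.0)

    def test_shifts_sum_to_zero(self, rng):
        wa = pd.Series(rng.dirichlet(np.ones(5)), index=list("abcde"))
        wb = pd.Series(rng.dirichlet(np.ones(5)), index=list("abcde"))
        assert weight_shift(wa, wb).shift.sum() == pytest.approx(0.0, abs=1e-12)

    def test_indicator_mismatch(self):
        with pytest.raises(ValueError, match="indicator sets differ"):
            weight_shift(
                pd.Series({"a": 1.0}), pd.Series({"b": 1.0})
            )


class TestRankShift:
    def test_published_poland_and_lithuania(self):
        table = ref.eu_cocoso_table()
        rs = rank_shift(table["Ri_2019"], table["Ri_2021"])
        frame = rs.to_frame().set_index("entity")
        assert frame.loc["Poland", "shift"] == 6
        np.testing.assert_array_equal(
            frame["shift"].to_numpy(), table["rank_shift"].to_numpy()
        )
        ts = rank_shift(table["Si_2019"], table["Si_2021"])
        assert ts.to_frame().set_index("entity").loc["Lithuania", "shift"] == 1

    def test_identical_rankings_zero(self):
        r = pd.Series({"A": 1, "B": 2})
        np.testing.assert_allclose(rank_shift(r, r).shift, 0.0)

    def test_permutation_shifts_sum_to_zero(self, rng):
        m = 10
        a = pd.Series(rng.permutation(m) + 1, index=[f"c{i}" for i in range(m)])
        b = pd.Series(rng.permutation(m) + 1, index=[f"c{i}" for i in range(m)])
        assert rank_shift(a, b).shift.sum() == 0

    def test_country_mismatch(self):
        with pytest.raises(ValueError, match="country sets differ"):
            rank_shift(pd.Series({"A": 1}), pd.Series({"B": 1}))


class TestShiftSummary:
    def test_published_improvement_counts(self):
        table = ref.eu_cocoso_table()
        rs = rank_shift(table["Ri_2019"], table["Ri_2021"])
        summary = shift_summary(rs).set_index("outcome")
        assert summary.loc["improved", "count"] == 9
        assert summary.loc["unchanged", "count"] == 8
        assert summary.loc["declined", "count"] == 10
        assert summary.loc["improved", "percent"] == pytest.approx(33.33)
        assert summary["count"].sum() == 27

    def test_all_zero(self):
        r = pd.Series({"A": 1, "B": 2, "C": 3})
        summary = shift_summary(rank_shift(r, r)).set_index("outcome")
        assert summary.loc["unchanged", "percent"] == 100.0

    def test_balanced(self):
        a = pd.Series({"A": 1, "B": 2})
        b = pd.Series({"A": 2, "B": 1})
        summary = shift_summary(rank_shift(a, b)).set_index("outcome")
        assert summary.loc["improved", "percent"] == 50.0
        assert summary.loc["declined", "percent"] == 50.0
        assert summary.loc["unchanged", "count"] == 0


class TestClusterProfile:
    def _matrix(self):
        return DecisionMatrix(
            countries=("A", "B", "C"),
            indicators=("x", "y"),
            scores=np.array([[40.0, 10.0], [60.0, 30.0], [90.0, 50.0]]),
        )

    def test_tier_means(self):
        profile = cluster_profile(self._matrix(), {"A": 2, "B": 2, "C": 1})
        assert profile.loc[2, "x"] == 50.0
        assert profile.loc[2, "y"] == 20.0

    def test_singleton_tier_equals_row(self):
        profile = cluster_profile(self._matrix(), {"A": 2, "B": 2, "C": 1})
        np.testing.assert_allclose(profile.loc[1], [90.0, 50.0])

    def test_missing_tier_rejected(self):
        with pytest.raises(ValueError, match="no tier"):
            cluster_profile(self._matrix(), {"A": 1, "B": 1})


class TestRegionalWeightComparison:
    def test_long_format_and_alignment(self, rng):
        w = pd.Series({"x": 0.3, "y": 0.7})
        permuted = w.reindex(["y", "x"])
        table = regional_weight_comparison(
            {("EU", "2019"): w, ("Africa", "2019"): permuted}
        )
        assert set(table.columns) == {"region", "period", "indicator", "weight"}
        pivot = table.pivot_table(
            index=["region", "period"], columns="indicator", values="weight"
        )
        # aligned by name, not by position
        assert pivot.loc[("Africa", "2019"), "x"] == 0.3

    def test_single_region_passthrough(self):
        w = pd.Series({"x": 0.25, "y": 0.75})
        table = regional_weight_comparison({("EU", "2019"): w})
        np.testing.assert_allclose(
            table.set_index("indicator")["weight"].reindex(["x", "y"]),
            [0.25, 0.75],
        )

    def test_indicator_mismatch_rejected(self):
        with pytest.raises(ValueError, match="indicator mismatch"):
            regional_weight_comparison(
                {
                    ("EU", "2019"): pd.Series({"x": 1.0}),
                    ("EMR", "2019"): pd.Series({"z": 1.0}),
                }
            )

    def test_accepts_entropy_results(self, toy_matrix):
        res = compute_entropy_weights(toy_matrix)
        table = regional_weight_comparison({("EU", "2019"): res})
        assert len(table) == toy_matrix.n
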