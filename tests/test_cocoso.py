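import numpy as np
import pytest

from hespat import (
    CocosoRanker,
    appraisal_scores,
    comparability_sums,
    composite_index,
    minmax_normalize,
    rank_alternatives,
    rank_cocoso,
)
from hespat import reference as ref

from .conftest import random_matrix


def eu2019_weights() -> np.ndarray:
    w = (
        ref.regional_weights()
        .query("region == 'European Union' and period == '2019'")["weight"]
        .to_numpy()
    )
    return w / w.sum()


class TestMinmaxNormalize:
    def test_benefit_column(self):
        norm = minmax_normalize(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(norm.values[:, 0], [0, 0.5, 1])

    def test_cost_column_flips(self):
        norm = minmax_normalize(np.array([[0.0], [10.0]]), orientation="cost")
        np.testing.assert_allclose(norm.values[:, 0], [1, 0])

    def test_constant_column_is_all_zero(self):
        norm = minmax_normalize(np.array([[5.0, 1.0], [5.0, 2.0]]))
        np.testing.assert_allclose(norm.values[:, 0], [0, 0])

    def test_extremes_map_to_zero_and_one(self, rng):
        X = random_matrix(rng, m=9, n=4)
        norm = minmax_normalize(X)
        assert np.all(norm.values >= 0) and np.all(norm.values <= 1)
        np.testing.assert_allclose(norm.values.max(axis=0), 1.0)
        np.testing.assert_allclose(norm.values.min(axis=0), 0.0)


class TestComparabilitySums:
    def test_all_ones_row(self):
        cs, p = comparability_sums(np.ones((1, 4)), np.full(4, 0.25))
        np.testing.assert_allclose(cs, [1.0])
        np.testing.assert_allclose(p, [4.0])

    def test_published_worked_rows(self):
        # published normalized rows x published weights reproduce the
        # published CS and P columns (inputs printed at 5 decimals)
        rows = ref.eu2019_worked_rows()
        cs, p = comparability_sums(
            rows["normalized"].to_numpy(), eu2019_weights()
        )
        np.testing.assert_allclose(cs, rows["sums"]["CS"], atol=2e-3)
        np.testing.assert_allclose(p, rows["sums"]["P"], atol=2e-3)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            comparability_sums(np.ones((2, 2)), np.array([1.5, -0.5]))

    def test_zero_power_convention(self):
        # 0**w = 0 for w > 0; zero-weight columns contribute 1
        cs, p = comparability_sums(
            np.array([[0.0, 0.5]]), np.array([0.4, 0.6])
        )
        np.testing.assert_allclose(p, [0.0 + 0.5 ** 0.6])
        cs, p = comparability_sums(
            np.array([[0.0, 0.5]]), np.array([0.0, 1.0])
        )
        np.testing.assert_allclose(p, [1.0 + 0.5])


class TestAppraisalScores:
    def test_two_alternative_hand_example(self):
        ka, kb, kc = appraisal_scores(
            np.array([0.6, 0.4]), np.array([1.0, 1.0]), lam=0.5
        )
        np.testing.assert_allclose(ka, [8 / 15, 7 / 15])
        np.testing.assert_allclose(kb, [2.5, 2.0])
        np.testing.assert_allclose(kc, [1.0, 0.875])

    def test_identical_rows_symmetry(self):
        cs = np.full(5, 0.3)
        p = np.full(5, 2.0)
        ka, kb, kc = appraisal_scores(cs, p)
        np.testing.assert_allclose(ka, 0.2)
        np.testing.assert_allclose(kb, 2.0)
        np.testing.assert_allclose(kc, 1.0)

    def test_zero_minimum_is_hard_error(self):
        with pytest.raises(ValueError, match="min\\(CS\\).*index 1"):
            appraisal_scores(np.array([0.5, 0.0]), np.array([1.0, 1.0]))

    def test_lambda_limits_reduce_kc(self):
        cs = np.array([0.2, 0.5, 0.9])
        p = np.array([1.5, 2.5, 2.0])
        _, _, kc0 = appraisal_scores(cs, p, lam=0.0)
        np.testing.assert_allclose(kc0, p / p.max())
        _, _, kc1 = appraisal_scores(cs, p, lam=1.0)
        np.testing.assert_allclose(kc1, cs / cs.max())

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            appraisal_scores(np.array([0.5]), np.array([1.0]), lam=1.5)


class TestCompositeIndex:
    def test_published_austria_triple(self):
        ci = composite_index(
            np.array([0.038]), np.array([15.125]), np.array([0.851])
        )
        assert abs(ci[0] - 6.123) < 0.005  # inputs rounded at 3 dp

    def test_hand_toy_values(self):
        ci = composite_index(
            np.array([8 / 15, 7 / 15]),
            np.array([2.5, 2.0]),
            np.array([1.0, 0.875]),
        )
        np.testing.assert_allclose(ci, [2.4451, 2.0486], atol=1e-3)
        np.testing.assert_array_equal(rank_alternatives(ci), [1, 2])

    def test_equal_triples_equal_index(self):
        ci = composite_index(
            np.array([0.3, 0.3]), np.array([2.0, 2.0]), np.array([0.9, 0.9])
        )
        assert ci[0] == ci[1]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            composite_index(np.array([0.0]), np.array([1.0]), np.array([1.0]))


class TestRankAlternatives:
    def test_published_ci_columns_reproduce_published_ranks(self):
        table = ref.eu_cocoso_table()
        for period in ref.PERIODS:
            ranks = rank_alternatives(table[f"Ci_{period}"].to_numpy())
            np.testing.assert_array_equal(
                ranks, table[f"Ri_{period}"].to_numpy()
            )

    def test_ties_share_competition_rank(self):
        with pytest.warns(UserWarning, match="tied"):
            ranks = rank_alternatives(np.array([3.0, 3.0, 1.0]))
        np.testing.assert_array_equal(ranks, [1, 1, 3])


class TestCocosoRankerProperties:
    def test_affine_invariance_of_benefit_columns(self, rng):
        X = random_matrix(rng, m=7, n=4)
        w = rng.dirichlet(np.ones(4))
        base = rank_cocoso(X, weights=w)
        Y = X.copy()
        Y[:, 2] = 3.5 * Y[:, 2] + 40.0
        shifted = rank_cocoso(Y, weights=w)
        np.testing.assert_allclose(shifted.Ci, base.Ci, atol=1e-10)
        np.testing.assert_array_equal(shifted.rank, base.rank)

    def test_dominance(self, rng):
        for _ in range(20):
            X = random_matrix(rng, m=6, n=4, low=10, high=90)
            w = rng.dirichlet(np.ones(4))
            dominant = X.max(axis=0) + rng.uniform(1, 5, size=4)
            X = np.vstack([X, dominant])
            res = rank_cocoso(X, weights=w)
            assert res.rank[-1] == 1
            assert res.CS[-1] == res.CS.max()
            assert res.P[-1] == res.P.max()

    def test_estimator_contract(self, toy_matrix):
        est = CocosoRanker(lam=0.5)
        ranks = est.fit_predict(toy_matrix)
        assert sorted(ranks) == [1, 2, 3, 4]
        np.testing.assert_allclose(est.ka_.sum(), 1.0)
        assert np.all(est.kc_ <= 1.0 + 1e-12)
        # both kb ratios are >= 1 at every row (minima are over rows)
        assert np.all(est.kb_ >= 2.0)
        assert est.get_params()["lam"] == 0.5
        res = est.result()
        assert res.countries == toy_matrix.countries

    def test_epsilon_shift_rescues_all_minimum_row(self, rng):
        X = random_matrix(rng, m=5, n=3, low=20, high=80)
        X = np.vstack([X, X.min(axis=0)])  # all-minimum row -> CS = 0
        w = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="min\\(CS\\)"):
            rank_cocoso(X, weights=w)
        est = CocosoRanker(weights=w, eps=1e-6).fit(X)
        assert est.ranks_[-1] == 6
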