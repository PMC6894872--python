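import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_spd
from mvextrap._errors import DimensionError, MvextrapError
from mvextrap.extrapolation_measures import (
    Cutoff,
    MeasureVector,
    cmvpv,
    cutoff_leverage,
    cutoff_max,
    cutoff_quantile,
    extrapolation_index,
    mvpv_det,
    mvpv_trace,
)
from mvextrap.linear_diagnostics import DesignMatrix
from test_mvn_gibbs import make_degenerate_draws


def cofactor_det(M):
    """Laplace cofactor expansion, test-only oracle."""
    M = np.asarray(M, float)
    n = M.shape[0]
    if n == 1:
        return M[0, 0]
    total = 0.0
    for j in range(n):
        minor = np.delete(np.delete(M, 0, axis=0), j, axis=1)
        total += (-1) ** j * M[0, j] * cofactor_det(minor)
    return total


def measure_vec(values, split=None, **kw):
    values = np.asarray(values, float)
    if split is None:
        split = np.array(["observed"] * values.size, dtype=object)
    return MeasureVector(values=values, measure_kind="mvpv_det", split=np.asarray(split, object), **kw)


class TestScalarization:
    def test_trace_of_diagonal(self):
        assert mvpv_trace(np.diag([1.0, 2.0, 3.0, 4.0])) == 10.0

    def test_trace_of_zero_matrix(self):
        assert mvpv_trace(np.zeros((3, 3))) == 0.0

    def test_trace_equals_eigenvalue_sum(self):
        S = random_spd(4, np.random.default_rng(0))
        assert abs(mvpv_trace(S) - np.linalg.eigvalsh(S).sum()) < 1e-10

    def test_det_of_diagonal(self):
        assert np.isclose(mvpv_det(np.diag([1.0, 2.0, 3.0, 4.0])), 24.0)

    def test_det_of_singular_psd_is_zero(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 3))
        S = A @ A.T  # rank 3 of 4
        assert abs(mvpv_det(S)) < 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_det_matches_cofactor_expansion(self, seed):
        S = random_spd(4, np.random.default_rng(seed))
        assert np.isclose(mvpv_det(S), cofactor_det(S), rtol=1e-8)

    def test_indefinite_matrix_rejected(self):
        M = np.diag([1.0, -0.5, 2.0])
        with pytest.raises(MvextrapError, match="indefinite"):
            mvpv_det(M)

    def test_non_square_rejected(self):
        with pytest.raises(DimensionError):
            mvpv_trace(np.ones((2, 3)))


class TestCmvpv:
    def test_degenerate_chain_empty_conditioning(self):
        draws = make_degenerate_draws([[1.0, 0.0], [0.0, 1.0]])
        sigma = np.array([[2.0, 0.3], [0.3, 1.5]])
        draws.Sigma_draws = np.repeat(sigma[None], draws.n_draws, axis=0)
        v = cmvpv(draws, x_i=[1.0, 0.0], observed_values=[np.nan, np.nan],
                  mask=[False, False], target=0)
        assert np.isclose(v, sigma[0, 0])

    def test_observed_target_rejected(self):
        draws = make_degenerate_draws([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(MvextrapError, match="observed"):
            cmvpv(draws, [1.0, 0.0], [0.5, np.nan], mask=[True, False], target=0)

    def test_conditioning_on_correlated_draw_reduces_value(self):
        # fixed draws with strong correlation: Schur complement shrinks variance
        rng = np.random.default_rng(5)
        n_draws = 300
        B = rng.normal(0, 0.1, size=(n_draws, 2, 2))
        sigma = np.array([[1.0, 0.9], [0.9, 1.0]])
        draws = make_degenerate_draws([[0.0, 0.0], [0.0, 0.0]], n_draws=n_draws)
        draws.B_draws = B
        draws.Sigma_draws = np.repeat(sigma[None], n_draws, axis=0)
        x = np.array([1.0, 0.5])
        with_cond = cmvpv(draws, x, [np.nan, 0.2], mask=[False, True], target=0)
        without = cmvpv(draws, x, [np.nan, np.nan], mask=[False, False], target=0)
        assert with_cond < without


class TestCutoffs:
    def test_max_simple(self):
        assert cutoff_max(measure_vec([1.0, 2.0, 3.0])).value == 3.0

    def test_max_single_value(self):
        assert cutoff_max(measure_vec([5.0])).value == 5.0

    def test_max_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.random(1000)
        assert cutoff_max(measure_vec(v)).value == np.sort(v)[-1]

    def test_max_uses_observed_split_only(self):
        mv = measure_vec([1.0, 9.0], split=["observed", "prediction"])
        assert cutoff_max(mv).value == 1.0

    def test_empty_observed_split_rejected(self):
        mv = measure_vec([1.0], split=["prediction"])
        with pytest.raises(MvextrapError):
            cutoff_max(mv)

    def test_quantile_median_of_odd_set(self):
        assert cutoff_quantile(measure_vec([1.0, 2.0, 3.0, 4.0, 5.0]), 0.5).value == 3.0

    def test_quantile_of_constants(self):
        assert cutoff_quantile(measure_vec([2.5] * 10), 0.9).value == 2.5

    def test_quantile_interpolation_convention(self):
        # h = (l-1) r + 1 = 95.05 for values 1..100 at r = 0.95
        v = np.arange(1.0, 101.0)
        assert np.isclose(cutoff_quantile(measure_vec(v), 0.95).value, 95.05)

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_level_out_of_range(self, r):
        with pytest.raises(ValueError):
            cutoff_quantile(measure_vec([1.0, 2.0]), r)

    def test_leverage_cutoff_defaults_to_max_when_no_high_leverage(self):
        rng = np.random.default_rng(3)
        design = DesignMatrix.from_covariates(rng.standard_normal((50, 2)) * 0.2)
        v = rng.random(50)
        mv = measure_vec(v)
        c = cutoff_leverage(mv, design, leverage_multiplier=50.0)
        assert c.value == cutoff_max(mv).value
        assert c.removed_locations == []

    def test_leverage_cutoff_excludes_planted_extreme_row(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((40, 2))
        Z[0] = [25.0, -25.0]  # far outlier carries the largest measure value
        design = DesignMatrix.from_covariates(Z)
        v = rng.random(40) * 0.5
        v[0] = 10.0
        c = cutoff_leverage(measure_vec(v), design)
        keep = np.ones(40, dtype=bool)
        keep[c.removed_locations] = False
        assert 0 in c.removed_locations
        assert c.value == v[keep].max()
        assert c.value < 10.0

    def test_leverage_rule_removing_everything_rejected(self):
        design = DesignMatrix.from_covariates(np.random.default_rng(0).standard_normal((10, 2)))
        with pytest.raises(MvextrapError):
            cutoff_leverage(measure_vec(np.ones(10)), design, leverage_multiplier=0.0)


class TestExtrapolationIndex:
    def test_boundary_value_is_not_extrapolation(self):
        mv = measure_vec([2.0], split=["prediction"])
        rep = extrapolation_index(mv, Cutoff(value=2.0, rule="max"))
        assert rep.index[0] == 0
        assert np.isclose(rep.relative[0], 1.0)

    def test_double_the_cutoff_is_flagged(self):
        mv = measure_vec([4.0], split=["prediction"])
        rep = extrapolation_index(mv, Cutoff(value=2.0, rule="max"))
        assert rep.index[0] == 1
        assert np.isclose(rep.relative[0], 2.0)

    @given(st.integers(0, 500))
    def test_index_iff_relative_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(30) * 3
        mv = measure_vec(v, split=["prediction"] * 30)
        rep = extrapolation_index(mv, Cutoff(value=1.0, rule="max"))
        assert np.array_equal(rep.index == 1, rep.relative > 1.0)

    def test_nested_sets_under_decreasing_cutoffs(self):
        rng = np.random.default_rng(6)
        v = rng.random(100)
        mv = measure_vec(v, split=["prediction"] * 100)
        k1, k2 = 0.8, 0.5
        s1 = set(np.flatnonzero(extrapolation_index(mv, Cutoff(k1, "max")).index))
        s2 = set(np.flatnonzero(extrapolation_index(mv, Cutoff(k2, "max")).index))
        assert s1 <= s2

    def test_report_dataframe_columns(self):
        mv = measure_vec([1.0, 3.0], split=["prediction", "prediction"])
        df = extrapolation_index(mv, Cutoff(2.0, "quantile", 0.95)).to_dataframe()
        assert list(df["extrapolation_index"]) == [0, 1]
        assert set(df.columns) >= {"location_id", "measure_value", "cutoff_value", "relative_value"}
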