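import numpy as np
import pytest
from hypothesis import given, strategies as st

from mapskin.metrics import (ObservedSeries, aafe, fold_ratio, pk_parameters,
                             twofold_coverage)


class TestAAFE:
    def test_identity_gives_one(self):
        res = aafe([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == pytest.approx(1.0)
        assert res.n_excluded == 0

    @pytest.mark.parametrize("obs, pred, expected", [
        (90.9, 263.8, 2.90),   # overpredicted early exposure
        (52.5, 49.1, 1.07),    # peak concentration
        (5233.7, 5546.5, 1.06),
        (144.0, 155.3, 1.08),
    ])
    def test_single_pair_worked_examples(self, obs, pred, expected):
        """For one pair the AAFE equals max(pred/obs, obs/pred)."""
        assert round(aafe([pred], [obs]).value, 2) == expected

    def test_zero_observed_excluded_and_counted(self):
        res = aafe([1.0, 2.0, 3.0], [0.0, 2.0, 3.0])
        assert res.n_used == 2
        assert res.n_excluded == 1
        with pytest.raises(ValueError):
            aafe([1.0], [0.0])

    @given(st.lists(st.tuples(st.floats(0.01, 1e4), st.floats(0.01, 1e4)),
                    min_size=1, max_size=20))
    def test_at_least_one_and_symmetric(self, pairs):
        p = [a for a, _ in pairs]
        o = [b for _, b in pairs]
        forward = aafe(p, o).value
        assert forward >= 1.0
        assert forward == pytest.approx(aafe(o, p).value)

    @given(st.lists(st.tuples(st.floats(0.01, 1e4), st.floats(0.01, 1e4)),
                    min_size=1, max_size=10),
           st.lists(st.tuples(st.floats(0.01, 1e4), st.floats(0.01, 1e4)),
                    min_size=1, max_size=10))
    def test_concatenation_lies_between_parts(self, part1, part2):
        """AAFE of a pooled pair-set is bracketed by the parts' AAFEs."""
        a1 = aafe([p for p, _ in part1], [o for _, o in part1]).value
        a2 = aafe([p for p, _ in part2], [o for _, o in part2]).value
        both = aafe([p for p, _ in part1 + part2],
                    [o for _, o in part1 + part2]).value
        lo, hi = sorted((a1, a2))
        assert lo - 1e-9 <= both <= hi + 1e-9


class TestFoldRatio:
    def test_worked_examples(self):
        assert round(fold_ratio(49.1, 52.5).ratio, 2) == 0.94
        assert fold_ratio(49.1, 52.5).within_twofold
        r = fold_ratio(263.8, 90.9)
        assert round(r.ratio, 2) == 2.90
        assert not r.within_twofold

    def test_identity_and_reciprocity(self):
        assert fold_ratio(5.0, 5.0) == (1.0, True)
        assert (fold_ratio(3.0, 7.0).ratio * fold_ratio(7.0, 3.0).ratio
                == pytest.approx(1.0))

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio(1.0, 0.0)


class TestTwofoldCoverage:
    def test_identical_series_fully_covered(self):
        frac, flags = twofold_coverage([1, 2, 3], [1, 2, 3])
        assert frac == 1.0
        assert flags.all()

    def test_counting(self):
        frac, flags = twofold_coverage([1.0, 2.0, 3.0, 12.0], [1.0, 2.0, 3.0, 4.0])
        assert frac == 0.75
        assert list(flags) == [True, True, True, False]

    @given(st.integers(0, 1000))
    def test_matches_per_point_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        o = rng.uniform(0.1, 10, size=8)
        p = o * rng.lognormal(0, 0.8, size=8)
        frac, flags = twofold_coverage(p, o)
        brute = [0.5 <= pi / oi <= 2.0 for pi, oi in zip(p, o)]
        assert list(flags) == brute
        assert frac == pytest.approx(np.mean(brute))


class TestPKParameters:
    def test_constant_profile(self):
        res = pk_parameters([0.0, 12.0, 24.0], [5.0, 5.0, 5.0], [(0, 24)])
        assert res.c_max == 5.0
        assert res.t_max_h == 0.0   # first occurrence on ties
        assert res.auc[(0, 24)] == pytest.approx(120.0)

    def test_triangular_profile(self):
        res = pk_parameters([0.0, 6.0, 24.0], [0.0, 10.0, 0.0], [(0, 24)])
        assert res.c_max == 10.0
        assert res.t_max_h == 6.0
        assert res.auc[(0, 24)] == pytest.approx(10.0 * 24 / 2)

    def test_window_clipping_and_interpolated_edges(self):
        res = pk_parameters([0.0, 10.0], [0.0, 10.0], [(2, 4), (0, 50)])
        assert res.auc[(2, 4)] == pytest.approx((2 + 4) / 2 * 2)
        assert res.auc[(0, 50)] == pytest.approx(50.0)  # clipped to t=10

    def test_insensitive_to_interpolated_points(self):
        t = np.array([0.0, 4.0, 8.0, 24.0])
        c = np.array([0.0, 8.0, 5.0, 1.0])
        dense_t = np.union1d(t, np.linspace(0, 24, 97))
        dense_c = np.interp(dense_t, t, c)
        a = pk_parameters(t, c, [(0, 24), (2, 20)])
        b = pk_parameters(dense_t, dense_c, [(0, 24), (2, 20)])
        assert a.auc[(0, 24)] == pytest.approx(b.auc[(0, 24)])
        assert a.auc[(2, 20)] == pytest.approx(b.auc[(2, 20)])
        assert a.c_max == b.c_max

    def test_smooth_profile_against_fine_grid_quadrature(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 48, size=200))
        t[0], t[-1] = 0.0, 48.0
        f = lambda x: 20 * x * np.exp(-x / 8)
        coarse = pk_parameters(t, f(t), [(0, 48)]).auc[(0, 48)]
        fine_t = np.linspace(0, 48, 20001)
        fine = np.trapezoid(f(fine_t), fine_t)
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            pk_parameters([0.0, 1.0], [1.0, 1.0], [(5, 6)])


def test_observed_series_validation():
    with pytest.raises(ValueError):
        ObservedSeries(times_h=np.array([0.0, 1.0]), values=np.array([1.0]),
                       compartment="ED")
    with pytest.raises(ValueError):
        ObservedSeries(times_h=np.array([1.0, 0.5]), values=np.array([1.0, 1.0]),
                       compartment="ED")
    with pytest.raises(ValueError):
        ObservedSeries(times_h=np.array([0.0]), values=np.array([-1.0]),
                       compartment="ED")
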