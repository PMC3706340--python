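"""Closed-form curves: fixed points, closed-form inversions, asymptotes,
monotonicity, and the Monte-Carlo checks tying them to the read simulator."""

import math

import numpy as np
import pytest

from debridge.feasibility import (
    INFEASIBLE,
    FeasibilityParams,
    build_feasibility_table,
    critical_window,
    debruijn_curve_N,
    gap_factor,
    greedy_curve_N,
    lander_waterman_N,
    lower_bound_N,
    multibridging_curve_N,
    p_unbridged,
    simplebridging_curve_N,
)
from debridge.repeat_stats import RepeatStats


def _stats(G, a=None, b=None, c=None):
    a, b, c = a or {}, b or {}, c or {}
    l_rep = max(list(a) + [0])
    l_int = max([m for m, _ in b] + [0])
    l_tri = max(list(c) + [0])
    return RepeatStats(
        G=G,
        topology="circular",
        a=a,
        b=b,
        c=c,
        l_repeat=l_rep,
        l_interleaved=l_int,
        l_triple=l_tri,
        L_crit=max(l_int, l_tri) + 1,
    )


class TestPUnbridged:
    def test_window_closes_at_ell_L_minus_1(self):
        p = FeasibilityParams(10_000, 50, 100, 0.01)
        assert p_unbridged(49, p) == 1.0
        assert p_unbridged(60, p) == 1.0

    def test_no_reads_never_bridges(self):
        assert p_unbridged(10, FeasibilityParams(10_000, 50, 0, 0.01)) == 1.0

    def test_direct_value(self):
        p = FeasibilityParams(10_000, 50, 100, 0.01)
        assert p_unbridged(29, p) == pytest.approx(math.exp(-0.2), rel=1e-12)


class TestLanderWaterman:
    def test_fixed_point_property(self):
        G, L, eps = 10**6, 100, 0.01
        N = lander_waterman_N(G, L, eps)
        assert N == pytest.approx(G / L * math.log(N / eps), rel=1e-9)

    def test_longer_reads_need_fewer(self):
        assert lander_waterman_N(10**6, 200, 0.01) < lander_waterman_N(
            10**6, 100, 0.01
        )

    def test_monte_carlo_coverage_probability(self):
        # with N = N_LW uniform reads, the circle should be covered with
        # probability within the target band
        G, L, eps = 10**5, 100, 0.05
        N = int(round(lander_waterman_N(G, L, eps)))
        rng = np.random.default_rng(0)
        trials = 2000
        covered = 0
        for _ in range(trials):
            starts = np.sort(rng.integers(0, G, N))
            gaps = np.diff(starts)
            mx = max(gaps.max(initial=0), G - starts[-1] + starts[0])
            covered += mx <= L
        assert 0.93 <= covered / trials <= 0.99


class TestGreedyCurve:
    def test_no_repeats_is_pure_coverage(self):
        st = _stats(10**5)
        assert greedy_curve_N(100, st, 10**5, 0.01) == pytest.approx(
            lander_waterman_N(10**5, 100, 0.01)
        )

    def test_single_repeat_closed_form(self):
        G, L, eps, m = 10**5, 100, 0.01, 60
        st = _stats(G, a={m: 1})
        closed = max(
            lander_waterman_N(G, L, eps), G * math.log(1 / eps) / (2 * (L - m - 1))
        )
        assert greedy_curve_N(L, st, G, eps) == pytest.approx(closed, rel=1e-6)

    def test_asymptote_at_l_repeat_plus_1(self):
        st = _stats(10**5, a={60: 1})
        assert greedy_curve_N(61, st, 10**5, 0.01) is INFEASIBLE
        assert math.isfinite(greedy_curve_N(62, st, 10**5, 0.01))


class TestDebruijnCurve:
    def test_cbar_two_at_twice_critical_length(self):
        st = _stats(10**6, b={(99, 99): 1})
        assert st.L_crit == 100
        ratio = debruijn_curve_N(200, st, 10**6, 0.01) / lander_waterman_N(
            10**6, 200, 0.01
        )
        assert 1.9 <= ratio <= 2.1

    def test_cbar_tends_to_one(self):
        st = _stats(10**6, b={(99, 99): 1})
        L = 10**6 - 1
        ratio = debruijn_curve_N(L, st, 10**6, 0.01) / lander_waterman_N(
            10**6, L, 0.01
        )
        assert ratio == pytest.approx(1.0, rel=0.01)

    def test_infeasible_at_or_below_K(self):
        st = _stats(10**6, b={(99, 99): 1})
        assert debruijn_curve_N(100, st, 10**6, 0.01) is INFEASIBLE


class TestSimpleBridgingCurve:
    def test_reduces_to_coverage_without_repeats(self):
        st = _stats(10**5)
        L = 100
        n = simplebridging_curve_N(L, st, 10**5, 0.01)
        # K = 1: effective spacing L-1
        assert n == pytest.approx(
            lander_waterman_N(10**5, L, 0.01), rel=2.5 / L * 2
        )

    def test_decreasing_in_L(self):
        st = _stats(10**5, b={(60, 70): 1, (40, 45): 2}, c={20: 1})
        vals = [
            simplebridging_curve_N(L, st, 10**5, 0.01) for L in range(75, 220, 12)
        ]
        assert all(math.isfinite(v) for v in vals)
        assert all(x >= y - 1e-6 for x, y in zip(vals, vals[1:]))

    def test_infeasible_at_triple_asymptote(self):
        st = _stats(10**5, c={80: 1})
        assert simplebridging_curve_N(81, st, 10**5, 0.01) is INFEASIBLE


class TestMultiBridgingCurve:
    def test_no_repeats_equals_coverage_exactly(self):
        st = _stats(10**5)
        L = 100
        assert multibridging_curve_N(L, st, 10**5, 0.01) == pytest.approx(
            lander_waterman_N(10**5, L, 0.01), rel=0.03
        )

    def test_dominant_triple_gap_ratio(self):
        # a single long triple: depth ratio to the lower bound approaches
        # 3 ln(3/eps) / ln(1/(2 eps))
        eps = 0.01
        st = _stats(10**6, c={500: 1})
        L = 520
        ratio = multibridging_curve_N(L, st, 10**6, eps) / lower_bound_N(
            L, st, 10**6, eps
        )
        pred = 3 * math.log(3 / eps) / math.log(1 / (2 * eps))
        assert ratio == pytest.approx(pred, rel=0.01)

    def test_infeasible_below_L_crit(self):
        st = _stats(10**5, b={(60, 70): 1}, c={80: 1})
        assert st.L_crit == 81
        assert multibridging_curve_N(81, st, 10**5, 0.01) is INFEASIBLE


class TestLowerBound:
    def test_interleaved_asymptote(self):
        st = _stats(10**5, b={(60, 70): 1})
        assert lower_bound_N(61, st, 10**5, 0.01) is INFEASIBLE
        assert math.isfinite(lower_bound_N(62, st, 10**5, 0.01))

    def test_no_events_reduces_to_coverage(self):
        st = _stats(10**5)
        assert lower_bound_N(100, st, 10**5, 0.01) == pytest.approx(
            lander_waterman_N(10**5, 100, 0.01)
        )

    def test_quadruple_product_reduces_to_square_when_long_copy_unbridgeable(self):
        # shorter length m < L-1 <= n: (p_m p_n)^2 = 2 eps with p_n = 1
        G, eps = 10**5, 0.01
        st = _stats(G, b={(60, 200): 1})
        L = 100  # 60 < L-1 < 200
        expect = G * math.log(1 / (2 * eps)) / (2 * (L - 61))
        assert lower_bound_N(L, st, G, eps) == pytest.approx(
            max(expect, lander_waterman_N(G, L, eps))
        )

    def test_sum_mode_at_least_as_strong(self):
        st = _stats(10**5, b={(60, 70): 3}, c={50: 2})
        for L in (90, 120, 200):
            assert lower_bound_N(L, st, 10**5, 0.01, mode="sum") >= lower_bound_N(
                L, st, 10**5, 0.01, mode="max"
            ) - 1e-6


class TestGapFactorAndWindow:
    def test_printed_value(self):
        assert gap_factor(0.01) == pytest.approx(3.72, abs=0.005)

    def test_exact_log_algebra(self):
        assert gap_factor(1 / 9) == pytest.approx(4.5, rel=1e-12)

    def test_limit_three(self):
        assert gap_factor(1e-12) == pytest.approx(3.0, abs=0.2)

    def test_window_unit_ratio(self):
        cw = critical_window(1000, 100, 0.1)  # G/L_crit = 1/eps -> r = 1
        assert cw.r == pytest.approx(1.0)
        assert cw.W == pytest.approx(100 / 3)

    def test_window_exact_identity(self):
        cw = critical_window(3_000_000, 3000, 0.01)
        assert cw.r == pytest.approx(1.5, rel=1e-12)
        assert cw.W == pytest.approx(750.0, rel=1e-12)


class TestFeasibilityTable:
    def test_orderings_and_normalisation(self, interleaved_fixture_small):
        fx = interleaved_fixture_small
        st = fx.stats
        G, eps = st.G, 0.01
        grid = list(range(st.L_crit + 4, st.L_crit * 3, 23))
        table = build_feasibility_table(st, G, eps, grid)
        wide = table.pivot(index="L", columns="algorithm", values="N_min")
        finite = wide[np.isfinite(wide["multibridging"])]
        # sufficient conditions can never beat the necessary ones
        assert (finite["multibridging"] >= finite["lower_bound"] - 1e-6).all()
        # c_bar >= 1 wherever finite
        cb = table[table.feasible]["c_bar"]
        assert (cb >= 1 - 1e-6).all()
        # every curve non-increasing in L on its feasible range
        for alg in wide.columns:
            v = wide[alg][np.isfinite(wide[alg])].to_numpy()
            assert (v[:-1] >= v[1:] - 1e-6).all()

    def test_infeasible_region_nesting(self, interleaved_fixture_small):
        st = interleaved_fixture_small.stats
        assert st.l_repeat >= st.L_crit - 1  # fixture regime for the nesting
        G = st.G
        # greedy's infeasible region contains the K-mer algorithms' region
        L_mid = st.L_crit + 2  # feasible for K-mer algorithms, not for greedy
        if L_mid <= st.l_repeat + 1:
            assert greedy_curve_N(L_mid, st, G, 0.01) is INFEASIBLE
            assert math.isfinite(multibridging_curve_N(L_mid, st, G, 0.01))

    def test_grid_must_increase(self, interleaved_fixture_small):
        st = interleaved_fixture_small.stats
        with pytest.raises(ValueError):
            build_feasibility_table(st, st.G, 0.01, [400, 300])

    def test_curves_non_increasing_in_eps(self):
        st = _stats(10**5, b={(60, 70): 1}, c={30: 2})
        for fn in (simplebridging_curve_N, multibridging_curve_N, greedy_curve_N):
            loose = fn(120, st, 10**5, 0.1)
            tight = fn(120, st, 10**5, 0.01)
            assert tight >= loose - 1e-6
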