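"""Closed-form feasibility curves for complete reconstruction.

All formulas live in the Poisson read-arrival model: ``N`` reads of length
``L`` with starts at rate ``N/G`` on a circular genome of length ``G``, and a
target failure probability ``eps`` in (0, 1/2).  Logarithms are natural
throughout.

The pieces:

* ``lander_waterman_N`` — the coverage fixed point ``N = (G/L') ln(N/eps)``
  where ``L'`` is the effective spacing (``L`` for plain coverage, ``L - K``
  when adjacent reads must overlap by ``K``).
* ``p_unbridged`` — probability that a fixed length-``ell`` interval is
  unbridged, ``exp(-(N/G) (L - ell - 1)^+)``: a bridging read must start in
  the ``L - ell - 1`` window that lets it cover one base on each side.
* per-algorithm minimal-``N`` curves (GREEDY, DEBRUIJN, SIMPLEBRIDGING,
  MULTIBRIDGING) and the repeat-pattern lower bound, each a function of the
  repeat statistics only.

Every algorithm curve reports ``c_bar = N / N_LW``, the coverage depth
normalised by the Lander-Waterman depth; feasible curves satisfy
``c_bar >= 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

INFEASIBLE = math.inf

#: bisection bracket: curves are marked infeasible beyond BRACKET_FACTOR * N_LW
BRACKET_FACTOR = 1e3
_RTOL = 1e-9


class SolverError(RuntimeError):
    """Fixed-point / bisection failure, with the offending parameters."""


@dataclass(frozen=True)
class FeasibilityParams:
    """A (G, L, N, eps) operating point."""

    G: int
    L: int
    N: float
    eps: float

    def __post_init__(self):
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 1/2)")

    @property
    def coverage(self) -> float:
        return self.N * self.L / self.G

    def c_bar(self) -> float:
        return self.N / lander_waterman_N(self.G, self.L, self.eps)


@dataclass(frozen=True)
class CriticalWindow:
    """Width of the read-length window over which required depth collapses."""

    W: float
    r: float
    L_crit: int


def p_unbridged(ell: float, params: FeasibilityParams) -> float:
    """P[a fixed length-``ell`` subsequence is unbridged]."""
    window = max(params.L - ell - 1, 0.0)
    return math.exp(-params.N / params.G * window)


def _coverage_fixed_point(G: float, span: float, eps: float) -> float:
    """Largest root of N = (G/span) ln(N/eps) (the stable fixed point)."""
    if span <= 0:
        return INFEASIBLE
    lam = G / span

    def f(N):
        return N - lam * math.log(N / eps)

    lo = max(lam, eps * 1.000001, 1e-12)
    if f(lo) > 0:  # even the stationary point satisfies the equation's rhs
        raise SolverError(
            f"no coverage fixed point for G={G}, span={span}, eps={eps}"
        )
    hi = lo * 2
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2
    else:
        raise SolverError(f"bracket growth failed (G={G}, span={span}, eps={eps})")
    N = brentq(f, lo, hi, rtol=1e-12)
    assert abs(f(N)) <= 1e-6 * N
    return float(N)


def lander_waterman_N(G: float, L: float, eps: float) -> float:
    """Reads needed to cover a length-``G`` circle w.p. >= 1 - eps (Eq. fixed
    point ``N_LW = (G/L) ln(N_LW / eps)``, Poisson starts)."""
    if L < 2 or G <= L:
        raise ValueError("need 2 <= L < G")
    return _coverage_fixed_point(G, L, eps)


def _min_N_for_constraint(h, N_LW: float, eps: float) -> float:
    """Minimal N with h(N) <= eps, h strictly decreasing; INFEASIBLE beyond
    the bracket [1, BRACKET_FACTOR * N_LW]."""
    hi = BRACKET_FACTOR * N_LW
    if h(hi) > eps:
        return INFEASIBLE
    lo = 1.0
    if h(lo) <= eps:
        return lo
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if h(mid) <= eps:
            hi = mid
        else:
            lo = mid
        if hi - lo <= _RTOL * hi:
            break
    return float(hi)


def greedy_curve_N(L: int, stats, G: int, eps: float) -> float:
    """Minimal N for GREEDY: every repeat bridged (union bound
    sum_m a_m p_m^2 <= eps) plus plain coverage.  Asymptote at
    L = l_repeat + 1."""
    if stats.l_repeat >= L - 1 and stats.a:
        return INFEASIBLE
    N_LW = lander_waterman_N(G, L, eps)
    if not stats.a:
        return N_LW

    items = [(m, cnt) for m, cnt in stats.a.items()]

    def h(N):
        lam = N / G
        return sum(cnt * math.exp(-2 * lam * (L - m - 1)) for m, cnt in items)

    N_req = _min_N_for_constraint(h, N_LW, eps)
    return max(N_LW, N_req)


def debruijn_curve_N(L: int, stats, G: int, eps: float) -> float:
    """Minimal N for DEBRUIJN at the theorem-optimal K* = L_crit: adjacent
    reads must overlap by K*, i.e. the coverage fixed point with spacing
    L - K*.  c_bar is then ~ 1/(1 - K*/L)."""
    K = stats.L_crit
    if L <= K:
        return INFEASIBLE
    return _coverage_fixed_point(G, L - K, eps)


def background_K(stats) -> int:
    """Smallest sensible K-mer size: just above the longest repeat an i.i.d.
    sequence of the same length would typically carry (~2 log4 G)."""
    return int(2 * math.log(max(stats.G, 4), 4)) + 2


def _interleaved_constraint(stats, G: int, L: int, eps: float, N_LW: float, K: int):
    """Minimal N with sum b_{m,n} p_m^2 p_n^2 <= eps over pairs with the
    shorter length >= K (shorter pairs never materialise as X-nodes)."""
    items = [
        (m, n, cnt) for (m, n), cnt in stats.b.items() if m >= K
    ]
    if not items:
        return 1.0
    if max(m for m, _, _ in items) >= L - 1:
        return INFEASIBLE

    def h(N):
        lam = N / G
        return sum(
            cnt
            * math.exp(
                -2 * lam * (max(L - m - 1, 0) + max(L - n - 1, 0))
            )
            for m, n, cnt in items
        )

    return _min_N_for_constraint(h, N_LW, eps)


def _triple_constraint(stats, G, L, eps, N_LW, K, triple_bound):
    """Minimal N with every length->=K triple all-bridged w.p. >= 1 - eps."""
    items = [(m, cnt) for m, cnt in stats.c.items() if m >= K]
    if not items:
        return 1.0
    if max(m for m, _ in items) >= L - 1:
        return INFEASIBLE

    if triple_bound == "exact":

        def h(N):
            lam = N / G
            tot = 0.0
            for m, cnt in items:
                p = math.exp(-lam * (L - m - 1))
                tot += cnt * (1.0 - (1.0 - p) ** 3)
            return tot

    elif triple_bound == "union":

        def h(N):
            lam = N / G
            return sum(3 * cnt * math.exp(-lam * (L - m - 1)) for m, cnt in items)

    else:
        raise ValueError(f"unknown triple_bound {triple_bound!r}")

    return _min_N_for_constraint(h, N_LW, eps)


def simplebridging_curve_N(
    L: int, stats, G: int, eps: float, K: int | None = None
) -> float:
    """Minimal N for SIMPLEBRIDGING: all interleaved repeats bridged
    (sum b_{m,n} p_m^2 p_n^2 <= eps) and overlap-by-K coverage, with the
    theorem-minimal K = l_triple + 1 by default (K must exceed l_triple)."""
    if K is None:
        K = stats.l_triple + 1
    if K <= stats.l_triple:
        raise ValueError("SIMPLEBRIDGING needs K > l_triple")
    if L <= K or (stats.b and stats.l_interleaved >= L - 1):
        return INFEASIBLE
    N_cov = _coverage_fixed_point(G, L - K, eps)
    N_int = _interleaved_constraint(stats, G, L, eps, N_cov, K)
    if N_int is INFEASIBLE:
        return INFEASIBLE
    return max(N_cov, N_int)


def multibridging_curve_point(
    L: int, stats, G: int, eps: float, triple_bound: str = "exact"
):
    """(N, K) on the MULTIBRIDGING curve: the cheaper of running with a small
    K (background floor; long triple repeats must then be all-bridged) or
    with K = l_triple + 1 (no triples in the graph, but adjacent reads must
    overlap more).  Conditions at parameter K: interleaved pairs of length
    >= K bridged, triples of length >= K all-bridged, adjacent overlap >= K.
    """
    if L <= stats.L_crit and (stats.b or stats.c):
        return INFEASIBLE, None
    candidates = sorted({background_K(stats), stats.l_triple + 1})
    best = (INFEASIBLE, None)
    for K in candidates:
        if L <= K:
            continue
        N_cov = _coverage_fixed_point(G, L - K, eps)
        N_int = _interleaved_constraint(stats, G, L, eps, N_cov, K)
        if N_int is INFEASIBLE:
            continue
        N_tri = _triple_constraint(stats, G, L, eps, N_cov, K, triple_bound)
        if N_tri is INFEASIBLE:
            continue
        N = max(N_cov, N_int, N_tri)
        if N < best[0]:
            best = (N, K)
    return best


def multibridging_curve_N(
    L: int, stats, G: int, eps: float, triple_bound: str = "exact"
) -> float:
    """Minimal N for MULTIBRIDGING (see :func:`multibridging_curve_point`)."""
    return multibridging_curve_point(L, stats, G, eps, triple_bound)[0]


def lower_bound_N(
    L: int, stats, G: int, eps: float, mode: str = "max"
) -> float:
    """Repeat-pattern lower bound on N (holds for every algorithm).

    A pair of interleaved repeats or a triple repeat whose copies are all
    unbridged makes the reads equally likely under a second sequence, so
    reconstruction fails w.p. >= 1/2; requiring error <= eps forces each such
    event's probability below 2*eps.  ``mode="max"`` takes the binding event
    (the tightest single constraint, jointly with plain coverage);
    ``mode="sum"`` instead bounds the summed event probabilities by 2*eps.
    Returns INFEASIBLE for L <= L_crit.
    """
    if (stats.b or stats.c) and L <= stats.L_crit:
        return INFEASIBLE
    N_LW = lander_waterman_N(G, L, eps)
    log_term = math.log(1.0 / (2.0 * eps))
    if mode == "max":
        best = N_LW
        for (m, n), cnt in stats.b.items():
            w = 2 * (max(L - m - 1, 0) + max(L - n - 1, 0))
            if w == 0:
                return INFEASIBLE
            best = max(best, G * log_term / w)
        for m, cnt in stats.c.items():
            w = 3 * max(L - m - 1, 0)
            if w == 0:
                return INFEASIBLE
            best = max(best, G * log_term / w)
        return best
    if mode == "sum":
        b_items = list(stats.b.items())
        # the summed bound needs the same length floor as the b table: exact
        # c_m counts at tiny m are astronomically large with negligible
        # per-event probability, and would swamp the sum numerically
        floor = stats.interleaved_min_length
        c_items = [(m, cnt) for m, cnt in stats.c.items() if m >= floor]

        def h(N):
            lam = N / G
            tot = sum(
                cnt * math.exp(-2 * lam * (max(L - m - 1, 0) + max(L - n - 1, 0)))
                for (m, n), cnt in b_items
            )
            tot += sum(
                cnt * math.exp(-3 * lam * max(L - m - 1, 0)) for m, cnt in c_items
            )
            return tot

        N_req = _min_N_for_constraint(h, N_LW, 2.0 * eps)
        if N_req is INFEASIBLE:
            return INFEASIBLE
        return max(N_LW, N_req)
    raise ValueError(f"unknown mode {mode!r}")


def gap_factor(eps: float) -> float:
    """Depth ratio of MULTIBRIDGING to the lower bound when a single triple
    repeat dominates: 3 ln(3/eps) / ln(1/eps)  (~3.72 at eps = 1e-2)."""
    if not (0 < eps < 1 / 3):
        raise ValueError("eps must lie in (0, 1/3)")
    return 3.0 * math.log(3.0 / eps) / math.log(1.0 / eps)


def critical_window(G: int, L_crit: int, eps: float) -> CriticalWindow:
    """Approximate width W = L_crit / (2r + 1), r = ln(G/L_crit)/ln(1/eps),
    of the read-length window between impossibility and bare coverage."""
    if not (G > L_crit >= 1 and 0 < eps < 1):
        raise ValueError("need G > L_crit >= 1 and eps in (0,1)")
    r = math.log(G / L_crit) / math.log(1.0 / eps)
    return CriticalWindow(W=L_crit / (2 * r + 1), r=r, L_crit=L_crit)


ALGORITHMS = {
    "lower_bound": lower_bound_N,
    "greedy": greedy_curve_N,
    "debruijn": debruijn_curve_N,
    "simplebridging": simplebridging_curve_N,
    "multibridging": multibridging_curve_N,
}


def build_feasibility_table(stats, G: int, eps: float, L_grid) -> pd.DataFrame:
    """Evaluate every curve on ``L_grid``.

    Returns a tidy frame with columns (algorithm, L, N_min, c_bar, feasible);
    infeasible points carry N_min = inf.
    """
    L_grid = list(L_grid)
    if any(b >= a for a, b in zip(L_grid[1:], L_grid)):
        raise ValueError("L_grid must be strictly increasing")
    rows = []
    for L in L_grid:
        try:
            N_LW = lander_waterman_N(G, L, eps)
        except (ValueError, SolverError) as exc:
            raise SolverError(f"coverage solve failed at L={L}: {exc}") from exc
        for name, fn in ALGORITHMS.items():
            try:
                N = fn(L, stats, G, eps)
            except SolverError as exc:
                raise SolverError(f"{name} failed at L={L}: {exc}") from exc
            rows.append(
                {
                    "algorithm": name,
                    "L": L,
                    "N_min": N,
                    "c_bar": N / N_LW if math.isfinite(N) else math.inf,
                    "feasible": math.isfinite(N),
                }
            )
    return pd.DataFrame(rows)
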