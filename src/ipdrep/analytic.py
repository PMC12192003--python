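"""Exact expected-income curves in the large-population limit.

With N >> 1 agents and one sweep of N pairings, an agent of reputation q
plays as the uniformly chosen first player once on average, against an
opponent drawn from the top-of-n order-statistic density

    p_max(x) = n F(x)^(n-1) p_q(x),

and plays as the chosen second player with probability n F(q)^(n-1),
against a uniformly drawn opponent. Its expected income is

    I(q) = I1(q) + n F(q)^(n-1) I2(q),
    I1(q) = int_0^1 p_max(x) G1(q, x) dx,
    I2(q) = int_0^1 p_q(x)  G1(q, x) dx,

with the convention 0^0 = 1 so that n = 1 gives I = I1 + I2 everywhere.

Because G1(q, x) is affine in the opponent reputation x, both integrals
collapse exactly to G1 evaluated at a mean: I1(q) = G1(q, m_n) with m_n the
mean of p_max, and I2(q) = G1(q, m) with m the mean of p_q. The two moments
are computed once per (distribution, n) by adaptive quadrature; everything
downstream is then closed-form in q.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .distributions import ReputationDistribution
from .game import DEFAULT_PAYOFFS, ModelParams, PayoffMatrix, expected_game_payoff

__all__ = [
    "IncomeCurve",
    "ExtremumReport",
    "SocietySummary",
    "max_reputation_density",
    "expected_income_first",
    "expected_income_second",
    "total_income",
    "income_curve",
    "closed_form_income_case1",
    "closed_form_income_case2",
    "defector_income",
    "find_extrema",
    "society_summary",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-12, limit=200)


@dataclass(frozen=True, eq=False)
class IncomeCurve:
    """Expected income I(q) sampled on a reputation grid."""

    params: ModelParams
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if np.any((grid < 0) | (grid > 1)) or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing within [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("income values must be finite")


@dataclass(frozen=True)
class ExtremumReport:
    """A located extremum of I(q): where, how high, and of what kind."""

    location: float
    value: float
    kind: str  # "maximum" | "minimum"
    placement: str  # "interior" | "boundary"


@dataclass(frozen=True)
class SocietySummary:
    """Density-weighted mean E(I) and spread sigma(I) of expected income."""

    expected_income: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def max_reputation_density(dist: ReputationDistribution, n: int, x):
    """Density of the highest reputation among n independent draws.

    ``n F(x)^(n-1) p_q(x)``; reduces to ``p_q`` itself at n = 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    F = np.asarray(dist.cdf(x), dtype=float)
    return n * F ** (n - 1) * np.asarray(dist.pdf(x), dtype=float)


@functools.lru_cache(maxsize=None)
def _dist_mean(dist: ReputationDistribution) -> float:
    val, _ = integrate.quad(lambda x: x * float(dist.pdf(x)), 0.0, 1.0, **_QUAD_KW)
    return val


@functools.lru_cache(maxsize=None)
def _max_mean(dist: ReputationDistribution, n: int) -> float:
    if n == 1:
        return _dist_mean(dist)
    val, _ = integrate.quad(
        lambda x: x * float(max_reputation_density(dist, n, x)), 0.0, 1.0, **_QUAD_KW
    )
    return val


def expected_income_first(q, params: ModelParams):
    """Expected income per game as the first (uniformly chosen) player.

    Equals the quadrature of G1(q, x) against the top-of-n density; since
    G1 is affine in x this is G1(q, E[q_max]) exactly.
    """
    return expected_game_payoff(q, _max_mean(params.dist, params.n), params.payoffs)


def expected_income_second(q, params: ModelParams):
    """Expected income per game as the chosen second player.

    Quadrature of G1(q, x) against the reputation density itself; equal to
    ``expected_income_first`` when n = 1.
    """
    return expected_game_payoff(q, _dist_mean(params.dist), params.payoffs)


def total_income(q, params: ModelParams):
    """Total expected income I(q) = I1(q) + n F(q)^(n-1) I2(q).

    Uses 0^0 = 1, so at n = 1 every agent — including q = 0 — is equally
    likely to be the second player and I = I1 + I2.
    """
    q = np.asarray(q, dtype=float)
    F = np.asarray(params.dist.cdf(q), dtype=float)
    weight = params.n * F ** (params.n - 1)
    return expected_income_first(q, params) + weight * expected_income_second(q, params)


def income_curve(params: ModelParams, grid_size: int = 1001) -> IncomeCurve:
    """Sample I(q) on a regular grid of ``grid_size`` points over [0, 1]."""
    grid = np.linspace(0.0, 1.0, grid_size)
    return IncomeCurve(params=params, grid=grid, values=np.asarray(total_income(grid, params)))


def closed_form_income_case1(q, n: int, payoffs: PayoffMatrix = DEFAULT_PAYOFFS):
    """Polynomial closed form of I(q) for the uniform reputation density."""
    q = np.asarray(q, dtype=float)
    T, R, P, S = payoffs.as_tuple()
    head = 0.5 * n * q ** (n - 1) * (-P * q + P + q * R + q * S - q * T + T)
    tail = (n * q * R - n * q * T + n * T - P * q + P + q * S) / (n + 1)
    return head + tail


def closed_form_income_case2(q, n: int, payoffs: PayoffMatrix = DEFAULT_PAYOFFS):
    """Polynomial closed form of I(q) for the linearly increasing density 2x."""
    q = np.asarray(q, dtype=float)
    T, R, P, S = payoffs.as_tuple()
    head = (n / 3.0) * q ** (2 * (n - 1)) * (-P * q + P + 2 * q * R + q * S - 2 * q * T + 2 * T)
    tail = (2 * n * q * R - 2 * n * q * T + 2 * n * T - P * q + P + q * S) / (2 * n + 1)
    return head + tail


def defector_income(params: ModelParams) -> float:
    """Expected income of an always-defecting (q = 0) agent, n >= 2.

    With n >= 2 a zero-reputation agent is never picked as the second
    player, so its whole income comes from the first-player role:
    I(0) = I1(0) = int p_max(x) [x T + (1-x) P] dx. For the uniform density
    this is (1 + 5n)/(1 + n); for the 2x density, (1 + 10n)/(1 + 2n).
    At n = 1 the premise fails (the single candidate is taken regardless
    of reputation), so n = 1 is rejected.
    """
    if params.n < 2:
        raise ValueError("defector_income requires n >= 2; at n = 1 the q=0 agent still plays second")
    return float(expected_income_first(0.0, params))


def _refine(params: ModelParams, lo: float, hi: float, kind: str) -> tuple[float, float]:
    sign = -1.0 if kind == "maximum" else 1.0
    res = optimize.minimize_scalar(
        lambda q: sign * float(total_income(q, params)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), float(total_income(res.x, params))


def find_extrema(params: ModelParams, grid_size: int = 1001) -> list[ExtremumReport]:
    """Locate all extrema of I(q) on [0, 1].

    A dense grid scan brackets interior sign changes of the slope; each
    bracket is refined by bounded scalar minimisation to about 1e-6 in q.
    The two boundary points are always reported separately (classified by
    comparison with their inner neighbour), so curves whose best income
    sits at q = 1 show up as boundary maxima.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.asarray(total_income(grid, params), dtype=float)
    reports: list[ExtremumReport] = []
    for i in range(1, grid_size - 1):
        if vals[i] > vals[i - 1] and vals[i] >= vals[i + 1]:
            kind = "maximum"
        elif vals[i] < vals[i - 1] and vals[i] <= vals[i + 1]:
            kind = "minimum"
        else:
            continue
        loc, val = _refine(params, grid[i - 1], grid[i + 1], kind)
        # a grid-resolution kink that refines into the bracket edge is not
        # an interior extremum
        if loc <= grid[0] + 1e-7 or loc >= grid[-1] - 1e-7:
            continue
        reports.append(ExtremumReport(loc, val, kind, "interior"))
    reports.append(
        ExtremumReport(0.0, float(vals[0]), "maximum" if vals[0] >= vals[1] else "minimum", "boundary")
    )
    reports.append(
        ExtremumReport(1.0, float(vals[-1]), "maximum" if vals[-1] >= vals[-2] else "minimum", "boundary")
    )
    return reports


def society_summary(params: ModelParams) -> SocietySummary:
    """Density-weighted mean and spread of expected income.

    E(I) = int p_q(x) I(x) dx and sigma(I) = sqrt(int p_q(x) (I(x) - E)^2 dx),
    i.e. the standard deviation of income across the society, which is the
    scale on which income inequality is usually quoted.
    """
    pdf = params.dist.pdf
    mean, _ = integrate.quad(
        lambda x: float(pdf(x)) * float(total_income(x, params)), 0.0, 1.0, **_QUAD_KW
    )
    var, _ = integrate.quad(
        lambda x: float(pdf(x)) * (float(total_income(x, params)) - mean) ** 2,
        0.0,
        1.0,
        **_QUAD_KW,
    )
    return SocietySummary(expected_income=mean, dispersion=float(np.sqrt(max(var, 0.0))))
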