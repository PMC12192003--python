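"""Reputation densities on the unit interval.

An agent's reputation ``q`` is its fixed probability of cooperating in any
single Prisoner's Dilemma game. The composition of the society is described
by a probability density ``p_q(x)`` on [0, 1]. Six named densities are
built in:

========================  =======================================  =============
name                      density p_q(x)                           shape
========================  =======================================  =============
``uniform``               1                                        flat
``linear_increasing``     2x                                       more cooperators
``linear_decreasing``     2 - 2x                                   more defectors
``exp_decreasing``        C(a) (e^{-ax} - e^{-a}),  a > 0          mostly defectors
``hump``                  6x(1-x)                                  mid-reputation
``ushape``                3(2x-1)^2                                polarised
========================  =======================================  =============

with ``C(a) = a e^a / (e^a - a - 1)`` chosen so the exponential density
integrates to one and vanishes at x = 1. User-supplied densities are
accepted as tabulated (x, density) pairs with linear interpolation.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "ReputationDistribution",
    "BUILTIN_CASES",
    "make_distribution",
    "custom_distribution",
    "quantile",
    "sample_reputations",
    "validate_distribution",
]

ArrayLike = float | np.ndarray


@dataclass(frozen=True, eq=False)
class ReputationDistribution:
    """A reputation density/CDF pair on [0, 1].

    ``pdf`` and ``cdf`` are vectorised callables defined on [0, 1].
    ``ppf`` (inverse CDF) is optional; when absent, quantiles are obtained
    by monotone numerical inversion of ``cdf`` (see :func:`quantile`).
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)
    pdf: Callable[[ArrayLike], ArrayLike] = None  # type: ignore[assignment]
    cdf: Callable[[ArrayLike], ArrayLike] = None  # type: ignore[assignment]
    ppf: Callable[[ArrayLike], ArrayLike] | None = None

    def label(self) -> str:
        if self.params:
            inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
            return f"{self.name}({inner})"
        return self.name


def _exp_prefactor(a: float) -> float:
    return a * math.exp(a) / (math.exp(a) - a - 1.0)


def _make_uniform() -> ReputationDistribution:
    return ReputationDistribution(
        name="uniform",
        pdf=lambda x: np.ones_like(np.asarray(x, dtype=float)),
        cdf=lambda x: np.asarray(x, dtype=float),
        ppf=lambda u: np.asarray(u, dtype=float),
    )


def _make_linear_increasing() -> ReputationDistribution:
    return ReputationDistribution(
        name="linear_increasing",
        pdf=lambda x: 2.0 * np.asarray(x, dtype=float),
        cdf=lambda x: np.asarray(x, dtype=float) ** 2,
        ppf=lambda u: np.sqrt(np.asarray(u, dtype=float)),
    )


def _make_linear_decreasing() -> ReputationDistribution:
    return ReputationDistribution(
        name="linear_decreasing",
        pdf=lambda x: 2.0 - 2.0 * np.asarray(x, dtype=float),
        cdf=lambda x: 1.0 - (1.0 - np.asarray(x, dtype=float)) ** 2,
        ppf=lambda u: 1.0 - np.sqrt(1.0 - np.asarray(u, dtype=float)),
    )


def _make_exp_decreasing(a: float = 5.0) -> ReputationDistribution:
    if a <= 0:
        raise ValueError(f"exp_decreasing slope must be positive, got a={a}")
    c = _exp_prefactor(a)
    ea = math.exp(-a)

    def pdf(x: ArrayLike) -> ArrayLike:
        x = np.asarray(x, dtype=float)
        return c * (np.exp(-a * x) - ea)

    def cdf(x: ArrayLike) -> ArrayLike:
        x = np.asarray(x, dtype=float)
        return c * ((1.0 - np.exp(-a * x)) / a - x * ea)

    return ReputationDistribution(
        name="exp_decreasing", params={"a": a}, pdf=pdf, cdf=cdf
    )


def _make_hump() -> ReputationDistribution:
    return ReputationDistribution(
        name="hump",
        pdf=lambda x: 6.0 * np.asarray(x, dtype=float) * (1.0 - np.asarray(x, dtype=float)),
        cdf=lambda x: np.asarray(x, dtype=float) ** 2 * (3.0 - 2.0 * np.asarray(x, dtype=float)),
    )


def _make_ushape() -> ReputationDistribution:
    # 3(2x-1)^2 == -12x(1-x) + 3
    def cdf(x: ArrayLike) -> ArrayLike:
        x = np.asarray(x, dtype=float)
        return 0.5 * ((2.0 * x - 1.0) ** 3 + 1.0)

    return ReputationDistribution(
        name="ushape",
        pdf=lambda x: 3.0 * (2.0 * np.asarray(x, dtype=float) - 1.0) ** 2,
        cdf=cdf,
        ppf=lambda u: 0.5 * (1.0 + np.cbrt(2.0 * np.asarray(u, dtype=float) - 1.0)),
    )


BUILTIN_CASES: dict[str, Callable[..., ReputationDistribution]] = {
    "uniform": _make_uniform,
    "linear_increasing": _make_linear_increasing,
    "linear_decreasing": _make_linear_decreasing,
    "exp_decreasing": _make_exp_decreasing,
    "hump": _make_hump,
    "ushape": _make_ushape,
}


def make_distribution(case_name: str, **params: float) -> ReputationDistribution:
    """Build a named reputation distribution.

    Parameters
    ----------
    case_name
        One of ``uniform``, ``linear_increasing``, ``linear_decreasing``,
        ``exp_decreasing``, ``hump``, ``ushape``.
    **params
        Named parameters; only ``exp_decreasing`` takes one (``a > 0``,
        default 5, the slope of the exponential decay).
    """
    try:
        factory = BUILTIN_CASES[case_name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_CASES))
        raise ValueError(f"unknown distribution case {case_name!r}; known cases: {known}") from None
    return factory(**params)


def custom_distribution(
    x: Sequence[float], density: Sequence[float], *, name: str = "custom"
) -> ReputationDistribution:
    """Build a distribution from tabulated (x, density) pairs.

    The density is linearly interpolated between the tabulated points and
    must cover [0, 1]. If the trapezoidal integral deviates from 1 by less
    than 1e-3 the table is silently renormalised; a larger deviation is
    treated as bad input and rejected.
    """
    x = np.asarray(x, dtype=float)
    density = np.asarray(density, dtype=float)
    if x.ndim != 1 or x.shape != density.shape or x.size < 2:
        raise ValueError("custom density needs matching 1-d x and density arrays, length >= 2")
    order = np.argsort(x)
    x, density = x[order], density[order]
    if x[0] > 1e-12 or x[-1] < 1 - 1e-12:
        raise ValueError("custom density table must span [0, 1]")
    if np.any(density < 0):
        raise ValueError("custom density has negative values")

    # resample onto a fine regular grid so the cdf is cheap and monotone
    grid = np.linspace(0.0, 1.0, 4097)
    dens = np.interp(grid, x, density)
    total = np.trapezoid(dens, grid)
    if abs(total - 1.0) > 1e-3:
        raise ValueError(
            f"custom density integrates to {total:.6g}, more than 1e-3 away from 1; "
            "refusing to renormalise"
        )
    dens = dens / total
    cum = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cum /= cum[-1]

    def pdf(q: ArrayLike) -> ArrayLike:
        return np.interp(np.asarray(q, dtype=float), grid, dens)

    def cdf(q: ArrayLike) -> ArrayLike:
        # exact integral of the piecewise-linear pdf, so d(cdf)/dq == pdf
        q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
        i = np.clip(np.searchsorted(grid, q, side="right") - 1, 0, grid.size - 2)
        dq = q - grid[i]
        return cum[i] + dq * (dens[i] + np.interp(q, grid, dens)) / 2.0

    return ReputationDistribution(name=name, pdf=pdf, cdf=cdf)


@functools.lru_cache(maxsize=None)
def _inversion_table(dist: ReputationDistribution) -> tuple[np.ndarray, np.ndarray]:
    xs = np.linspace(0.0, 1.0, 8193)
    us = np.asarray(dist.cdf(xs), dtype=float)
    us[0], us[-1] = 0.0, 1.0
    return xs, np.maximum.accumulate(us)


def quantile(dist: ReputationDistribution, u: ArrayLike) -> np.ndarray:
    """Inverse CDF, vectorised over probabilities ``u`` in [0, 1].

    Uses the closed-form inverse when the distribution provides one;
    otherwise a monotone table inversion of the CDF refined by two clipped
    Newton steps.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("quantile probabilities must lie in [0, 1]")
    if dist.ppf is not None:
        return np.asarray(dist.ppf(u), dtype=float)
    xs, us = _inversion_table(dist)
    x = np.interp(u, us, xs)
    for _ in range(2):
        f = np.asarray(dist.cdf(x), dtype=float) - u
        slope = np.maximum(np.asarray(dist.pdf(x), dtype=float), 1e-9)
        x = np.clip(x - f / slope, 0.0, 1.0)
    return x


def sample_reputations(
    dist: ReputationDistribution, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` i.i.d. reputations from ``dist`` (inverse-CDF sampling)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return quantile(dist, rng.random(count))


def validate_distribution(dist: ReputationDistribution, *, tol: float = 1e-8) -> None:
    """Check the defining invariants of a reputation density.

    Raises ``ValueError`` if the density is negative anywhere on a fine
    grid, does not integrate to one within ``tol``, has a CDF that fails
    to run monotonically from 0 to 1, or a CDF whose numerical derivative
    disagrees with the density.
    """
    xs = np.linspace(0.0, 1.0, 2001)
    pdf = np.asarray(dist.pdf(xs), dtype=float)
    if np.any(pdf < -1e-12):
        raise ValueError(f"{dist.label()}: density is negative")
    total, _ = integrate.quad(lambda x: float(dist.pdf(x)), 0.0, 1.0, limit=200)
    if abs(total - 1.0) > tol:
        raise ValueError(f"{dist.label()}: density integrates to {total!r}, not 1")
    cdf = np.asarray(dist.cdf(xs), dtype=float)
    if abs(cdf[0]) > 1e-9 or abs(cdf[-1] - 1.0) > 1e-9:
        raise ValueError(f"{dist.label()}: cdf endpoints are ({cdf[0]}, {cdf[-1]})")
    if np.any(np.diff(cdf) < -1e-12):
        raise ValueError(f"{dist.label()}: cdf is not nondecreasing")
    h = 1e-5
    inner = np.linspace(h, 1.0 - h, 101)
    deriv = (np.asarray(dist.cdf(inner + h)) - np.asarray(dist.cdf(inner - h))) / (2 * h)
    if np.max(np.abs(deriv - np.asarray(dist.pdf(inner)))) > 1e-6:
        raise ValueError(f"{dist.label()}: cdf derivative does not match pdf")
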