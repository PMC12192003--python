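"""Agent-based Monte Carlo realisation of the selection-and-play process.

A society of N agents with fixed reputations plays repeated one-shot
Prisoner's Dilemma games. Each iteration: the first player is uniform over
all N agents; n distinct candidates are drawn uniformly from the other
N - 1 agents and the candidate with the highest reputation becomes the
second player (ties broken uniformly at random); each player cooperates
independently with probability equal to its own reputation; realised
payoffs accumulate per agent. Reputations never change during a run.

The simulator validates the analytic large-N income curves and exposes the
finite-size effects that the analytic module deliberately ignores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytic import SocietySummary
from .distributions import ReputationDistribution, sample_reputations
from .game import PayoffMatrix

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "BinnedIncomeCurve",
    "run_simulation",
    "binned_income_curve",
    "simulated_society_summary",
]


@dataclass(frozen=True, eq=False)
class SimulationConfig:
    """Parameters of one Monte Carlo run.

    ``reputations`` optionally fixes the agents' reputations directly
    (e.g. an all-cooperator society); otherwise ``agent_count`` i.i.d.
    draws from ``dist`` are made at the start of the run.
    """

    agent_count: int
    iterations: int
    n: int
    dist: ReputationDistribution
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    seed: int = 0
    reputations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.agent_count - 1):
            raise ValueError(
                f"need 1 <= n <= agent_count - 1, got n={self.n}, N={self.agent_count}"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.reputations is not None:
            reps = np.asarray(self.reputations, dtype=float)
            if reps.shape != (self.agent_count,):
                raise ValueError("reputations must have length agent_count")
            if np.any((reps < 0) | (reps > 1)):
                raise ValueError("reputations must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class SimulationResult:
    """Per-agent outcome of a run: reputations, accumulated incomes, role counts."""

    config: SimulationConfig
    reputations: np.ndarray
    incomes: np.ndarray
    first_counts: np.ndarray
    second_counts: np.ndarray


@dataclass(frozen=True, eq=False)
class BinnedIncomeCurve:
    """Empirical income curve: equal-width reputation bins with per-bin stats.

    ``values`` are per-bin mean incomes rescaled by agent_count/iterations,
    estimating the analytic I(q); empty bins carry NaN. ``sem`` is the
    standard error of each rescaled bin mean.
    """

    centers: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    counts: np.ndarray


def _draw_candidates(
    rng: np.random.Generator, first: np.ndarray, n_agents: int, n: int
) -> np.ndarray:
    """Draw n distinct candidates per iteration, uniform over agents != first.

    Draws index tuples in the (N-1)-sized complement of the first player and
    redraws the few rows containing duplicates, which keeps the whole batch
    vectorised (duplicate probability is O(n^2/N) per row).
    """
    iters = first.size
    cand = rng.integers(0, n_agents - 1, size=(iters, n))
    while True:
        if n == 1:
            break
        sorted_rows = np.sort(cand, axis=1)
        bad = np.any(sorted_rows[:, 1:] == sorted_rows[:, :-1], axis=1)
        if not bad.any():
            break
        cand[bad] = rng.integers(0, n_agents - 1, size=(int(bad.sum()), n))
    # shift the complement indices past the first player's own index
    return cand + (cand >= first[:, None])


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full selection-and-play process; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    N, iters, n = config.agent_count, config.iterations, config.n
    T, R, P, S = config.payoffs.as_tuple()

    if config.reputations is not None:
        reps = np.asarray(config.reputations, dtype=float).copy()
    else:
        reps = sample_reputations(config.dist, N, rng)

    first = rng.integers(0, N, size=iters)
    cand = _draw_candidates(rng, first, N, n)

    cand_reps = reps[cand]
    row_max = cand_reps.max(axis=1)
    tie_key = rng.random((iters, n)) * (cand_reps == row_max[:, None])
    second = cand[np.arange(iters), tie_key.argmax(axis=1)]

    coop1 = rng.random(iters) < reps[first]
    coop2 = rng.random(iters) < reps[second]
    pay1 = np.where(coop1, np.where(coop2, R, S), np.where(coop2, T, P))
    pay2 = np.where(coop2, np.where(coop1, R, S), np.where(coop1, T, P))

    incomes = np.zeros(N)
    np.add.at(incomes, first, pay1)
    np.add.at(incomes, second, pay2)
    first_counts = np.bincount(first, minlength=N)
    second_counts = np.bincount(second, minlength=N)

    return SimulationResult(
        config=config,
        reputations=reps,
        incomes=incomes,
        first_counts=first_counts,
        second_counts=second_counts,
    )


def binned_income_curve(result: SimulationResult, bin_count: int = 20) -> BinnedIncomeCurve:
    """Group agents into equal-width reputation bins and average their incomes.

    Incomes are rescaled by agent_count/iterations so that one sweep of
    agent_count pairings corresponds to scale 1, making the bin means
    directly comparable with the analytic I(q).
    """
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    cfg = result.config
    scale = cfg.agent_count / cfg.iterations
    rescaled = result.incomes * scale
    edges = np.linspace(0.0, 1.0, bin_count + 1)
    idx = np.clip(np.digitize(result.reputations, edges) - 1, 0, bin_count - 1)

    counts = np.bincount(idx, minlength=bin_count)
    if counts.sum() == 0:
        raise ValueError("binning produced no occupied bins")
    sums = np.bincount(idx, weights=rescaled, minlength=bin_count)
    sq_sums = np.bincount(idx, weights=rescaled**2, minlength=bin_count)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = sq_sums / np.maximum(counts, 1) - means**2
        sem = np.where(counts > 1, np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1)), np.nan)

    return BinnedIncomeCurve(
        centers=(edges[:-1] + edges[1:]) / 2.0,
        values=means,
        sem=sem,
        counts=counts,
    )


def simulated_society_summary(result: SimulationResult) -> SocietySummary:
    """Mean and standard deviation of rescaled per-agent incomes."""
    scale = result.config.agent_count / result.config.iterations
    rescaled = result.incomes * scale
    return SocietySummary(
        expected_income=float(rescaled.mean()),
        dispersion=float(rescaled.std()),
    )
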