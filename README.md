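# ipdrep

Expected income in a society of Prisoner's Dilemma players whose partners
are chosen by reputation.

## The model

A society of N ≫ 1 agents plays repeated one-shot Prisoner's Dilemma games
with payoffs T > R > P > S and 2R > T + S (defaults T=5, R=3, P=1, S=0).
Each agent carries a fixed reputation q ∈ [0, 1]: the probability that it
cooperates in any game. Reputations across the society follow a density
p_q(x) on [0, 1].

Each game is set up by selective assortment:

1. the **first** player is drawn uniformly from the society;
2. the **second** player is the most reputable of n candidates drawn
   uniformly (without replacement) from the remaining agents. The maximum
   of n draws has the order-statistic density
   p_max(x) = n F(x)^{n-1} p_q(x), with F the CDF of p_q.

Both players then cooperate independently with probability equal to their
own reputation, so the expected payoff of player 1 is bilinear:

    G1(q1, q2) = q1 [q2 R + (1 - q2) S] + (1 - q1) [q2 T + (1 - q2) P].

In the large-N limit the expected income of a reputation-q agent over one
sweep of N pairings depends only on q, n, and p_q:

    I(q) = I1(q) + n F(q)^{n-1} I2(q),
    I1(q) = ∫ p_max(x) G1(q, x) dx   (income as first player),
    I2(q) = ∫ p_q(x)  G1(q, x) dx    (income as second player),

with the convention 0^0 = 1 so that n = 1 gives I = I1 + I2. Society-level
summaries are the density-weighted mean E(I) = ∫ p_q(x) I(x) dx and the
dispersion σ(I), the square root of the weighted squared deviation.

The package computes I(q) exactly (G1 is affine in the opponent reputation,
so each integral collapses to G1 evaluated at a mean computed once by
adaptive quadrature), locates its interior and boundary extrema, reproduces
the society summary table for six built-in reputation densities, and
validates everything against a seeded agent-based Monte Carlo simulator of
the finite-N process. It is aimed at researchers in evolutionary game
theory and cooperation dynamics who want exact curves, not just simulation
estimates.

## Worked example

```python
from ipdrep import ModelParams, find_extrema, make_distribution, total_income

params = ModelParams(n=2, dist=make_distribution("uniform"))
print(round(float(total_income(0.0, params)), 3))
for rep in find_extrema(params):
    print(rep.kind, rep.placement, round(rep.location, 3), round(rep.value, 3))
```

prints

```
3.667
maximum interior 0.722 5.231
minimum boundary 0.0 3.667
minimum boundary 1.0 5.0
```

With two candidates competing for the second-player slot, an always-defector
(q = 0) earns 11/3 ≈ 3.667 — the worst income in the society — while the
best income, ≈ 5.231, goes to agents of intermediate reputation q ≈ 0.722:
reputable enough to be chosen often, defecting often enough to cash in T.
At n = 1 the same society instead rewards pure defection (I(q) = 6 − 3q).

The same numbers from the shell:

```sh
ipdrep extrema --case uniform --n 2
ipdrep table1 --out table1.csv
ipdrep compare --case exp_decreasing --a 5 --n 3 --agents 10000 --seed 7
```

`table1` writes the society mean income and dispersion for all six built-in
densities and n ∈ {1, 2, 3, 5, 10}; `compare` runs the agent-based
simulator and z-scores each reputation bin against the analytic curve.

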