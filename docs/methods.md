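# Methods

## Model and assumptions

Agents never change behaviour: reputation q is both an agent's probability
of cooperating and its attractiveness as a partner, fixed for the whole
process. There is no learning, no reputation updating, no spatial or
network structure, and no strategy memory — each game is a one-shot
Prisoner's Dilemma in expectation. These are modelling choices, not
simplifications of the implementation: the analytic solvability of the
expected-income curve rests on them.

The income formula I(q) = I1(q) + n F(q)^{n-1} I2(q) is the large-N limit:
the probability of being drawn as the first player (1/N per pairing, N
pairings) contributes I1 once, and the probability of being the best of n
uniformly sampled candidates contributes n F(q)^{n-1} weighted games as the
second player. Finite-N corrections (an agent cannot partner itself; the
candidate pool is the empirical population, not the ideal density) are
O(1/N) and are deliberately left to the simulator.

At n = 1 the "best of one" candidate is taken regardless of reputation, so
the exponent F(q)^{n-1} = F(q)^0 must equal 1 for every q including q = 0;
the code fixes 0^0 = 1 (numpy's convention already) so that the n = 1 curve
I = I1 + I2 holds at the boundary.

## Computing the income integrals

G1(q, x) is affine in the opponent reputation x. Hence

    I1(q) = G1(q, E[q_max]),   I2(q) = G1(q, E[q]),

exactly, where E[q_max] is the mean of the order-statistic density
n F^{n-1} p_q and E[q] the mean of p_q. The implementation computes those
two moments once per (distribution, n) with `scipy.integrate.quad`
(epsabs = epsrel = 1e-12, limit 200) and caches them, making every curve,
extremum search and society integral effectively closed-form in q. The
test suite checks this reduction against brute-force nested quadrature of
the defining integrals for every built-in density, and against the
polynomial closed forms available for the uniform and linearly increasing
densities (agreement to 1e-8 on a 101-point grid for n = 1..10).

Society summaries use one further quadrature over p_q(x) I(x). The
dispersion is reported as a standard deviation (the square root of the
density-weighted squared deviation): that is the scale on which the
reference summary table's bracketed values fall, and the natural unit of
income inequality.

## Extremum location

`find_extrema` scans I(q) on a regular grid (default 1001 points), brackets
every local extremum by discrete comparison, and refines each bracket with
bounded scalar minimisation (`xatol` 1e-9, well past the 1e-6 reporting
precision). Monotone curves produce no interior reports; the two boundary
points are always reported separately, classified by comparison with their
inner neighbour, so "best income at q = 1" cases appear as boundary maxima
rather than being silently dropped. A refinement that collapses onto a
bracket edge is discarded as a grid artefact.

Known quirk of the reference values: the linearly increasing density at
n = 2 has its interior minimum at (220 − √32200)/300 ≈ 0.1352, usually
quoted as "near 0.134"; the package reports the computed root.

## Built-in densities and sampling

The six built-in compositions (uniform; linear 2x; linear 2 − 2x;
truncated exponential with slope a, default a = 5, normalised by
a e^a/(e^a − a − 1) and shifted so the density vanishes at x = 1; the hump
6x(1 − x); the U-shape 3(2x − 1)^2) all carry closed-form CDFs, and
closed-form inverse CDFs where elementary (uniform, both linear cases, the
U-shape). Sampling is inverse-CDF: closed form when available, otherwise a
monotone 8193-point inversion table refined by two clipped Newton steps —
exact enough that a 20-bin chi-squared test at 10^5 draws passes at the
0.001 level for every case. User densities are accepted as tabulated
(x, density) pairs, linearly interpolated, with the CDF computed as the
exact integral of the interpolant; tables off normalisation by less than
1e-3 are renormalised, anything worse is rejected as probably erroneous
input.

## The simulator

The Monte Carlo engine realises the finite-N process literally: reputations
drawn once and frozen; first player uniform over N; n distinct candidates
drawn uniformly from the other N − 1 agents (vectorised with redraw of the
rare duplicate rows); maximal-reputation candidate chosen with uniform
random tie-breaking (measure-zero for continuous densities, but required
for reproducibility with discretised custom densities); independent
cooperation draws; realised payoffs accumulated per agent. One
`numpy.random.Generator` seeded from the config drives the whole run.

Iterations are decoupled from N; binned income curves rescale per-agent
income by N/iterations so a run of any length estimates I(q) on the
one-sweep scale. Default validation runs use N = 10^4 agents and 10^4
iterations with 20 reputation bins — bins then hold ~500 agents and the
per-bin standard error is small enough to resolve the curve shape while a
full 6-case × 5-n validation sweep completes in seconds.

What the simulator does and does not show: it validates the selection
rules, the payoff accounting and the large-N limit of the analytic module
against an independent realisation of the same idealised process. It does
not emulate any feature of real societies beyond the model's assumptions —
no real data, no heterogeneous interaction rates, no reputation dynamics —
so agreement here is evidence of internal consistency, not of empirical
adequacy.

## Numerical choices and edge cases

- Payoff matrices validate the strict PD ordering by default; a
  `strict=False` flag admits other social-dilemma orderings (Snowdrift,
  Stag Hunt) without mislabelling them.
- Degenerate equal payoffs T=R=P=S=c reduce I(q) to c(1 + n F(q)^{n-1})
  exactly; this is used as a closed-form oracle in tests.
- The always-defector income formula I(0) = I1(0) holds only for n ≥ 2
  (for n ≥ 2 a q = 0 agent is never selected as second player);
  `defector_income` rejects n = 1, where I(0) = I1(0) + I2(0) instead.
- Empty reputation bins are reported as missing (NaN) rather than zero;
  comparison z-scores are computed only for bins holding at least two
  agents.

## Known limitations

- General-n symbolic closed forms exist only for the uniform and linearly
  increasing densities; the decreasing, hump and U-shaped cases go through
  the (exact) moment reduction.
- The society dispersion of the simulator includes selection and game
  noise on top of the reputation-driven spread, so it converges to the
  analytic σ(I) only as iterations → ∞ at fixed N/iterations; the mean is
  unbiased at any run length.
- Three cells of the commonly cited society summary table cannot be
  reproduced at two-decimal precision by exact computation (the computed
  values are 5.4286, 3.2594 and 4.9286 where 5.42, 3.25 and 4.95 are
  usually quoted); the package reports the computed values, which are
  confirmed by brute-force quadrature and large-N simulation.
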