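# Methods

## Model

An environment has `N` discrete states with a uniform source `p(x) = 1/N`;
`H[X] = log2 N` is the proxy for environmental complexity. Perception is a
stochastic codebook `p(xhat|x)`; its resource cost is the transmission rate
`R = I(X; Xhat)` in bits and its error cost is the expected distortion
`D = sum_{x,xhat} p(x) p(xhat|x) d(x, xhat)` under an `N x N` distortion
matrix `d` with zero diagonal (a correct percept is free). The
rate-distortion function `R(D)` is the minimal rate over codebooks with
expected distortion at most `D`.

Environments are random: the `N(N-1)` off-diagonal entries of `d` are drawn
i.i.d. from a shifted exponential or shifted lognormal density. The shift is
the target *minimal confound* `d_min = min_{x != xhat} d(x, xhat)`, the
cheapest possible confusion. `d_min` divides the distortion axis into a
high-fidelity regime (`D < d_min`), where `R(D)` grows like `log2 N`, and a
low-fidelity regime (`D > d_min`), where `R(D)` saturates as `N` grows
because harmless synonyms accumulate linearly in `N`.

## Solver

`R(D)` is computed by the Blahut-Arimoto fixed point at gain `beta`:

    p(xhat|x) <- r(xhat) exp(-beta d(x, xhat)) / Z(x)
    r(xhat)   <- sum_x p(x) p(xhat|x)

iterated from the uniform codebook until the Lagrangian
`L = R + beta D / ln 2` (bits) changes by less than `tol = 1e-10`, with a cap
of `max_iter = 1000` iterations. Both half-steps are exact coordinate
minimizations of a jointly convex functional, so `L` is non-increasing — a
property the test suite asserts on every iteration of randomized problems. A
fixed-iteration mode (no tolerance test) is available for strict
reproduction of fixed-count runs.

Conventions and numerical choices:

- **Bases.** Rates are bits everywhere; the exponential weight uses the
  natural base, so `beta` is in nats per distortion unit (this affects only
  the labeling of `beta`, not `R(D)`).
- **Stability.** Since `d >= 0` with a zero diagonal, `exp(-beta d)` lies in
  `(0, 1]` and every row retains its diagonal weight `1`; the iteration
  cannot overflow or lose a whole row even at `beta` in the hundreds, so no
  explicit log-domain shift is needed (the diagonal *is* the row maximum).
- **Initialization** is always the uniform codebook. The problem is convex,
  so warm starts change nothing but the iteration count; a warm-start option
  was deliberately omitted to keep one code path.
- **Beta search.** The achieved distortion `D_beta` is monotone
  non-increasing in `beta`. A distortion target is located by doubling an
  upper bracket from `beta = 1` until `D_beta` falls below target (hard cap
  `1e7`), then bisecting until `|D_beta - target| < 1e-4 * D_max` or the
  bracket is narrower than `1e-8`. The smallest examined `beta` achieving
  `D_beta <= target` is reported as the empirical required gain.
- **Curve sweep.** Distortion targets evenly tile `[0, D_max]` where
  `D_max = min_xhat sum_x p(x) d(x, xhat)` is the distortion of the best
  zero-rate (constant) codebook. The `D = 0` end is solved at the beta cap;
  the `D = D_max` end is written down exactly as the best constant codebook
  (rate 0), because at `beta = 0` the uniform codebook is a fixed point
  whose distortion (the grand mean of `d`) lies beyond the curve's right
  endpoint. Degenerate all-zero matrices collapse to the single point
  `(R, D) = (0, 0)`.
- **Ties.** `0 log 0 = 0` throughout (`scipy.special.xlogy`); tiny negative
  rates from rounding are clipped to 0.

## Bounds

All bounds are evaluated per matrix and compared against the solver in the
tests (lower bound <= solved rate <= each upper bound, at the achieved
distortion of every swept point):

- **Quantile bound** `log2(1 / P(d < D))`: N-independent ceiling in the
  low-fidelity regime; `inf` when the quantile mass is zero. The ensemble
  CDF version uses the closed-form exponential/lognormal CDF; the empirical
  version uses the matrix's own off-diagonal entries.
- **Synonym bound** `(1/N) sum_x log2(N / N_D(x))` with
  `N_D(x) = #{xhat : d(x, xhat) < D}` (strict inequality; the state itself
  always counts since `d(x, x) = 0`). Achievable by mapping each state
  uniformly onto its synonyms, hence a rigorous upper bound.
- **Uniform-allocation bound**: the codebook keeping `1 - C` on the diagonal
  and spreading `C` evenly off it has rate
  `log2 N - H_b(C) - C log2(N-1)` and distortion `C <d>`; its rate formula
  is checked to `1e-12` against the mutual information of the explicitly
  constructed codebook.
- **Uniform-environment lower bound**
  `log2 N - H_b(D/d_min) - (D/d_min) log2(N-1)` (zero beyond
  `d_min (N-1)/N`): the exact `R(D)` of the easier environment in which
  every confusion costs `d_min`. This Hamming-type form is pinned by three
  checks: it reduces to `1 - H_b(D)` at `N = 2`, its zero-rate endpoint is
  `d_min (N-1)/N`, and its large-N behavior is `(1 - D/d_min) log2 N`,
  matching the leading-order bracket.
- **Large-N bracket** `[(1 - D/d_min) log2 N, (1 - D/<d>) log2 N]`, valid
  for `D < d_min`; the ensemble slope fit must land inside it.
- **Required gain** `(C / (<d> - D)) log2 N`: when high-fidelity coding at
  rate `C log2 N` beats not coding at all.
- **Gaussian case** `(1/2) log2(sigma^2 / D)` for squared error: a continuum
  source has no minimal confound and hence no low-fidelity plateau.

## Synthetic-data generator

The generator *is* the study condition: unstructured random environments.
Defaults follow the analysis setup — unit-mean exponential entries with
shift 0, 1, or 20; a lognormal alternative calibrated so that `P(d < D)`
matches the exponential reference at one quantile (the calibration pins only
the log-mean; `log_sd` stays free with default 1.0, the simplest choice
consistent with the single stated constraint); and a pairwise-correlated
variant in which each off-diagonal entry is replaced by the average of
itself and one uniformly chosen other entry (partners drawn with
replacement, recorded for testability, replacement simultaneous).

What the generator does **not** emulate: block/hierarchical structure,
state-dependent (non-exchangeable) costs, non-uniform sources, or
environments whose correlation scale grows with `N`. Passing tests
therefore show the two-regime scaling for exchangeable unstructured costs,
not for strongly structured real perceptual domains.

## Ensemble experiments

`run_ensemble` draws matrices per size `N`, solves the rate and the minimal
required gain at each distortion target by bisection, and aggregates cells
with a percentile bootstrap of the mean (1000 resamples, 68% level by
default; the bootstrap variant is a package choice, made once). A draw whose
zero-rate distortion falls below a target contributes rate 0 and is flagged.
Slopes of mean rate versus `log2 N` come from unweighted least squares
(`scipy.stats.linregress`).

Problem sizes are desk-scale by design: 10 samples with `N` in
{20, 50, 100} for the regime checks, 5 draws at `N = 200` for the
low-fidelity ceiling, 20 matrices up to `N = 50` for the bound sandwich,
and 25 draws for the self-averaging check. Larger, figure-scale runs
(50 samples, `N` up to 200 across the whole grid) use the same code paths
via `RunConfig`.

## Reproducibility

Every random quantity derives from a single root seed through
`derive_seed(root, task_label, indices...)` (CRC-mixed, platform-stable,
`< 2**31`), so execution order cannot change results. A run manifest records
the config, seeds, and a content hash per generated matrix; replaying a
manifest regenerates byte-identical CSVs, which the tests assert.

## Known limitations

- Only stochastic codebooks are considered; deterministic (hard-clustering)
  codebooks and multi-letter coding are out of scope.
- The solver returns feasible codebooks, so swept points lie on or slightly
  above the true curve; near phase transitions (clusters merging as `beta`
  decreases) convergence within the iteration cap can leave points a few
  thousandths of a bit high.
- The pairwise-correlated ensemble has no closed-form entry CDF; its
  quantile bound must use the empirical CDF.
- Bootstrap intervals with 10 samples per cell are indicative, not sharp;
  slope standard errors at three sizes are similarly coarse.
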