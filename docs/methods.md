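# Methods

## The problem and the model

`growthmap` analyses a long annual series of crude rates -- the motivating
case is the Italian crude suicide rate per 100,000 inhabitants, 1873-2010,
elaborated from ISTAT judicial statistics -- by treating each annual rate
`s_t` as the discrete derivative of a latent cumulative level
`S_t = sum_{i<=t} s_i` ("the suicide population accumulated since the base
year").  The question the analysis asks is mechanistic: which growth law
generates increments with the observed shape?

Four candidate laws are compared on the cumulative series:

* **constant growth** -- `S_t = c + b t`; derivative is flat;
* **Malthusian growth** -- `dS/dt = a S`, i.e. `S_t = S_0 e^{a t}`;
  derivative is an exponential of the same rate;
* **restrained (Verhulst) growth** -- `dS/dt = a S - b S^2`, with carrying
  capacity `a/b`: the maximum level the social environment sustains.  The
  discrete form, after normalizing the level by its carrying capacity so
  the state lives in (0, 1), is the logistic map

      x_{t+1} = k x_t (1 - x_t),    k = 1 + a;

* **cubic extension** -- `x_{t+1} = k1 x - k2 x^2 + k3 x^3` (`k2` stored
  positive, entering negatively), which lets a restrained process keep
  creeping upward during late-series stress periods instead of saturating.

The scientific payoff of a fitted `k` is qualitative: `k < 1` decay,
`1 <= k <= 3` convergence to the fixed point `(k-1)/k`, `3 < k < 3.8`
period-doubling cycles, `3.8 <= k <= 4` deterministic chaos.  A small `k`
slightly above 1 reads as a tightly bounded, self-regulating growth
process; a `k` near 3.8-4 as a socially unstable one in which
interventions have unpredictable effects.  The band edges implemented are
the round figures of the applied literature (1, 3, 3.8, 4), a deliberate
reading aid rather than textbook bifurcation values (the true
period-doubling onset is 3.5699...): the classifier reproduces the
taxonomy this style of analysis uses, and `classify_regime`'s docstring
says so.

## Estimation: iterate, standardize, match

The map is nonlinear in its parameters and the orbit is built recursively,
so it is fitted by direct search rather than regression:

1. standardize the cumulative target `Ts = (S - M)/sigma` (population
   sigma, denominator `n`);
2. iterate the map over a grid of `(k, x0)` (logistic) or
   `(k1, k2, k3, x0)` (cubic) candidates, one orbit per candidate, the
   orbit length equal to the window length;
3. standardize each orbit the same way;
4. score each candidate by `R^2 = (sum Ts^2 - sum (Ts - Tp)^2)/sum Ts^2`,
   which may be negative and is never clamped;
5. map the winning orbit back to the data scale by
   `F = u_t + (x_t - u_j) ds_t/ds_j` and difference it to get fitted
   annual rates.

With both series standardized, the Step-4 score equals `2 r - 1` where `r`
is the Pearson correlation between target and orbit.  The vectorized
scanner uses that identity with running sums (`sum x`, `sum x^2`,
`sum Ts*x`), so the full coarse grid (801 x 400 logistic candidates, ~1.3e8
cubic candidates) is evaluated without materializing any orbit matrix.
The reported `r2` of a `FitResult` is always recomputed from the stored
series with the explicit Step-4 formula; the running-sum form only ranks.

**Alignment.** The scored sequence is the orbit *including* the initial
condition, `[x0, x1, ..., x_{n-1}]`, aligned with the window years.  The
alternative (the image sequence `[x1..x_n]`, which is what the Step-5
formula literally writes) is implemented behind `GridConfig.alignment`;
the orbit convention is the default because the published reference
moments of the winning orbit (mean 0.03685, SD 0.02211 for 136 iterates
from k=1.065, x0=0.001983) match it exactly and the image variant does
not.

**Grids.** Logistic: `k` on [0, 4] step 0.005, `x0` on (0, 0.2] step
0.0005, then two refinement passes shrinking both steps x10 around the
incumbent (final resolution 5e-5 in `k`, 5e-6 in `x0`).  Cubic: `k1` on
[0.9, 1.3] step 0.005, `k2` on [0, 5] step 0.05, `k3` on [0, 60] step 0.5,
`x0` on (0, 0.05] step 0.0005, same refinement scheme; the box brackets
all published optima for this family with margin while keeping the coarse
sweep near 1e8 cheap evaluations (about 3 minutes on one core).  Each
refinement pass re-scans +/-30 fine steps (= +/-3 coarse cells) around the
incumbent, clipped to the original ranges -- wide enough that the cell of
the continuous optimum is always inside the window even when the coarse
argmax lands a couple of cells away along the ridge.  Ties on the score
break toward smaller `k` (then `k2`, `k3`), then smaller `x0`,
deterministically.

**Numerical guards.** Cubic orbits can run away for admissible-looking
coefficients; any state with magnitude beyond `blowup_bound` (default 10)
marks the candidate divergent -- counted and discarded, never fatal, and a
typed `DivergentOrbit` error outside the scanner.  Candidates whose orbit
variance falls below a relative floor (1e-12 of the mean square) are also
discarded: near-fixed-point orbits have running-sum variances dominated by
cancellation error, which otherwise manufactures spurious correlations
above 1.

**Identifiability: the (k, x0) ridge.** On S-shaped targets the score
surface is a long flat ridge: slightly smaller `k` with slightly larger
`x0` produces a nearly identical standardized orbit.  On noiseless
synthetic targets the ridge is flat to below 1e-8 in `R^2`, i.e. below the
resolution at which float64 scores can be ordered reliably, so the
practical resolution of `k` is of order 1e-4 even though the final grid is
5e-5.  Interval estimates are out of scope (the search is an argmax, not a
likelihood), but `search_log` records every pass so the flatness is
inspectable.

## Comparison fits and model ranking

The linear and exponential fits are ordinary least squares of `S` and
`ln S` on the 0-based window index (R^2 for the exponential is on the log
scale; the slope there is the Malthusian growth constant, with per-year
base `e^a`).  Intercepts depend on the index origin and are reported but
not emphasized.

Models are ranked by the **derivative-level** score: the fitted cumulative
series is differenced (the fitted derivative for year `y` is
`F(y) - F(y-1)`, so the first window year carries none), the observed
rates over the compared years are standardized, the fitted derivatives are
expressed in that same frame, and the Step-4 formula is applied.  A
constant derivative (the linear model) scores near zero by construction;
the exponential model's derivatives overshoot grossly on this kind of data
and score deeply negative -- negative values are reported as-is.  Level
R^2 is displayed alongside but never used for ranking: an almost perfect
level fit with the wrong increment mechanism extrapolates poorly.

## The synthetic data generator

`generate_series` emulates exactly the structure the estimator assumes: a
true map generates a latent level curve; an affine frame
(`scale_mean`, `scale_sd`; default 427.75/252.88, the moments of the
historical Italian cumulative series) gives it realistic magnitudes; first
differences become annual increments; Gaussian noise of SD `noise_sd`
(rate units; 0 by default -- the estimator itself is deterministic) is
added to the increments; increments are truncated at zero because a crude
rate cannot be negative, and the truth record counts how many were
substantively truncated (below -1e-9; converged orbits produce +/-1e-16
increment round-off that clipping cannot distort).  Noise enters on
increments, not on levels, because the observable is the annual rate.

Two honest limitations of this design surfaced in testing and are part of
the documented behavior:

* a fast-saturating orbit mapped through a wide frame can place early
  *levels* below zero; `recovery_experiment` therefore narrows the frame
  per draw so the noiseless level series stays positive (fitting
  standardizes, so the frame cannot change recovery difficulty);
* for `k > 2` the logistic orbit overshoots its fixed point, so some true
  increments are genuinely negative and the non-negative-rate observation
  model censors them; noiseless recovery for such truths can be biased by
  up to ~0.1 in `k`.  Exact noiseless recovery (to the ridge-resolution
  limit above) holds for the uncensored draws, and the recovery table
  exposes `n_truncated` so the two populations are separable.

What passing synthetic tests do **not** show: real rate series have
autocorrelated and heteroscedastic disturbances, demographic composition
effects and reporting-regime changes, none of which the generator
emulates.

Replicate seeds derive from the experiment seed by fixed offsets
(`seed + 100003*(i+1) + 1009*j`, kept below 2^31), so any single replicate
is individually reproducible.

## Packaged data and study defaults

The packaged fixture is the transcribed Italian total series (year, rate;
1873-2010, 2-decimal precision).  Accumulation starts at the default base
year (the first year, 1873) and the fitted window opens two years later
(1875-2010, 136 observations), matching the original study design of
fixing the initial condition just after the 1873-75 boom; both are
configuration.  The published study also reports `n = 147` in one place
(which would be 1864-2010); 147 is not reachable from the printed series,
which starts in 1873, and the discrepancy is simply noted.  Sex-specific
series were not transcribable from the available source tables, so
subgroup behavior is covered by the synthetic suite instead; the pipeline
runs unchanged on any subgroup CSV.

The standardization stores the population SD (251.95 for the fixture
window); the published SD of 427.75-mean target, 252.88, matches the
sample (n-1) convention.  Both the Step-4 score and the Step-5 rescaling
are invariant to that choice, so it affects printed moments only.

Change-point years (1876, 1893, 1961, 1984, 1996 in the original
analysis) are accepted as annotations in the configuration and carried
into reports; they are never computed here -- the Bayesian change-point
method is out of scope.

## Reproducibility and problem sizes

Every stochastic component draws from `numpy.random.default_rng` seeded
explicitly; pipelines are deterministic end-to-end and machine-readable
reports are byte-identical across reruns (fixed key order, no
timestamps).  The default test suite runs the full logistic search many
times (about half a second each), one full cubic search (about three
minutes), and a 150-fit recovery experiment (about a minute); the
acceptance script runs only the logistic search and finishes in seconds.
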