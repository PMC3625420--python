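# Methods

## Model

Choice behavior in a two-alternative free-choice concentration task is
modeled as a sequence of Bernoulli visits whose success probability (visit
to the sweeter option) is a three-parameter Weibull psychometric function of
the relative stimulus intensity `x = |c1 − c2| / mean(c1, c2)`:

```
Ψ(x; m, s, π_l) = ½ [ π_l + (1 − π_l)(2 − exp(−exp( (2sm/ln 2)(ln x − ln m) + ln ln 2 ))) ]
```

- `m` (threshold, dimensionless, > 0): intensity of half-asymptotic
  performance. With no lapsing, `Ψ(m) = 0.75` exactly; in general
  `Ψ(m) = 0.75 − 0.25 π_l`.
- `s` (slope, dimensionless, > 0): the slope at threshold of the underlying
  discrimination function `F = 2Ψ − 1`. Note that `dΨ/dx` at `m` is `s/2`
  when `π_l = 0`, because mapping `F` onto the 2-AFC scale halves all
  derivatives; the package's tests verify the parameterization through `F`.
- `π_l` (lapse rate, in [0, 1)): probability of a stimulus-independent
  visit. A lapsing forager hits the sweeter option at the 0.5 chance rate,
  so the upper asymptote sits at `1 − π_l/2`, and the lapse implied by an
  observed asymptote is `2(1 − upper)`.

Aggregated over a day, the likelihood of `k` visits to the sweeter option
out of `n` is Binomial(`n`, `Ψ(x)`). The independence assumption ignores
serial correlation within a visit stream; the sequential analysis below
addresses that aspect separately.

## Priors and posterior computation

Priors follow the study protocol: threshold ~ Normal(1, 0.5), slope ~
Normal(2, 1), both truncated to (0, ∞); lapse ~ Beta(2, 20), deliberately
wider than the 0.01–0.10 range typical of human work because exploratory
foraging inflates lapsing. Truncation renormalization constants are
omitted — they change the evidence, never the posterior shape. A flat slope
prior (improper uniform on (0, 50]) is available to remove prior shrinkage
where slope bias itself is under study.

Sampling uses an affine-invariant ensemble sampler (emcee) on the
transformed coordinates `(ln m, ln s, logit π_l)` with the corresponding
Jacobian, so positivity and the unit interval need no rejection. The
ensemble (32 walkers by default) starts in a 0.05-radius ball around the
posterior mode found by Nelder–Mead; the default run keeps 5,000 pooled
post-burn-in draws, discarding the first ~20 % of each chain. Reported
estimates are posterior means with central 95 % quantile intervals (the
natural reading of interval estimates from MCMC draws); highest-density
intervals would differ only for markedly skewed marginals. Diagnostics
(mean acceptance fraction, per-parameter effective sample size via ArviZ)
ride along in the summary. Runs are bit-for-bit reproducible given the
seed.

An independent brute-force check, `grid_posterior`, integrates the same
unnormalized posterior on a 3-D grid: a coarse pass over a range covering
well beyond 99.9 % of the prior mass locates the posterior bulk, a fine pass
(220 × 220 × 160 by default) is then spent on the interval holding all but
~1e−6 of the mass. If coarsening the final grid by half shifts the total
mass by more than 1 %, a resolution error is raised rather than returning a
doubtful oracle value. Sampler and grid agree within Monte-Carlo error
(3 standard errors, SE = posterior SD / √ESS) on every tested dataset; the
heavy-tailed flat-prior slope posterior needs longer chains (≈8,000 draws)
for its mean to stabilize, which the affected tests use.

With the likelihood disabled (`likelihood_weight=0`, a testing hook) the
sampler reproduces the prior means — truncated-normal means 1.028 and 2.055,
Beta mean 2/22 — within Monte-Carlo error. Credible-interval calibration is
checked the standard way: truths drawn from the prior, data simulated, 95 %
intervals required to cover at ≥ 90 % over 50 replicates.

## Event-log reduction

The pipeline consumes visitation logs (columns: day, time_s, bee_id,
feeder_id, color, concentration, rewarded) and per-day condition tables.
Choices made during the initial sampling/exploration phase are excluded by
dropping each marked bee's first 800 visits *per day* — reversals reset the
task daily, so the cut restarts daily rather than accumulating across days.
The unmarked pool, which cannot be separated into individuals, is cut by
`800 × n̂` visits per day, where `n̂` = total unmarked visits / mean daily
visits of marked bees (bees with ≥ 50 visits on a day). Daily responses are
`k/n` for visits to whichever color is sweeter that day; the two reversal
presentations of a condition are pooled by summing counts (equivalently, a
visit-weighted mean response). Days with no surviving visits are explicit
missing markers, never 0 or 0.5; equal-concentration days keep their counts
but are flagged (intensity NaN) and excluded from fits.

Secondary analyses:

- **Concordance**: Spearman rank correlation between marked and unmarked
  daily responses, midranks for ties, with the classical
  `S = (1 − ρ) n(n² − 1)/6` reported alongside. On the built-in day table
  this gives ρ = 0.904/0.909 for the two colonies against the published
  0.92/0.91 — the printed responses are rounded to two decimals, which
  creates rank ties the raw data evidently did not have (the published
  integer S = 18 is recovered exactly under one ordering of the tied pair),
  so the tests assert agreement at print-rounding precision.
- **Non-reward rates**: per-day proportion of visits falling within the
  refill delay at lower- vs higher-concentration feeders, compared by
  two-sided paired t test across days; zero-variance difference vectors
  return a flagged result instead of raising.
- **Sequential choice**: on high-intensity days (default 0.67), for bees
  whose preference for the sweeter color exceeds 90 % within their first
  800 visits, the probability of sampling the low-concentration color after
  two consecutive sweeter-color visits with outcomes RR, RN or NN (reward/
  non-reward, order-sensitive; NR pairs are outside the tested set). Paired
  t tests contrast NN against RN and against RR — the negative-incentive
  predictions that a win-stay/lose-shift forager should satisfy.
- **Learning curves**: proportion of sweeter-color visits in consecutive
  bins of 100, final partial bin reported with its size.

## Synthetic colony generator

The generator is the ground-truth instrument for every pipeline stage,
emulating the statistical structure of the apparatus: per bee and day, a
visit budget is drawn from a lognormal with mean 1,076 and SD 642 visits
(matching the observed marked-bee daily activity); inter-visit intervals
are exponential at the rate spending the budget over a 12-h session — the
simplest renewal process producing realistic refill-delay collisions, in
lieu of any published timing distribution. Color choice per visit is
Bernoulli with probability from the bee's true curve at the day's
intensity; feeders within a color class are uniform; a feeder rewards a
visit only if it last dispensed more than 10 s earlier, so the non-reward
rate is an emergent function of forager density (it increases monotonically
with colony activity, reproducing the ~50 % rates seen at high traffic).
An optional learning ramp pulls choice probability from 0.5 toward the
stationary curve as `1 − exp(−k/τ)` in visit number `k`; with
`τ ≈ 150` visits the asymptote is effectively reached within 400–600
visits, the observed acquisition scale. Unmarked foragers are simulated as
individuals and logged under the shared label, reproducing the information
loss the real reader suffers.

What the generator does *not* model: spatial feeder geometry and
traplining, handling times, nectar depletion/energetics, day-to-day
carryover of preferences (each day's choices are conditionally independent
given the curve), and any sequential reward-memory effects. Passing
round-trip tests therefore validates the bookkeeping and estimation
machinery, not these behavioral phenomena.

## Pooling-bias experiment

Seven individual curves share slope 5 and lapse 0.15 but differ in
threshold (mean 0.25, SD 0.057); their predicted performances at
intensities {0.05, 0.15, 0.25, 0.3, 0.4, 0.5, 0.6} are averaged with 200
visits each (1,400 per intensity) and refit under a flat slope prior. The
default threshold set is deterministic — an evenly spaced symmetric grid
rescaled to the exact mean and sample SD — with an option to draw normally
instead; the default count construction is noise-free
(`k = round(1400 · mean Ψ)`), with a binomial-sampling mode available.
The refit recovers threshold (≈0.250) and lapse (≈0.15) but puts the slope
near 4.2, well below the common truth of 5: averaging sigmoids with
scattered inflection points flattens the aggregate sigmoid. The bias
direction persists in ≥ 8 of 10 replicates with redrawn thresholds and
vanishes when thresholds are homogeneous.

## Numerical choices and edge cases

- The double-exponential argument is clamped to |700|, which only takes
  effect where the curve is already within double-precision distance of an
  asymptote.
- `psychometric_inverse` bisects on `ln x` after geometric bracket
  expansion; robust for all valid parameters, no derivatives needed.
- Log-posterior evaluations clip Ψ into (1e−300, 1 − 1e−16) before taking
  logs; parameter values outside the prior support yield −∞ by contract
  rather than raising.
- Fits with fewer than three distinct intensities warn and, with a single
  intensity, flag the posterior as prior-dominated; fitting proceeds.
- Degenerate paired t tests (zero variance of differences) return a
  flagged result object.
- Problem sizes in tests (visit budgets, replicate counts, draw counts) are
  chosen to keep each estimate's Monte-Carlo error far below the tolerance
  it is compared at.

## Known limitations

- The binomial likelihood ignores within-day serial correlation; effective
  sample sizes of real visit streams are smaller than raw visit counts, so
  credible intervals on real data are optimistic.
- The unmarked-pool plateau cut removes the first `800 × n̂` visits of the
  mixed stream, which only approximates cutting 800 visits per anonymous
  individual.
- Priors are placed directly on threshold and slope as stated by the study
  protocol; no threshold-scaled reparameterization of the slope prior is
  attempted.
- The published day table prints responses to two decimals and visit totals
  in thousands; analyses reconstructed from it (concordance, unmarked-bee
  refit) inherit that rounding, and their tests use correspondingly widened
  tolerances.
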