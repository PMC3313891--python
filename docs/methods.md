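# Methods

## The reconstruction model

A published Kaplan-Meier curve summarizes right-censored time-to-event data
through the product-limit estimator

S(t_m) = ∏_{j=1..m} (n_j − d_j)/n_j,  with  n_{m+1} = n_m − d_m − c_m,

where d_m, c_m and n_m are the events, censorings and at-risk count at the
m-th step.  Digitizing the plot yields coordinates (T_k, S_k), k = 1..N,
with T_1 = 0 and S_1 = 1; publications additionally print the number at
risk `nrisk_i` at a handful of times `trisk_i` (defining `nint` intervals
over the coordinate rows) and sometimes the total number of events
`totevents`.  The reconstruction inverts the product-limit recursion under
one structural assumption: **censoring occurs at a constant rate within
each risk interval** (reasonable when censoring is non-informative).  The
procedure per interval i:

1. *Initial censoring guess.* Under no censoring the at-risk count at the
   next published time would be `round(nrisk_i · S_next/S_cur)`; the
   shortfall of the published `nrisk_{i+1}` against that is the initial
   censoring count. Negative guesses are floored at 0 (a risk set cannot
   grow).
2. *Placement.* The censorings are spread evenly over the interval at
   `t_lo + c·(t_hi − t_lo)/(ncensor+1)` and counted into the half-open
   coordinate bins [T_k, T_{k+1}).
3. *Propagation.* Walking the coordinates, each survival drop is converted
   to an integer event count `d_k = round(n_k (1 − S_k/S_last))`, where
   `S_last` is the running KM estimate at the most recent event coordinate
   (digitized curves need not step at every click, so the last-event index
   is tracked explicitly); then `n_{k+1} = n_k − d_k − c_k`.
4. *Re-adjustment.* The interval's censoring count is shifted by the
   boundary residual `n̂(trisk_{i+1}) − nrisk_{i+1}` and steps 2-3 repeat
   until the propagated at-risk count equals the published one.
5. The *last interval* has no published risk number at its end; its
   censoring count is the prior total scaled by the interval's span
   relative to the time already elapsed, capped at the number still at
   risk.
6. If `totevents` is reported, the last interval's censoring count is
   further shifted by the running event surplus until the reconstructed
   total matches, or censoring is exhausted.  If the total is already
   exceeded before the last interval, that interval is frozen (no further
   events or censorings).

Four **information levels** select which stages run: `all_information`
(everything), `no_total_events` (stop after step 5), `no_numbers_at_risk`
(one interval, censoring grown from 0 against the event total), and
`neither` (no censoring assumed — a single propagation pass; expectedly
the least accurate, particularly for hazard ratios, since the risk sets
late in follow-up are then systematically overstated).

IPD derivation is mechanical: one `(T_k, 1)` record per reconstructed
event, one `(cen_t, 0)` record per placed censoring, and subjects still at
risk after the final coordinate are censored at T_N so that the record
count always equals the initial number at risk.

## Numerical choices

* **Rounding** is half-to-even everywhere ("round to nearest integer"),
  centralized in one helper, matching the IEEE default of the numerical
  environments this kind of analysis is run in.
* **Bins are half-open** [T_k, T_{k+1}) so a censor time on a shared
  boundary is counted exactly once.  (The even-spacing formula keeps times
  strictly inside the interval, so boundary hits only arise from duplicate
  coordinates, which get zero-width bins and no mass.)
* **Integer safeguards:** d_k is clamped to [0, n_k]; a censor count that
  would drive the risk set negative is trimmed; once the risk set or the
  KM estimate reaches 0, later event counts are forced to 0 with a warning
  if the digitized curve still decreases.  These guards make the
  life-table identity n_{k+1} = n_k − d_k − c_k an exact integer invariant
  of every output, whatever the input quality.
* **Iteration control:** the re-adjustment loops (steps 4 and 6) are
  integer-valued fixed-point iterations; they are capped at 1000 passes
  with cycle detection, returning the best state visited plus a diagnostic
  rather than looping forever on inconsistent inputs.  Unattainable
  published targets (e.g. a risk number larger than achievable with zero
  censoring) produce a warning and the propagated count is carried forward
  so conservation still holds.
* **Determinism:** the reconstruction itself contains no randomness.

## Input handling

Digitized input is click data: survival values that *increase* between
consecutive coordinates are clamped down to the running minimum (with a
warning; `strict=True` makes them fatal), values outside [0, 1] are
clipped, and published risk times must match a curve coordinate within an
absolute + relative tolerance of 1e-6 + 1e-4·t, since exact float equality
is unreliable after digitization.  Repair is idempotent.  Number-at-risk
columns must be positive and non-increasing; risk intervals must tile the
coordinate rows contiguously.  `nrisk_i` is interpreted as the risk set
*just before* `trisk_i` (subjects with observed time ≥ trisk_i), the
convention used by risk tables under KM plots and the one consistent with
the boundary-matching step.

## Survival statistics

The product-limit estimator uses the events-before-censorings convention
for ties.  Confidence intervals use Greenwood's variance on the log-S
scale, `S·exp(±1.96·se(log S))` — the default of the R `survival` package
that such reconstructions are usually compared against — with a
complementary log-log variant behind `conf_type="loglog"`.  The median is
the first event time with S ≤ 0.5 (no interpolation); its CI endpoints are
the first times the respective confidence bands reach 0.5.  The two-arm
hazard ratio maximizes the Cox partial likelihood for a single binary
covariate by Newton's method (start 0, gradient tolerance 1e-9, max 50
iterations, step halving), with Efron's tie correction by default and
Breslow behind a flag for cross-checks; the SE of log HR comes from the
observed information.  When all events fall in one arm the maximizer
diverges and the estimate is reported as unbounded with a warning.

## What the simulator emulates — and what it does not

`synthetic` draws exponential or Weibull event times per arm with
independent uniform or exponential censoring and an administrative cutoff,
then renders the *exact* digitization of each arm's KM plot: a coordinate
at t = 0, one at every distinct event time carrying the exact product-limit
value, and a terminal coordinate at the end of follow-up.  Risk tables are
derived by direct counting at caller-chosen coordinate times (default: five
roughly equally spaced times, mimicking the four-or-five printed in real
publications), and the true event count supplies `totevents`.

This validates the algorithmic chain, not the human one.  Real digitized
data have click-placement error, missed steps, and axis-calibration bias;
the optional `DigitizationNoise` (Gaussian jitter plus step dropping) is an
explicit stand-in with no empirical calibration, and it is off by default.
Passing pipeline tests therefore demonstrate correctness of the inversion
given faithful coordinates; accuracy on a blurry scanned figure is bounded
by digitization quality, which is out of scope.  Two useful calibration
points from the test suite: with no censoring and perfect coordinates the
reconstruction is *exact* at every event time regardless of information
level, and with censoring the reconstructed KM estimate stays within one
integer-rounding step (1/min n̂_k) of the digitized curve wherever patients
remain.

## Accuracy evaluation

Errors are measured on the natural scale for survival probabilities and on
the log scale for medians, hazard ratios and their standard errors
(multiplicative error is the natural description for ratio-type
quantities).  `mean_error` reports bias with a normal-theory CI.
`mean_abs_error` reports the typical magnitude of a single error; its CI
describes the *distribution* of absolute errors, obtained by folding
Monte-Carlo normal draws with the observed mean and variance (150 000 draws
by default, configurable down for tests).

`variance_components` fits a balanced two-way random-effects ANOVA
(exemplar × observer with replicates, computed via statsmodels) and solves
the expected-mean-square equations, pooling the interaction into
within-cell error when its F-test p-value exceeds 10%.  Reproducibility is
σ_r = √(σ²_within + σ²_interaction + σ²_observer) — the error of a single
observer reconstructing once — and σ_e is the exemplar SD, how much
accuracy depends on which curve is reconstructed.  Negative moment
estimates are clamped to 0 (standard practice).  CIs are obtained by
resampling each mean square as SS/χ²(df) and re-solving; this is the
natural reading of "sampling the degrees of freedom" for scaled chi-square
mean squares, and the interpretive choice is noted here deliberately.

`recovery_study` chains everything: simulate → digitize → risk table →
reconstruct at each information level → re-estimate → compare.  The
human-observer factor is *emulated* by replicate digitization-noise seeds;
with noise off, observer and replicate dimensions are degenerate and only
ME/MAE are reported.  Default problem sizes in the study and test suite
(e.g. 200 subjects/arm, exponential rates 0.1 vs 0.07, uniform(0, 30)
censoring with administrative cutoff 25 — about 35-40% censored) were
chosen as typical of oncology RCT reports; they reproduce the expected
qualitative gradient: survival probabilities and medians are nearly
insensitive to the information level, while hazard-ratio accuracy degrades
sharply when neither risk numbers nor event totals are available.

## Known limitations

* Curves that pool over prognostic covariates reconstruct pooled data;
  subgroup KM curves or covariate adjustment are impossible by design.
* The constant-within-interval censoring assumption cannot recover
  informative or heavily clustered censoring patterns.
* Reconstruction quality is bounded by digitization quality; the package
  repairs monotonicity violations but cannot detect calibration bias.
* The Cox fit covers exactly one binary covariate (the two-arm contrast);
  multivariable models should be fitted on the derived IPD with a general
  survival package.
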