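# Methods

`ceatopo` implements the quantitative core of a rostro-caudal
circuit-topography study of a genetically defined central-amygdala
(CeA) population: peri-event statistics on single-cell calcium traces,
linear-versus-sigmoid encoding-model comparison with neuron-resampling
bootstrap, and the battery of tracing-topography statistics (expression
cutoff, connectivity-correlation clustering, starter-location
relationships, an AP-shuffle permutation test, local-connectivity
regressions, and anterograde AP-bias comparisons).  Because the
underlying recordings and histology are not deposited, every analysis
is exercised end-to-end on synthetic cohorts with planted ground
truth; the seeded generators are first-class, tested code.

## Trace normalization and peri-event windows

Traces are neurons x frames fluorescence at a fixed frame rate
(default 6 frames/s, the miniscope acquisition convention).  Two
normalizations serve two kinds of comparison:

* **dF/F** for across-time comparisons: `(F - F_mean) / F_mean` with
  `F_mean` the per-neuron mean over the entire recording.  Invariant
  to multiplicative rescaling; undefined (and rejected, naming the
  neuron) when `F_mean = 0`.
* **Peri-event z-score**: `(F - F_mean) / F_sd` with moments over the
  union of a designated baseline period and the event's pre-stimulus
  window.  `F_sd` is the sample (n-1) standard deviation — a
  convention that must be fixed for oracles to match; we use the
  sample form throughout.  Invariant to positive affine transforms.

Peri-event slicing maps the event onset to the first frame at or after
the onset time and includes that frame, so a +/-10 s window at
6 frames/s is exactly 121 frames.  Default windows are 10 s before and
after tone (CS) and shock (US) onsets and 5 s around freezing bouts.

## Response classification

A neuron is *excited* by a stimulus if either sub-criterion fires:

1. a two-sided Wilcoxon signed-rank test of response-window versus
   baseline-window frames rejects at `alpha = 0.05` with a positive
   median shift, or
2. the trapezoidal AUC of the response window divided by its length
   exceeds `auc_factor = 2` times the absolute length-normalized
   baseline AUC.

*Inhibited* is the mirror image, so negating every trace swaps excited
and inhibited calls exactly; both sub-criterion outcomes are stored
for audit.  Zero differences are dropped (Wilcoxon convention) and we
use scipy's hybrid exact/normal-approximation p-values (exact for
small tie-free samples, tie- and continuity-corrected normal
approximation otherwise).  No multiple-testing correction is applied
across neurons; downstream summaries report raw proportions, with
uncertainty from a 10 000-resample neuron bootstrap.

Two calibration caveats, both visible in the test suite:

* the AUC criterion's `|2x baseline|` threshold collapses when the
  baseline AUC is near zero — exactly the situation for z-scored or
  dF/F null traces — so on null data the OR-criterion responsive rate
  is dominated by AUC false alarms (~0.33, stable across seeds) while
  the signed-rank rate stays at ~alpha/2 per direction.  Calibration
  claims therefore attach to the signed-rank sub-criterion;
* with unequal window lengths the signed-rank test falls back to a
  one-sample comparison against the baseline *mean*, whose own
  sampling noise becomes a common offset across response frames; for
  long response windows this is anticonservative.  Equal-length
  windows keep the test paired and calibrated, and are used wherever
  calibration matters.

Per-trial response magnitude (for learning-modulation calls) is the
mean z-score in the response window.  A neuron's trajectory across
trials is *increasing* if the OLS slope of magnitude on trial number is
significantly positive (slope testing requires at least three trials)
or, failing that, if frame-level first-versus-last-trial samples differ
by signed-rank with positive shift.  Trial cross-correlation is
zero-lag Pearson per neuron.  Response latency is the time from onset
to the first post-onset frame at or above `threshold_sd = 2` sustained
for at least 2 frames, computed on z-scored snippets.

## Encoding-model comparison

Stimulus-period activity (dF/F, t = 0-60 s from first contact) is fit
per neuron with an OLS line and with the four-parameter logistic
`y(x) = c / (1 + exp(-k*(x - x0))) + y0`.  The logistic optimizer is
bounded (k > 0; x0 within the window +/-30 s; c, y0 free) to kill the
mirror-image duplicate optimum, and multi-start: a data-driven primary
start plus a grid over k in {0.02, 0.1, 0.5} 1/s and x0 at the time
quartiles.  An optional linear-limit start (k -> 0 with c*k/4 matched
to the OLS slope) makes the logistic family effectively nest the line;
it guarantees `r2_sig >= r2_lin` but also lets the sigmoid chase noise
on truly linear data, so it is off by default.

Goodness-of-fit change is `delta_se = se_lin - se_sig` with
`se = sqrt(SSE / (n - p))` (residual standard error; p = 2 or 4), so
the sigmoid pays for its extra parameters.  Population statistics
(slope, R^2, k, delta_se) are bootstrapped by resampling neurons
(default 10 000 resamples); two populations' bootstrap distributions
are compared with an unpaired two-sided t-test.  That t-test inherits
inflated degrees of freedom from `n_boot` and is anticonservative by
construction; `bootstrap_difference_ci` provides a percentile-CI
alternative and is the better-calibrated summary.

A structural limit worth knowing: because the logistic family nests
the line, on truly linear data the fitted sigmoid's SSE advantage is
distributed roughly as sigma^2 * chi-square(2), while `delta_se > 0`
corresponds to an advantage of about 2*sigma^2.  A perfect optimizer
would therefore call ~37% of truly linear neurons "sigmoid-preferred"
regardless of noise level or sample size, capping sign-of-delta_se
discrimination accuracy near 82% on balanced ramp/sigmoid populations
(our optimizer measures ~87%: it recovers only part of the
noise-chasing gain).  Population-level separation by the bootstrap
route is unaffected and extremely strong.

## Tracing-topography statistics

Retrograde cohorts are tidy tables of per-subject labeled-cell counts
by region and hemisphere.  Regions are retained when their mean
across-subject fraction of the subject's total labeled cells strictly
exceeds 0.5% (`cutoff_fraction = 0.005`).  Connectivity structure is
the region x region Pearson correlation of per-subject *fractions*
(normalizing out injection efficiency), clustered by average linkage
on distance 1 - r; the cut (cluster count or height) is a parameter.
Each cluster's mean penetrance is correlated with the count-weighted
starter-cell AP centroid per subject; positive r means penetrance
rises toward less negative AP and is labeled *rostral*, negative
*caudal* (AP in mm relative to bregma, negative = posterior).

The in-plane test computes, per subject, the Pearson correlation of
(input count, starter count) over AP-ordered sections; the null
permutes the input counts' section assignment within subject (1000
shuffles, starter counts fixed) and records the mean shuffled r.  Real
versus mean-shuffled r are compared across subjects with a paired
two-sided signed-rank test.  Under a generative null the permutation
mean tracks the small negative bias of the per-subject r, so the
paired test holds its nominal size (measured rejection ~0.05 over 200
null cohorts) with power ~1.0 at planted r = 0.6 with 12 subjects of
10 sections.

Local connectivity is simple OLS of neighboring labeled-cell counts on
the starter subnucleus mix per (source, target) pair with 95% CIs.
Anterograde tables carry injection-normalized fluorescence per AP
level; a subject's *bias* is the OLS slope across AP levels (1/mm,
negative = rostral weighting), and rostral-versus-caudal target
differences use a two-way (group x target) ANOVA with Sidak-adjusted
(`1 - (1-p)^m`) per-target comparisons.  Incidence contrasts on binary
outcomes (k/n per group) report both the tie-corrected Mann-Whitney
p and Fisher's exact p.

## Synthetic cohorts

The generators are pure functions of (spec, seed) and emit planted
ground truth alongside the data.

* **Trace cohorts**: constant baseline (default 5 a.u.) plus additive
  i.i.d. Gaussian noise; responder classes are apportioned by the
  largest-remainder method (deterministic, sums exactly).  Templates
  lock to event onsets: transients rise instantly and decay
  exponentially (tau = 1 s default), ramps rise linearly during the
  event (default slope 1/60 a.u./s over a 60 s stimulus), sigmoids
  follow the logistic above (default c = 1, k = 0.2 1/s, x0 = 30 s).
  With zero noise each trace equals its analytic template to machine
  precision.  Real recordings add drift, correlated noise, bursty
  transients, and uneven amplitudes — none of which are modeled — so
  passing recovery tests demonstrates correctness of the estimators
  under their own assumptions, not robustness to real-data artifacts.
* **Tracing cohorts**: 12 subjects by default, split between rostral
  and caudal injection targets (AP centroids jittered around the two
  poles of the declared AP range, mirroring -1.0/-1.75 mm targets).
  Region counts are Poisson around a log-linear mean in the
  standardized AP centroid; a cluster's coupling in [0, 1] scales the
  log-slope (gain 1.5 per unit coupling).  Section series pair a
  Gaussian starter profile with input counts built from a correlated
  latent mix targeting the requested in-plane r (exact integer-affine
  coupling in the noiseless |r| = 1 case).  `count_noise="none"`
  replaces Poisson draws with rounded means for exactness tests.
* **Projection tables**: per-subject linear AP trend of the requested
  bias slope plus Gaussian noise, with an intercept large enough to
  keep fluorescence positive.

## Reproducibility experiments

`ceatopo.experiments` packages the study-condition experiments the
test suite and `scripts/acceptance.py` run: null-classifier
calibration (1000 neurons), sigmoid recovery (200 neurons, k = 0.1,
x0 = 30 s, 10% noise), ramp-versus-sigmoid discrimination (200 per
class), permutation-test size and power (200 cohorts each), two-block
cluster recovery, and direction recovery over 100 seeded cohorts.
These sizes keep the full suite within a few minutes on one core while
leaving Monte-Carlo error well below the margins being tested; all
randomness flows from explicit seeds.

## Known limitations

* The AUC response criterion is only meaningful when the baseline has
  non-negligible signed area (see caveats above).
* The bootstrap-distribution t-test mirrors the bootstrapped-distribution
  procedure it implements; for inference, prefer the percentile CI.
* Sign-of-delta_se model discrimination has the ~82% theoretical
  accuracy ceiling on balanced cohorts derived above.
* Hemisphere labels are carried through the tables but the topography
  statistics sum across hemispheres.
* No atlas geometry, image registration, or signal extraction: the
  package consumes extracted traces and count tables.
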