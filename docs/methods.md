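# Methods

## Signal model and time conventions

A secretion trace is the mean fluorescence of one microwell referenced to
its first frame, in arbitrary units linear in captured cytokine
(subtraction, not ratio, so units stay linear).  Time is hours since
stimulus addition; the first scan falls at one scan interval (defaults:
4 min for mouse-style runs, 15 min for human-style runs).  Before its
secretion onset a cell's noise-free signal rises with a slow drift slope
`a` (nonspecific accumulation); from the onset `t̂` it rises with slope
`b > a`:

    signal(t) = a·t  for t < t̂;   b·(t − t̂) + a·t̂  for t ≥ t̂.

The model is continuous at `t̂` by construction.

## Online onset detection

During an experiment the decision to recover a cell must be causal.  At
each new frame an OLS line is fitted to the signal history excluding the
last `window = 3` samples, and the cell is flagged when all three exceed
their predicted value by `sd_multiplier = 1` standard deviation; the flag
time is the time of the first exceeding sample.  Truncating a trace
anywhere past the flag never changes it.

Two standard deviations are defensible readings of "one standard
deviation", and they behave very differently:

* **residual SD** of the history regression — scale-free: with iid
  Gaussian noise, each evaluation has a ≈0.4% chance that three
  consecutive points all clear a 1-SD threshold, independent of the noise
  level.  Over an 8-h / 4-min trace (~110 evaluations) this accumulates
  to a per-trace false-alarm probability of tens of percent, which makes
  unattended monitoring useless.
* **SD of the raw past signal values** (default, `sd_mode="signal"`) —
  inflated by the accumulated drift, so the threshold grows with
  observation time and drift-only traces almost never trigger, while a
  genuine onset (slope step of `b − a` per frame) still clears it within
  one or two frames.

With the default configuration (`sd_mode="signal"`, regression on all
history excluding the window, `min_baseline_points = 25`, i.e. a 100-min
warm-up at 4-min scanning) the measured operating characteristics on the
default simulation conditions (drift 0.1, slope 2.0, noise 0.04 — a
per-frame signal-to-noise of ≈3) are: detection ≈96% of secreting cells,
median flag delay ≈1.4 scan intervals, false-positive rate ≈1–3% on
drift-only traces.  The residual-SD mode and a sliding-window history are
kept as options (`sd_mode="residual"`, `history=<n>`); the residual mode
is only usable with a human confirming each notification.  Cells whose
onset falls inside the warm-up period are the main source of missed
detections.

A flag with zero threshold SD but strictly exceeding samples (possible on
noiseless data) counts as a trigger; a float-rounding guard
(1e-9 × signal scale) prevents noiseless ramps from tripping it.

## Offline onset refinement

For fixed `t̂` the two-segment model is linear in `(a, b)`
(design columns `min(t, t̂)` and `max(t − t̂, 0)`), so the SSE is profiled
exactly: conditional linear least squares at every sample time, then
bounded 1-D minimisation between the neighbours of the best grid point
(`xatol = 1e-9`).  This finds the global optimum without an initialisation
dependence; a supplied `t_init` (e.g. the online flag, standing in for a
visually determined onset) is added to the candidate set but never
restricts the search.  Ties break to the smallest onset.  When
`b − a < 1e-6` signal-units/h the two segments are indistinguishable and
the fit is flagged unidentifiable (`converged=False`); no `b > a`
constraint is imposed during fitting.  Measured accuracy at the default
SNR: median |t̂ − truth| ≈ 0.07–0.09 scan intervals over 200 traces.

Δt (onset → recovery) is binned to the nearest of {0.5, 1.0, 1.5} h
within a ±0.1 h tolerance, else "other".  Two-channel onset order uses
the fitted onsets with a simultaneity tolerance of one scan interval by
default.

## Count model of the synthetic generator

Counts are negative binomial with var = μ + φμ² (dispersion φ = 0.2 by
default), gene baselines lognormal (median 20, log-SD 1), per-cell
library factors lognormal (median 1, log-SD 0.3) applied to endogenous
genes only.  Spike-in rows emulate exogenous reference RNA added at a
fixed amount per sample: constant mean, no state effect, no library
factor.  Planted classes multiply the NB mean by `2^±effect_log2fc` in
the states their transition mode affects (four-state set: EIG up at
transition+activated, ERG down there, LIG/LRG up/down only at activated,
SIG up only in silent, TIG up only at transition; three-state set: EIG,
LIG, LEG, TRG, TIG).  Gene means are absolute by default; a
`relative_abundance` switch rescales each cell's endogenous means to a
common total for purely compositional simulation.  Secreting-cell
assignment in the trace generator is by deterministic quota (first
⌈frac·n⌉ cells) so truth counts are exact; onset latencies are lognormal
(median 2.5 h, log-SD 0.5 — a broad several-hour spread) truncated 1 h
before the end of observation so every assigned onset is observable.
The generators do not model optics (evanescent-field decay,
photobleaching), cytokine diffusion, donor effects, or gene-gene
correlation; noise is iid Gaussian per frame for traces.  Passing tests
on these data shows the estimators are correct under the stated models,
not that the models exhaust real LCI-S or scRNA-seq structure.

## Normalisation for classification

CPM (columns scaled to 1e6) is provided and used for fold-change
computations, but the classification stages default to
log2(count / size factor + 1) with DESeq-style median-of-ratios size
factors (reference genes: endogenous, positive in every cell; spike-ins
excluded since they do not scale with cellular RNA content; total-count
fallback when no reference gene exists).  Rationale: CPM is compositional
— when a large gene block is induced in one state, every unregulated
gene's CPM drops there, and with 900 four-fold planted genes among 2900
this makes ~40% of truly null genes ANOVA-significant.  The pipeline
additionally runs the selection twice, excluding first-pass hits from the
size-factor reference, which removes the residual composition leak (null
rejection returns to the nominal α).  `scale="cpm"` restores plain CPM.

## Gene selection and class assignment

One-way fixed-effects ANOVA per gene across the activation states
(α = 0.05 four-state, α = 0.01 three-state); for multi-donor designs the
observations are per-donor state means, removing bias from unequal cell
numbers per state.  Genes constant everywhere get F = 0 / p = 1; zero
within-group variance with differing means is reported as p = 0 with a
degeneracy flag.  Selected genes are summarised as per-state mean
profiles (per-donor first when applicable), z-scored per gene, clustered
with K-means (Euclidean, 50 restarts, fixed seed; k = 14 / 8), and each
centroid is assigned to the template class with maximal Pearson
correlation (templates are the ±1 patterns implied by the class
definitions; below `min_correlation = 0.6` a cluster is unclassified).

A gene keeps its cluster's class only if its own profile (i) correlates
≥ `min_correlation` with the class template and (ii) swings ≥
`min_amplitude = 1.0` log2 units (2-fold) between its extreme states.
The amplitude floor exists because, at α = 0.05 over thousands of null
genes, the false positives that survive the F-test have template-like
shapes but hair-thin amplitudes; requiring a conventional minimal fold
keeps them out of the induced/reduced classes without touching the test
level.  Measured planted-class recovery at the default study conditions
(6 × 150 planted genes at 4-fold, 2000 nulls, 50 cells/state, k = 14):
per-class precision 1.00, recall ≥ 0.97.

Snapshot DEG selection applies the sequential filters: expressed
(count > 0) in more than 4 cells, mean-CPM fold ≥ 4 (pseudocount 1,
stated direction), two-sided Mann-Whitney, Benjamini-Hochberg adjustment,
adjusted p < 0.05 (the FDR < 0.1 reading of the BH step is retained as a
documented alternative threshold, not applied by default).  The direct
transient-induction rule requires transition > pre and
transition > activated, each with a one-sided Mann-Whitney at α = 0.05
and fold ≥ 2; these defaults are package choices for an idea stated
without thresholds.

## Survival analysis

Nelson-Aalen over distinct event times: Ĥ(t) = Σ dᵢ/nᵢ, variance
Σ dᵢ/nᵢ²; the secreting proportion is 1 − exp(−Ĥ) (the estimator named
for the curve), with a Kaplan-Meier-based proportion exposed for
comparison.  95% bands are built on the log-cumulative-hazard scale
(Ĥ·exp(±1.96·SE/Ĥ)) and mapped through 1 − exp(−·); at Ĥ = 0 the band is
degenerate at 0.  Cells that never secrete are censored at their last
observed scan.  The two-group log-rank test pools ties within each event
time and uses the hypergeometric variance; all-censored input yields a
flat zero curve and statistic 0 / p 1 rather than an error.  Measured
type-I calibration: 4.8–6.4% rejections at α = 0.05 over 1000
equal-hazard cohorts of 200 + 200 cells.

## qPCR utilities

ΔΔCt with either a calibrator sample or the mean ΔCt of a calibrator
group (single cells rarely offer one canonical calibrator); samples with
an undetected reference Ct are dropped and counted, never imputed.  The
variance-ratio F-test doubles the smaller tail for a two-sided p (capped
at 1, hence invariant under group exchange); a zero denominator variance
against a non-zero numerator reports (∞, 0) by convention.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
outputs byte for byte, including K-means (fixed `random_state`).  The
bundled verification runs use 200-trace detector cohorts, 5000-gene null
matrices, the 2910 × 200 planted classification matrix and 1000 log-rank
replicates of 200 + 200 cells — sizes chosen so the full suite completes
in seconds on a single core while leaving Monte-Carlo standard errors
well inside the asserted bands.

## Known limitations

* The online rule's operating characteristics are tied to the drift/noise
  regime; real baselines with structured (non-iid) noise will need the
  warm-up length and SD mode revisited.
* Median-of-ratios normalisation assumes a majority of unregulated,
  reasonably expressed genes; very sparse matrices fall back to
  total-count scaling.
* The class templates encode idealised ±1 patterns; intermediate kinetics
  (e.g. a gene induced at transition that decays halfway by the late
  state) map to whichever template correlates best.
* Per-donor averaging treats donors as exchangeable; no donor-specific
  baseline shifts are modelled or removed beyond the averaging itself.
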