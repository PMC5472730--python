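# Methods

This note documents the models and numerical choices behind `crossreact`:
what the synthetic generator does and does not emulate, how each analysis is
computed, and where the design was genuinely open.

## Task and trial clock

Each trial runs: 200 ms fixation → 500 ms offer-1 cue (grey = described,
white = experienced) → 750 ms offer-1 reveal (color symbol or direct water
delivery; sizes 75/100/150/200/250 µl) → 500 ms offer 2 (natural-scene
symbol; 150/175/200 µl) → 200 ms re-fixation → choice period of variable
duration → 300 ms chosen-option feedback → 750 ms outcome (reward delivery)
→ 1000 ms inter-trial interval. All times are stored per trial relative to
offer-1 cue onset (= 0 ms); trial type, offer sizes and offer-1 side are
randomized independently per trial. A choice is *correct* when the chosen
size is at least the unchosen size; on this 5×3 design a coin-flip chooser
scores 56.67% and a reward maximizer takes offer 1 on 40% of cells (exact
ties credited ½ — the only convention consistent with both numbers).

## Synthetic sessions

The generator is a first-class, tested component, not a fixture: it
instantiates the reactivation hypothesis as a generative model with known
ground truth so the analysis chain can be validated by parameter recovery.

**Choice model.** P(choose offer 1) = lapse/2 + (1−lapse)·σ(β_T(V₁−V₂)+b_T)
with per-type inverse temperature β_T and offer-1 bias b_T. Defaults
(β_D = 0.0219, β_E = 0.0327 µl⁻¹, b_D = 0.197, b_E = 0.172, lapse = 0.02)
were solved analytically so that expected accuracy is 81.72% on described
and 88.29% on experienced trials (85.0% overall) with a mild offer-1
preference (45.5%/43.1% against the 40% optimum) — the behaviour of the
recorded animals this package's analyses were built around.

**Spiking model.** Neuron *i* has a log-normal baseline (median 5 Hz,
log-SD 0.6, a typical cortical rate distribution) and four weights drawn
independently across neurons: structure-specific value weights
b_assoc_D, b_assoc_E ~ N(0, 0.005 Hz/µl), a reward-general weight
b_general ~ N(0, 0.007 Hz/µl), and a choice gain b_choice ~ N(0, 0.3 Hz).
The instantaneous rate is baseline everywhere except:

- during the 750 ms offer-1 reveal: + b_assoc[type]·offer1_size;
- during the 750 ms outcome epoch: + (b_assoc[type]+b_general)·reward
  + b_choice·1[chose offer 1].

Rates clip at zero; counts are Poisson per 10 ms bin with spike times
uniform within the bin. The weight SDs were calibrated once so that the
recovered overlap correlations fall in the 0.2–0.4 range and the cross-type
outcome transfer decodes near ~32%, matching the magnitudes the analyses
were designed to detect; tuned fractions come out at roughly 10–25% of
neurons per epoch. Because b_assoc_D and b_assoc_E are independent draws,
offer codes are unrelated across structures *by construction* — the
defining property the pipeline must recover.

**Decision time.** The choice period is uniform on 500–3000 ms (10 ms
grid). The mean (1.75 s) places mean reward delivery ≈ 4 s after cue onset,
consistent with the common-clock trial layout of the motivating experiment,
and its spread is what smears outcome-locked signals in common-clock
analyses while leaving per-event-aligned analyses untouched.

**What it does not emulate.** One simulated session records all 125 neurons
on the same 450 trials, whereas real recordings were collected serially and
pooled as a pseudo-population; shared-trial data have a far lower effective
noise floor in population-level statistics (see "Known limitations").
Refractoriness, adaptation, correlated noise, over-dispersion and
single-trial rate variability beyond Poisson spiking are deliberately
absent, so passing tests demonstrate correctness of the analysis chain and
recoverability of the planted architecture — not biological realism.

## Encoding analyses

Rates are counted in 10 ms bins aligned to the offer-1 cue, converted to
Hz, and z-scored per neuron over every recorded bin of the session (bins
past a trial's span are missing, not zero). PSTHs are smoothed with a
200 ms boxcar, truncated at series edges. Analysis windows (half-open,
per-trial event-aligned):

- offer 1: [200, 500) ms after value reveal;
- outcome: 400 ms centered on the population encoding peak (mean |t| of the
  outcome-size regression in a sliding 300 ms window over the 750 ms
  epoch; ties to the earliest bin, clipped to the epoch);
- offer 2: 300 ms, likewise peak-centerable, default [100, 400);
- choice: the 1000 ms ending at reward delivery (700 ms pre-choice plus
  300 ms feedback), since the choice period's duration varies by trial.

Tuning is OLS of the z-scored epoch-mean rate on size in raw µl (slopes are
therefore small, ~10⁻³ per µl), solved for all neurons at once as a batched
least-squares problem with a shared design matrix; outcome regressions use
offer-1-chosen trials (so the delivered reward equals the offer-1 size), or
all trials with a binary choice covariate in the alternative model. Neurons
need ≥ 10 usable trials. The census counts p < 0.05 slopes, tests the
fraction against 5% (one-sided binomial), and tests the sign split
(Pearson goodness-of-fit against ½) with the squared-odds effect size
(k/(n−k))².

## Overlap statistics

Signed and unsigned Spearman correlations (average ranks) between two
per-neuron slope vectors, with asymptotic p-values and a predictor-shuffle
permutation null: each of 1000 iterations permutes the predictor rows
independently within each of the two regressions, refits every neuron, and
correlates the shuffled slope vectors; the significance cutoff is the 95th
percentile of that null and the empirical p uses the +1 correction.
Fisher-z comparison of two correlations uses the independent-samples
formula, or a Steiger-style dependent form with SE = √(2(1−r_cross)/(n−3))
when the two correlations share neurons. Cook's distance from the OLS fit
of one coefficient set on the other screens for influential neurons at the
4/n threshold (an exact fit returns all-zero distances). Encoding-strength
comparisons are t-tests on squared coefficients with bias-corrected
Hedges' g.

## Decoding

A population activation state resamples, independently per neuron and with
replacement, one trial from each offer-size × trial-type group and averages
its z-scored rates over the epoch window; 500 states per condition (100 per
size class), emitted interleaved so contiguous cross-validation folds stay
class-balanced. Outcome-epoch states are built from offer-1-chosen trials.
A size group with no trials at all is imputed at 0 (the z-scored mean) and
flagged; more than half the groups empty is an error.

The decoder is a 125-40-5 network: h = logistic(W₁x), y = softmax(W₂h), no
bias terms, weights initialized U(−0.01, 0.01), trained for 1000 sweeps of
per-sample gradient-ascent updates (ΔW = 0.005·∂logL/∂W) in a freshly
shuffled order each sweep — no momentum, regularization or early stopping.
The per-sample gradient function is shared between the training loop and a
finite-difference test. Within-condition decoding uses 4-fold
cross-validation (375 train / 125 test); cross-condition transfer trains on
all states of one condition and tests on all states of the other (the two
sets share no samples, so folding adds nothing, and the actually tested n
is reported). Significance is a one-sided goodness-of-fit chi-square of the
correct count against 20% chance. A one-vs-rest linear SVM provides an
independent maximum-margin cross-check with the same report format.

## State space

Epoch-state matrix: 2 trial types × 5 epochs (offer-1 cue, offer-1 value,
offer 2, choice, outcome; all 300 ms) × mean z-scored rate per neuron;
PCA is column-centered without scaling, with component signs fixed by
making each loading vector's largest-magnitude element positive. The
distance analysis slides a 300 ms window (100 ms steps) along the common
cue-aligned clock from cue onset to the median trial's end of outcome,
computing the full-neuron-space Euclidean distance between the two types'
mean states (a PC-subspace variant was considered and rejected: the
distance is defined on states, and projecting first would entangle it with
the PCA's rank choice). Because trials end at different times, late windows
average over the trials still in progress (NaN-aware means; windows with
< 25% of trials are dropped). The null band shuffles trial-type labels
across trials 1000 times and reports pointwise mean, 2.5%/97.5% cutoffs and
+1-corrected p-values. Note the permutation-floor property: the distance of
two finite-sample means is positive even under the null, so the band's
lower cutoff sits above zero.

## Numerical choices and degenerate inputs

- One root seed fans out to every stage through `numpy` SeedSequences; all
  reported statistics reproduce bit-for-bit for a fixed seed.
- Chi-square tests are Pearson without continuity correction; binomial
  tests are exact; effect sizes for two-proportion comparisons are odds
  ratios (boundary proportions raise rather than being continuity-fudged).
- Complete separation in the choice-curve fit is flagged and the slope
  capped instead of diverging.
- A neuron with zero rate variance (no spikes) is an error naming the
  neuron; a constant predictor within a trial selection is an error rather
  than a silent NaN.
- The correlation power analysis is n = ((z₁₋α/2 + z_power)/atanh r)² + 3,
  rounded, floored at 4.

## Test-scale choices

The unit suite runs scaled-down sessions (20 neurons, 200 trials) for
speed; the end-to-end recovery checks use the full default conditions (125
neurons, 45 trials per group) over five generator seeds, pooling decoder
transfer counts across seeds because a single 500-state condition carries
~1.8 percentage points of binomial noise. Null-calibration checks use 500
scaled-down replicates (20–30 neurons/trials, 99-iteration nulls).

## Known limitations

- **Shared-trial sessions are cleaner than pseudo-populations.** With all
  125 neurons sharing one trial set, the label-shuffle distance band is
  tight enough to resolve the residual outcome-epoch separation that the
  planted structure-specific outcome weights necessarily produce (the
  described/experienced mean states differ by (b_D−b_E)·E[reward] at
  outcome, as they differ by (b_D−b_E)·E[offer] during the reveal). The
  package therefore reproduces the *ordering* — offer-epoch separation
  exceeds outcome-epoch separation, which also converges through the
  maintenance and choice periods — but a full return to non-significance at
  outcome is not attainable in shared-trial data with outcome reactivation
  planted at full strength; in serially recorded data the between-session
  noise floor hides it.
- **Rectification couples structures weakly.** Because firing rates clip
  at zero, every tuned neuron's class-mean profile is slightly convex in
  offer size, most so for low-baseline neurons — and baselines are shared
  across trial types. Extreme offer sizes therefore carry a weak
  type-independent signature that a five-class decoder can exploit: the
  cross-structure offer transfer sits ~1–2 percentage points above chance
  (e.g., ~21.7% pooled over seeds against 20%) even though the signed code
  correlation is zero by construction and stays inside its permutation
  band. The rank-correlation overlap statistic is blind to this channel;
  the decoder is not. At the trial counts of typical recordings the effect
  is far inside the chance band and invisible.
- The generator's linear-in-µl tuning matches the analysis model by
  design; rank-coding or saturating neurons are out of scope.
- The paired Fisher comparison implements the independent and
  Steiger-style forms; dependent comparisons require the user to supply the
  cross-correlation between the shared coefficient vectors.
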