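# crossreact

Analysis toolkit for a question in the neuroscience of economic choice: when
a subject evaluates an offer, does the orbitofrontal population *reactivate*
the neural response it produces when the corresponding reward is actually
delivered — and is that reactivated code specific to the *associative
structure* through which the offer was revealed?

The task it models is a two-option riskless choice in which offer 1 is
revealed either symbolically (a learned color cue, "described" trials) or by
direct delivery of a water aliquot ("experienced" trials), while offer 2 is
always symbolic. Described and experienced offers predict the same rewards
through different associative event sequences, so comparing their codes
separates structure-specific from reward-general value coding.

`crossreact` provides, as a library plus a thin CLI:

- **synthetic sessions** with known ground truth: Poisson spike trains whose
  per-neuron linear tuning instantiates the hypothesis (structure-specific
  offer coding; structure-specific *plus* reward-general outcome coding) and
  a calibrated logistic choice model (`crossreact.synthetic`);
- **behavioural statistics**: design-derived chance levels by enumeration,
  chi-square/binomial tests with odds-ratio and split-odds effect sizes, the
  logistic choice-curve fit, and the Fisher-z power analysis for
  correlations (`crossreact.behavior`);
- **encoding**: 10 ms binned, z-scored rates, epoch windows (including
  peak-encoding window placement), per-neuron OLS tuning regressions and
  the tuned-population census (`crossreact.encoding`);
- **the overlap statistic**: signed and unsigned (absolute-value) Spearman
  correlations between per-neuron coefficient vectors from two epochs, with
  predictor-shuffle permutation nulls, Fisher-z comparisons, Cook's-distance
  outlier screening (`crossreact.overlap`);
- **population decoding**: resampled pseudo-population activation states and
  a from-scratch 125-40-5 softmax network trained by per-sample gradient
  ascent (scikit-learn estimator interface), plus a maximum-margin
  cross-check decoder, for within- and cross-epoch/cross-type transfer
  (`crossreact.decoding`);
- **state-space trajectories**: PCA of epoch-averaged population states and
  the sliding Euclidean distance between trial types against a label-shuffle
  permutation band (`crossreact.state_space`).

## The statistics at the core

For neuron *i*, epoch *e* and trial type *T*, the tuning slope
*B*<sub>*e,T,i*</sub> is the OLS coefficient of the z-scored epoch-mean rate
on offer/outcome size (µl). The overlap between two codes is

&nbsp;&nbsp;signed: ρ = Spearman(*B*<sub>offer,*T*</sub>, *B*<sub>outcome,*T*</sub>) — shared coding scheme,
&nbsp;&nbsp;unsigned: ρ = Spearman(|*B*<sub>offer,*T*</sub>|, |*B*<sub>outcome,*T*</sub>|) — shared participation,

tested against the 95th percentile of correlations obtained by refitting all
regressions with predictors randomly permuted (1000 iterations). The decoder
is a three-layer network, hidden *h* = σ(W₁x), output *y* = softmax(W₂h),
trained by stochastic gradient ascent on the multinomial log-likelihood
(learning rate 0.005, 1000 sweeps, weights initialized U(−0.01, 0.01), no
biases/momentum/regularization); above-chance transfer from outcome states
to offer states (or across types) indicates a shared code.

## Worked example

```
$ crossreact simulate --seed 1 --out session/
wrote 450 trials, 2029588 spikes to session/
$ crossreact behavior --trials session/trials.csv --out session/
correct 89.11% (chance 56.67%), offer-1 38.22% (optimal 40.00%)
$ crossreact overlap --trials session/trials.csv --spikes session/spikes.csv \
    --seed 1 --out session/
OFR.D-OTC.D: r=+0.402 (perm p=0.0010, cutoff=0.151)
OFR.E-OTC.E: r=+0.202 (perm p=0.0130, cutoff=0.147)
OTC.D-OTC.E: r=+0.362 (perm p=0.0010, cutoff=0.146)
OFR.D-OFR.E: r=+0.079 (perm p=0.2018, cutoff=0.149)
```

The session simulates 125 neurons over 450 trials. The behaviour line says
the simulated chooser takes the larger reward 89% of the time against the
56.67% a coin-flip chooser would score on this offer design, and takes
offer 1 on 38% of trials (a reward maximizer would on 40%). The overlap
lines are the four pairwise coefficient correlations: offer and outcome
coding correlate within each trial type (r = 0.40, 0.20 — outcome-code
reactivation during evaluation), outcome coding correlates across the two
trial types (r = 0.36 — a shared reward-general component), while offer
coding does not (r = 0.08, inside the permutation null band — structure-
specific evaluation codes). Each r is printed with its permutation p and the
95% null cutoff; the first three exceed their cutoffs, the last does not,
which is the generator's planted architecture recovered from spikes.

`crossreact encode`, `decode`, and `trajectory` write the per-neuron
coefficient tables and census, the cross-epoch transfer matrix with
confusion counts, and the PCA/distance series, in the same JSON/CSV style.

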