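# Methods

This note documents the analysis definitions, the generative model behind the
synthetic sessions, the default parameters, and the known limitations. All
quantitative statements about the synthetic data are properties of the model
and are exercised by the test suite; nothing here is a claim about biological
recordings.

## Experimental design assumed by the analyses

A session contains an odour block of 16 stimuli — 15 odorants plus an
odourless control (stimulus id 0) — each presented 8 times in pseudorandom
order without immediate repeats (128 trials). Presentation cycles 1–4 carry a
like/dislike rating, cycles 5–8 a 4-alternative forced-choice identification.
An optional matched picture block presents 16 images with the same design.
Neurons carry a region label: PC (piriform cortex), AMY (amygdala), EC
(entorhinal cortex), HIP (hippocampus), PHC (parahippocampal cortex).

## Analysis definitions

**Rates and z-scoring.** Spike counts are taken in half-open windows relative
to stimulus onset via binary search; rates are counts divided by window
length. The z-scored rate of a trial is `(r − mean_b) / sd_b`, where `mean_b`
and `sd_b` (ddof = 1) are taken over that neuron's per-trial baseline rates —
window [−5, 0) s for odours, [−0.5, 0) s for images; the response windows are
[0, 2) and [0, 1) s. Neurons whose baseline rates have zero variance cannot
be z-scored; they are excluded from the matrix and reported.

**Stimulus-modulated neurons.** Per neuron, a one-way ANOVA of z-scored
response rates across the 16 stimulus identities (the control is a regular
16th group), alpha = 0.05, uncorrected. With the full design the degrees of
freedom are (15, 112). Rows with zero variance everywhere get F = 0, p = 1.

**Decoding.** The classifier computes class-mean templates on training trials
and assigns a test trial to the class whose template has the highest Pearson
correlation with it; exact ties, and correlations undefined because a vector
is constant, are resolved by a seeded uniform draw among the tied (or all)
classes. Pseudopopulations pool neurons across sessions: for each neuron the
trials of each class are shuffled independently, so pseudotrials assume
independence across neurons given the stimulus. Accuracy is the mean over 8
cross-validation splits and 10 within-split resampling runs, averaged over
random neuron subsamples of fixed size. The null distribution permutes labels
before template building; `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.
Chance is 1/16. Cross-modal decoding trains templates on one modality and
tests on the other with matched stimulus ids.

**Sparseness.** For stimulus *k*, with `x_i` the trial-averaged **raw** rate
of neuron *i* (control trials excluded, z-scored input rejected):
`A_k = (mean_i x_i)^2 / mean_i(x_i^2)` and `SI_k = (1 − A_k) / (1 − 1/N)`.
`SI` is scale-invariant, 0 for a uniform population and 1 for one-hot.
Regions are compared by a one-way ANOVA over per-stimulus SI values plus
Tukey HSD.

**Repetition suppression.** Per neuron, the least-squares slope of z-scored
response rate against presentation cycle 1–8 (control trials excluded).

**Valence.** Per neuron, the liked-minus-disliked mean z contrast
(rating-phase trials); population test: two-sided signed-rank. Against a
15-element reference valence, the per-odour population-mean z is
Spearman-correlated with a seeded permutation p-value. Note that with
narrowly tuned neurons the per-neuron contrast is structurally mixed-sign
(a neuron preferring a disliked odour has a negative contrast), so the
population correlation, pooled over enough neurons that every odour is
represented, is the more powerful readout of valence-scaled gain.

**Count statistics.** Exact binomial tail probabilities (two-sided via the
small-p convention: sum of all outcome probabilities ≤ that of the observed
count), pooled two-proportion z-tests, and seeded Spearman/sign permutation
tests all use add-one permutation p-values where applicable.

## Generative model

Each neuron is an inhomogeneous Poisson process with a piecewise-constant
rate. Baseline rates are log-normal (median 2 Hz, log-sd 0.5). A tuned
neuron's rate steps to a plateau from `latency` to `latency + duration` after
onset of a stimulus it responds to:

```
rate = baseline * (1 + nonspecific + gain * strength * v_mod) * d^(c−1) [* PC cycle-1 boost]
```

- `strength` is 1 for a preferred odour, `off_preferred_factor` for other
  odours (graded tuning, piriform only), 0 otherwise. Preferred-set sizes are
  drawn around the region's `tuning_breadth`.
- `gain` is gamma-distributed with region-specific mean and shape 4.
- `v_mod = 1 + valence_gain * v_k` in the amygdala only; odour valences
  `v_k ~ U(−1, 1)` are shared across a cohort. Ratings are Bernoulli with
  `P(liked) = logistic(2 v_k)`; identification is correct with
  probability 0.75.
- `d = suppression_decay` multiplies the response on each successive cycle;
  piriform additionally gets a ×1.5 first-cycle boost.
- Control trials evoke `baseline * (1 + nonspecific + gain * 0.3)` in
  odour-tuned neurons.
- `nonspecific` is a sniff-driven, stimulus-independent response present in
  every piriform neuron and identical across all 16 stimuli, including the
  control and including untuned neurons — so it carries no identity
  information and preserves the ANOVA null for untuned neurons.
- A fraction of odour-tuned neurons (`cross_modal_overlap`) is also tuned to
  the matched images; a small extra fraction is image-only.

Inter-trial intervals are 19.4 ± 0.4 s, so response windows never overlap
baselines of neighbouring trials.

### Default parameters

| Parameter | PC | AMY | EC | HIP | PHC |
|---|---|---|---|---|---|
| neurons / session | 20 | 26 | 18 | 24 | 16 |
| tuned fraction | 0.40 | 0.20 | 0.14 | 0.12 | 0.05 |
| tuning breadth (mean # preferred) | 4.0 | 1.0 | 1.5 | 1.0 | 1.5 |
| gain mean | 5.0 | 16.0 | 8.0 | 24.0 | 4.0 |
| off-preferred factor | 0.4 | 0 | 0 | 0 | 0 |
| nonspecific (sniff) gain | 1.5 | 0 | 0 | 0 | 0 |
| response latency (s) | 0.2 | 0.2 | 0.8 | 0.8 | 0.8 |

Scalars: response duration 1.5 s; control response factor 0.3; suppression
decay 0.95/cycle; PC first-cycle boost 1.5; valence gain 0.5 (AMY);
identification accuracy 0.75; cross-modal overlap 0.2; image-only tuned
fraction 0.05.

The regional contrast — broad, moderate-gain, sniff-responsive piriform
versus sparse, strong, one-hot medial-temporal responses — is what makes the
piriform population code measurably less sparse (lower SI) than amygdala and
hippocampus while keeping identity decodable in all tuned regions. Two
quantitative consequences worth noting:

- Log-normal baseline spread alone puts a floor on SI of roughly
  `1 − exp(−σ²) ≈ 0.22` at log-sd 0.5, so regional SI differences ride on top
  of that floor and need pooled cohorts (≈12 sessions) to resolve reliably.
- With one-hot tuning, a neuron's mean response across the 15 odours
  (≈ gain/15) is *below* its control response (0.3 × gain), so the
  positive odour-minus-control population contrast is a property of the
  broadly tuned piriform population, not of the narrow regions.

## Numerical and implementation choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohort generation derives child seeds below 2^31 from a parent seed.
- Spike times are written with full `repr` precision and parsed with
  round-trip float parsing, making `write_session`/`read_session` a byte-exact
  identity on re-write.
- Standard statistics (ANOVA, Mann–Whitney, Wilcoxon, Tukey HSD, binomial
  tests) come from scipy/statsmodels; study-specific machinery (classifier,
  pseudopopulations, sparseness, permutation schemes, generator) is
  implemented here and checked against brute-force oracles in the tests.

## Limitations

- Poisson spiking with a piecewise-constant rate: no refractoriness,
  bursting, oscillatory coupling, or within-trial dynamics beyond a single
  plateau; latencies are constant per region.
- Trial independence: apart from deterministic repetition suppression there
  is no drift, adaptation across the session, or behavioural state.
- The pseudopopulation construction assumes neurons are conditionally
  independent given the stimulus; real simultaneous recordings have noise
  correlations the synthetic data cannot exhibit.
- Valence, behaviour, and cross-modal structure are deliberately simple
  (linear gain, logistic rating, fixed identification accuracy) — sufficient
  for parameter-recovery tests, not for modelling behaviour.
- Region profiles are stylised defaults chosen to realise the qualitative
  regional contrasts above; they are not fits to any dataset.
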