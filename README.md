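# odorcode

Analyses for human single-neuron odour-coding experiments, together with a
seeded synthetic-session generator for end-to-end validation.

The experimental design the package targets: micro-wire recordings from the
piriform cortex (PC) and medial temporal lobe — amygdala (AMY), entorhinal
cortex (EC), hippocampus (HIP), parahippocampal cortex (PHC) — while a
participant smells 15 odorants plus an odourless control, each presented for
8 cycles (128 odour trials; cycles 1–4 with like/dislike ratings, cycles 5–8
with forced-choice identification), optionally followed by a matched
16-picture block.

## What it computes

- **Session I/O and validation** (`odorcode.session`): a plain-text session
  format (`neurons.tsv`, `spikes.tsv`, `trials.tsv`, `session.json`) with a
  lossless round trip, structural validation with coded issues, and rate
  matrices — raw firing rates in a response window, or rates z-scored against
  each neuron's pre-stimulus baseline distribution (neurons with zero baseline
  variance are excluded and logged).
- **Stimulus-modulated neurons** (`odorcode.responsiveness`): per-neuron
  one-way ANOVA across the 16 stimulus identities on baseline-z-scored rates
  (response window [0, 2) s vs baseline [−5, 0) s for odours; [0, 1) vs
  [−0.5, 0) for images), alpha = 0.05 uncorrected; baseline-z-scored PSTHs;
  odour-vs-control firing contrasts.
- **Identity decoding** (`odorcode.decoding`): maximum-correlation classifier
  (nearest class-mean template by Pearson correlation, seeded random
  tie-breaking), pseudopopulations assembled from neurons pooled across
  sessions with within-class trial shuffling, 8-fold cross-validation over
  random neuron subsamples, label-permutation null distributions with add-one
  p-values, window-length / population-size sweeps, cross-modal
  (image-to-odour) decoding, and chemical-label vs perceived-label decoding.
- **Population statistics** (`odorcode.popstats`): per-stimulus population
  sparseness (activity ratio `A = (mean x)^2 / mean(x^2)` and sparseness
  index `SI = (1 − A) / (1 − 1/N)` over raw trial-averaged rates, control
  excluded) with a cross-region ANOVA + Tukey comparison, repetition
  suppression (per-neuron slope of z-scored rate over the 8 presentation
  cycles), valence analysis (liked-vs-disliked contrasts and per-odour
  population response vs reference valence, seeded permutation p-values),
  exact binomial session-count tests and two-proportion z-tests.
- **Synthetic sessions** (`odorcode.simulate`): a seeded inhomogeneous-Poisson
  generator with known ground truth — per-region tuned fractions, response
  gains and tuning breadths, response latencies, repetition suppression,
  amygdala-only valence gain, cross-modal overlap, and behaviour (ratings,
  identification accuracy) — used throughout the test suite for parameter
  recovery and calibration checks. See `docs/methods.md` for the model.
- **Pipeline + CLI** (`odorcode.pipeline`, `odorcode.cli`): `odorcode
  simulate | detect | decode | run-all | report | binom` over the on-disk
  session format.

## Worked example

```python
import numpy as np

import odorcode as oc
from odorcode.session import ODOUR_BASELINE_WINDOW, ODOUR_RESPONSE_WINDOW

# One synthetic session: 16 stimuli (15 odours + odourless control) x 8 cycles.
session, truth = oc.generate_session(seed=42)
trials = session.odour_trials()
rates = oc.compute_rate_matrix(
    session, trials, ODOUR_RESPONSE_WINDOW, "zscored", ODOUR_BASELINE_WINDOW
)
labels = np.array([t.stimulus_id for t in trials])

# Stimulus-modulated neurons: one-way ANOVA on z-scored rates, alpha = 0.05.
results = oc.detect_modulated_neurons(rates, labels)
by_region = {r.neuron_id: r for r in results}
for region in ("PC", "AMY", "EC", "HIP", "PHC"):
    ids = [n.neuron_id for n in session.neurons_in_region(region)]
    sub = [by_region[i] for i in ids if i in by_region]
    frac = oc.modulated_fraction(sub)
    print(f"{region}: {sum(r.modulated for r in sub):2d}/{len(sub):2d} modulated ({frac:.0%})")

# Odour-identity decoding in piriform with a max-correlation classifier.
cfg = oc.DecodingConfig(n_neurons=15, n_subsample_runs=20, n_permutations=200, seed=0)
dec = oc.population_decoding_with_null([session], "PC", cfg)
print(f"PC decoding: {dec.accuracy:.3f} (chance {dec.chance:.4f}, p = {dec.p:.4f})")

# Population sparseness from raw trial-averaged rates, control excluded.
raw = oc.compute_rate_matrix(session, trials, ODOUR_RESPONSE_WINDOW, "raw")
for region in ("PC", "AMY"):
    ids = [n.neuron_id for n in session.neurons_in_region(region)]
    sp = oc.population_sparseness(raw.subset_neurons(ids), labels, region=region)
    print(f"{region} sparseness index: median {np.median(sp.sparseness_indices):.3f}")

# Exact session-level count statistic: 13 of 27 sessions significant at 0.05.
print(f"binomial P(X >= 13 | n=27, p=0.05) = {oc.exact_binomial_test(13, 27, 0.05, 'right'):.2e}")
```

Output (deterministic for the seeds above):

```
PC: 11/20 modulated (55%)
AMY:  8/26 modulated (31%)
EC:  4/18 modulated (22%)
HIP:  2/24 modulated (8%)
PHC:  1/16 modulated (6%)
PC decoding: 0.332 (chance 0.0625, p = 0.0050)
PC sparseness index: median 0.204
AMY sparseness index: median 0.239
binomial P(X >= 13 | n=27, p=0.05) = 1.26e-10
```

The same flow is available from the shell:

```sh
odorcode simulate --seed 42 --out session42
odorcode detect --session session42 --out detect.tsv
odorcode binom 13 27 0.05 --sided right
```

## Layout

```
src/odorcode/      session.py  simulate.py  responsiveness.py
                   decoding.py  popstats.py  pipeline.py  cli.py
tests/             unit, property, calibration and acceptance tests
scripts/           acceptance.py
docs/methods.md    generative model, analysis definitions, limitations
```
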