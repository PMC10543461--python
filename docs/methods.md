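# Methods

`riskseq` predicts whether a patient with a qualifying mental-health
diagnosis will acquire a new adverse-event diagnosis within the next 90
days, and screens every input feature for risk or protective association
with that outcome. This note records the model and procedure choices, the
synthetic study conditions, and the limits of what the synthetic results
demonstrate.

## Cohort construction

Input is a long-format event table (one row per patient, date, code).
For each patient the first *qualifying* diagnosis date anchors follow-up.
An adverse-event type counts as a **new onset** only when its first record
postdates that anchor; types already recorded before or on the anchor are
pre-existing, and such patients stay eligible for new onsets of *other*
types, with the pre-existing records kept in the history as ordinary
features.

One training sample is one (patient, index date) pair. Case patients
contribute one sample for every encounter between the anchor and the first
new onset whose 90-day window contains that onset (encounter-level
augmentation); each sample's history is truncated at its index date, so
the onset record itself is never visible. Control samples are encounters
with no adverse-event record in the following window, drawn uniformly
without replacement to `round(control_sampling_ratio x n_case_samples)`
(default ratio 1.0). By default encounters of case patients are not
control-eligible (`allow_case_patients_as_controls=False`): window-missing
encounters of a future case are ambiguous, and excluding them is the
conservative choice. Splitting into train/validation/test (8:1:1 by
default) is by *patient*, because augmented samples of one patient are
near-duplicates and sample-level splitting would leak them across folds
and inflate AUROC. No censoring correction is applied at the end of
follow-up: absence of a record in the window is taken as absence of the
event, as in retrospective EMR extracts.

## Encoding

A visit is the set of tokens sharing a calendar date. Tokens are
`DX:<cluster>`, `RX:<id>`, `LAB:<code>:<flag>` (flagged results only —
normal labs carry no token), `SD:<code>` for individual social
determinants (age binned to decades), and `NB:<feature>:Q<k>` for
zip-linked neighborhood features discretized by rank-based quantile bins
(quintiles by default; bins are computed over the zip table, so same zip
implies same tokens and bin occupancy differs by at most one when values
are distinct). The vocabulary is built on the training fold only; tokens
carried by fewer than `min_patient_count` (default 10) distinct training
patients collapse to UNK, and validation/test encoding can never add
tokens. Static SDoH tokens enter the sequence as a pseudo-visit at the
start (configurable to the end); histories keep the most recent
`max_visits` visits (default 200).

## Models

Two recurrent classifiers consume identical encoded sequences; visit
embeddings are the sum of the visit's token embeddings (mean available).

* **tanh-LSTM (TLSTM)** — stacked LSTM layers in which the input, forget
  and output gates use tanh instead of sigmoid, bounding gate outputs in
  (-1, 1); the candidate update and the output probability head keep
  their conventional activations (a probability requires a sigmoid).
  Sigmoid gates remain available for ablation. "Layers" counts stacked
  recurrent layers (default 8, configurable; the scaled-down studies here
  use 2).
* **RETAIN-style** — two recurrent streams run over the visits in
  reversed time order; one yields a scalar per visit, softmax-normalized
  into visit attention weights alpha (masked positions get exactly zero),
  the other a tanh-bounded gate vector beta per visit; the context
  `sum_t alpha_t (beta_t * v_t)` feeds an affine + sigmoid head.

Training is minibatch Adam (lr 1e-3, batch 64, optional decoupled weight
decay) on binary cross-entropy, with inverted dropout (rate 0.2) between
recurrent layers, early stopping on validation AUROC with strict
improvement and patience 3 (defaults mirror the upstream configuration:
embedding 128, hidden 128, dropout 0.2, layers 8, patience 3), and the
best-validation parameters returned. Everything is implemented in NumPy
over a small reverse-mode autodiff engine (`riskseq.autograd`) whose
gradients are finite-difference-checked in the test suite; inference is
deterministic, and the whole pipeline is reproducible bit-for-bit from
(config, seed). AUROC is the midrank statistic (equal to exhaustive
case/control pair comparison); precision/recall/F1 use a 0.5 threshold by
default. `repeat_experiment` re-splits, retrains and evaluates with
derived seeds (default 10 repeats) and reports per-repeat metrics with
mean and sample SD.

## Feature attribution and the relative-contribution test

For each sample and each token occurrence, the occlusion contribution is
`score(original) - score(with that single occurrence removed)`; the visit
is kept (possibly empty) so the only change is the occurrence itself. A
seeded embedding-noise mode (mean drop under K=10 Gaussian perturbations)
is available as the stochastic alternative; occlusion is the default
because it is deterministic and reproducible. The per-patient feature
contribution FC sums a feature's per-occurrence drops over all of the
patient's samples within one label group; a patient with samples under
both labels appears once per group.

For each feature with m event-group and n control-group carriers
(both >= 2):

    RC        = mean(FC | event) / mean(FC | control)
    Var(lnRC) = (sd_e/mean_e)^2 / m + (sd_c/mean_c)^2 / n     (sample SDs)
    95% CI    = exp(ln RC +/- 1.96 sqrt(Var))
    p         = two-sided normal tail of z = ln RC / sqrt(Var)

RC > 1 is a risk factor, RC < 1 protective. Inference requires RC > 0:
two negative group means still yield a positive ratio and full inference
(protective features under occlusion have negative contributions in both
groups — the squared coefficients of variation are sign-free), while
means of opposite sign, a zero denominator, or RC exactly 1 suppress
inference (classification UNDEFINED). No rescaling of FC or RC is
applied. Bonferroni uses M = number of features with a defined p in the
run; FDR is Benjamini-Hochberg (both via statsmodels, cross-checked
against brute-force definitions in the tests). Ranked reports use the
column order Feature Name, RC, 95%CIup, 95%CIdown, FDR_Q, Bonferroni
corrected p-value, sorted by FDR_Q with undefined rows last. Attribution
runs on the test fold by default (unseen data), configurable to all folds.

## Synthetic data generator

The generator emulates a retrospective EMR extract: per-patient irregular
encounter timelines (negative-binomial encounter counts over follow-up),
multimodal codes (diagnoses, medications, labs with ABNORMAL/HIGH/LOW
flags at 10% each, individual SDoH, zip-linked neighborhood features),
and a discrete-time outcome: per 90-day window after the qualifying
diagnosis, adverse-event onset is Bernoulli with probability
`baseline_hazard` times the product of the odds factors of planted codes
present in the preceding `lookback_days` (365 by default), clamped to
[0, 1]. Planted exposures follow therapy-like episodes: per 90-day block
a carrier is on or off (episode start probability, optional Markov
persistence), and while on, the code is recorded at each encounter with
`planted_encounter_prob`. Carrier status is drawn independently per code,
or mutually exclusively (one categorical draw) to emulate alternative
first-line treatments. Randomness uses per-patient substreams spawned
from the master seed, so adding patients never reshuffles earlier ones,
and window uniforms come from a dedicated substream so raising an odds
factor can only increase onset rates (common random numbers).

What it does **not** emulate: realistic code ontologies and co-occurrence
structure, visit-pattern dependence on health state (informative
observation), measurement error, censoring by death or disenrollment, and
continuous-time dynamics. Passing tests on this generator demonstrate the
pipeline's correctness and the attribution statistic's behaviour under
known ground truth — not clinical validity on real records.

## Planted-effect recovery study conditions

The end-to-end recovery study uses 3,000 patients, one risk medication
(odds factor 4.0, carrier fraction 0.6), one protective medication (odds
factor 0.25, carrier fraction 0.3), and ~100 null code identities
(diagnoses, medications, flagged labs, SDoH tokens) independent of the
outcome. The baseline per-window hazard is 0.25 and follow-up is a single
90-day window: a Bayes-ceiling analysis of the two-carrier outcome model
shows discrimination of 0.85+ is attainable only when the risk factor
saturates the hazard clamp (0.25 x 4.0 = 1.0), and the single window
keeps per-patient sample multiplicity comparable between case and control
patients, which the per-patient summed FC statistic needs for null
calibration. Carriers are always exposed at cohort entry and re-recorded
at 20% of encounters. The classifier for this study is the tanh-LSTM
scaled down to 2 layers and 32-dimensional embeddings/hidden states,
trained at most 5 epochs — sized so the full 10-seed study runs on one
CPU in minutes; the discrimination signal saturates within these epochs
at this scale.

Known limitation, documented deliberately: with a well-fitted classifier
on this deliberately sparse feature space, occlusion contributions are
modulated by where samples sit on the output sigmoid. Event-group samples
are concentrated on the flat high-score region and control samples
nearer the steep mid-region, which (a) biases null-token RC estimates
away from 1 — their false-positive rate under FDR can exceed the nominal
level — and (b) places the protective token's event-group carriers
(mostly dual carriers of both planted codes, scored mid-range) where
occlusion rises are largest, so the protective token's RC is pulled
toward and above 1 even though its hazard effect is real. Richer,
heterogeneous backgrounds (many moderate risk factors) sharpen risk-side
recovery but do not remove either distortion. The pipeline reports these
quantities as computed; see the acceptance suite for the exact behaviour
under the stated conditions.

## Numerical choices

* Ties in AUROC use midranks; ties in quantile binning share the lower
  bin (same value, same bin).
* BCE uses a 1e-12 floor inside the logs; extreme CI half-widths saturate
  to inf/0 rather than overflowing.
* Early stopping demands strict improvement; with a constant validation
  metric and patience 1, training stops after epoch 2.
* Degenerate inputs raise typed errors: single-class training folds,
  one-class evaluation sets (AUROC undefined), empty cohorts, fewer than
  three patients at splitting.
* The Bonferroni multiplier counts only features for which a p-value is
  defined (m, n >= 2 and RC > 0).
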