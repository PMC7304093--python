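# Methods

`anotext` implements a four-stage pipeline for computer-aided therapeutic
diagnosis in anorexia nervosa, operating on short free-text statements a
patient writes about the image of their own body, together with the
evaluation scheme used to score it against expert opinion. This note
records the models, the conventions chosen where the procedure was
genuinely open, the synthetic stated world, and known limitations.

## 1. Text preparation

Statements are whitespace-tokenized, case-folded, and stripped of all
characters in Unicode categories P* and S* (edges and interiors; digits
are kept). The dictionary pathway then removes stop-listed tokens and
maps each token to its basic grammatical form through a pluggable
surface→basic lookup (`BasicFormMap`, loaded from a two-column TSV) with
identity fallback; a morphological analyzer can be slotted in behind the
same contract. Basic forms must be fixed points of the map, so
lemmatization is idempotent and conserves token count. The recurrent
pathway receives all cleaned tokens in order, without stop-listing: the
network is the only stage sensitive to word order, and its vectorization
step is defined on the raw cleaned sequence.

## 2. Document sentiment

**Dictionary score.** With P and N the positive and negative
polarity-lexicon matches counted with multiplicity over the basic-form
bag,

    S = (P − N) / (P + N),   S = 0 when P + N = 0,

and the class is sign(S) ∈ {−1, 0, +1}. This exact ratio is a
reconstruction: the source study defers its dictionary method to earlier
work, but its per-document values are precisely of this rational form
(±1.00, ±0.33, −0.82 = −9/11, −0.71 = −5/7, …) and its neutral class
coincides with S = 0 throughout. Strength tags (weak/strong) in the
lexicon are parsed but not used as weights — weighting would destroy the
observed rational values. Negation scope and intensifiers are out of
scope; the method is order-blind by design.

**Recurrent classifier.** Tokens are embedded as 100-dimensional vectors
(word2vec; a numpy skip-gram/negative-sampling trainer is included for
desk-scale corpora, and word2vec-text-format vectors can be imported).
The network is a bidirectional GRU layer of 5 units per direction whose
per-position concatenated states (10 values) feed a unidirectional GRU
layer of 5 units; the final state passes through a dense softmax over two
classes mapped to {−1, +1}. The GRU recurrence convention is

    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
    n_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ n_t

(the "5 bidirectional units" are read as 5 per direction, following the
description of separate forward- and backward-state sub-units). The loss
is categorical cross-entropy, −(1/N) Σ log p_i[y_i], natural log, with
probabilities clamped to [1e−12, 1]; optimization is Adam with
β₁ = 0.9, β₂ = 0.999. The recorded default learning rate 5e−6 is a
fine-tuning rate inherited from the transfer-learning setting (pretrain
on a large review corpus, fine-tune on the clinical corpus); for
from-scratch training on small corpora raise it to about 1e−3. Sequences
are never truncated; batches are zero-padded under a length mask that
carries hidden state unchanged through padded steps, so the final state
is each sequence's last valid state. Weights are Glorot-uniform
initialized from the config seed; gradients are exact backpropagation
through time (verified against central finite differences in the test
suite), and the forward pass is verified against an independent scalar
unroll of the recurrences above. The binary output space follows the
pretraining regime, where polarity derives from review scores: the
network never emits the neutral class.

Large-corpus pretraining itself is out of scope; the packaged `train`
workflow pretrains on a synthetic planted-polarity corpus instead, and a
single-file tensor archive (npz with an embedded JSON config) imports
externally trained weights.

## 3. Emotion-intensity profiling

An affective word list assigns each term ratings for the five basic
emotions (happiness, anger, sadness, fear, disgust) on a declared scale,
by default [1, 7]; the loader is format-compatible with the Nencki
Affective Word List, which is licensed and never bundled. A one-level
taxonomy assigns a term to the group of its strictly maximal rating when
that rating reaches a threshold θ (default: the scale midpoint); ties or
a sub-threshold maximum leave the term unassigned. Document intensity per
emotion is the mean over contributing matched tokens (with multiplicity)
of the min-max normalized rating (r − lo)/(hi − lo) ∈ [0, 1]. An emotion
with no contributing token is *absent*, not zero — short statements
often match nothing, and the published per-document emotion table is
mostly blank for the same reason.

Both the membership rule and the intensity formula are documented
reconstructions: the source describes only "rules … taken from the
dictionary's emotional-sentiment measures" and reports intensities in
[0, 1] (e.g. sadness 0.8 and fear 0.24 for its worked patient example,
the output shape this stage reproduces). Whether a term could feed
several emotion groups in the original is unstated; the dominant-group
rule is this package's choice, θ configurable.

## 4. Difficulty areas

Six clinician-defined categories: self-esteem, acceptance of the social
assessment, emotions, autoimmune (aggressive/self-aggressive behaviour),
functioning of the body, body image. Each is a term set; the area score
of a document is the fraction of its basic-form tokens (with
multiplicity) matching the set — a value in [0, 1] suitable for a radar
chart, invariant under duplicating the document. A term listed under k
areas contributes to all k; the categories overlap semantically and the
source claims no exclusivity. Relative frequency is a reconstruction:
the source fixes the categories but prints no score formula and its
radar-chart axis is unreadable.

## 5. Evaluation

**One-vs-rest metrics.** For a target label, TP/TN/FP/FN are tallied
over scored records and TPR = TP/(TP+FN), TNR = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), F1 = 2TP/(2TP+FP+FN) =
2·PPV·TPR/(PPV+TPR). A zero denominator leaves a cell undefined
(rendered as a dash). Conventions matching the published tables: the
neutral row reports only TNR and NPV (the binary network never predicts
neutral; the published table dashes the other cells for both methods),
and each column mean averages its *rounded* displayed cells — the
published means follow that arithmetic, e.g. network PPV
(0.73 + 0.65)/2 = 0.69 where unrounded averaging gives 0.68. Rounding is
half-up to 2 decimals, in exact decimal arithmetic, applied at display
time only.

**Stratified errors.** Per clinical group, the percentage of documents
misclassified, broken down by expert label with the group's scored size
as denominator; group totals are the sums of their cells; the overall
line is total errors over all scored records.

**Wilcoxon matched-pairs signed-ranks test** (H0: equal medians) for
agreement between paired label vectors. Zero differences are dropped
(classic variant); absolute differences get midranks on ties; the
statistic is W+, the positive-rank sum. For up to 25 effective pairs the
exact two-sided p doubles the smaller tail of the exact null
distribution of W+, computed by convolution over the doubled (hence
integer) ranks — equivalent to enumerating all 2^n sign assignments,
which is exactly what the test suite's independent oracle does. Beyond
25 pairs a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. The degenerate all-zero case reports
p = 1 with a flag.

### The packaged label fixtures, and why there are two

The per-document evaluation of the original study is packaged as
`table1_labels.tsv`: a faithful transcription of its published
per-document table (44 pathological + 52 control records with expert,
network and dictionary labels). A second file,
`table1_labels_reconciled_synthetic.tsv`, is a *constructed* 95-record
variant (43 + 52): one pathological record dropped and three labels
flipped so that the stratified error counts per group and expert label
equal exactly the counts implied by the published error-percentage table
(whose denominators are 43 and 52).

Two fixtures are needed because the published tables are mutually
inconsistent, which we verified exhaustively: no per-document label set
of any composition reproduces both the published error percentages and
the published metric table at 2 decimals (integer search over all group
compositions and error-type assignments consistent with the
error-table's implied counts finds no solution even for the network
block alone). The error table is moreover internally inconsistent for
the dictionary method: its control-group cells sum to 50.00% while its
printed total is 40.38%. Consequently:

* the metric table is reproduced from the faithful transcription, where
  32 of its 36 cells (including every mean) match exactly and 4 cells
  differ by 0.01;
* the error table is reproduced from the reconciled fixture, where all
  cells match except the two dictionary totals that contradict their own
  summands;
* the corresponding six assertions in the acceptance suite fail by
  design and are left failing — they are unattainable for any dataset.

The agreement tests on the transcription yield p ≈ 0.286, 0.102 and
0.034 (expert–dictionary, expert–network, dictionary–network); the
published entries are typographically damaged ("0271", "0176", "0034")
and are therefore reported but never asserted. The published abstract's
"51% effectiveness" for the dictionary method has no derivation in the
source and is not reproduced; the companion "72%" is the network's mean
TPR, which the metric table reproduces.

## 6. The synthetic stated world

Generators produce format-compatible stand-ins with planted ground
truth; tokens are arbitrary letter strings, since every stage operates
on term identity. Defaults mirror the study corpus: 44 pathological and
52 control statements, mean length 60 tokens (dispersion 0.3, the notes
are short), pathological text tilted negative (negative-polarity weight
0.20 vs positive 0.05) and sad (sadness weight 0.15, fear 0.05), control
text mildly positive. Planted per-emotion intensity targets (pathological
sadness 0.75 vs control 0.55) are realized by drawing emotion-stratum
tokens preferring terms whose dominant rating is near the target —
necessary because a higher *count* of sadness tokens alone would not
move the mean-rating intensity. The synthetic affective list gives every
term a unique dominant emotion rated above the scale midpoint, so the
taxonomy's group assignment is known by construction.

What a green synthetic test does establish: the pipeline recovers
planted polarity (dictionary accuracy → 1 with document length; a
from-scratch network reaches perfect training and ≥ 0.9 held-out
accuracy on 100 planted documents) and the planted direction of the
sadness difference between groups. What it does not establish: anything
about real Polish morphology, real lexicon coverage of clinical
language, or the magnitude of group differences in real statements (the
source reports "about 10%" for sadness; magnitude is not reproducible
without the original Polish statements and the licensed lexicon, so only
the direction is tested).

## 7. Numerical choices

* CCE probability clamp 1e−12; natural log.
* Half-up decimal rounding to 2 places, display time only.
* Wilcoxon exact/approximate crossover at 25 effective pairs.
* Glorot-uniform init; Adam ε = 1e−8; per-batch shuffling from the
  config seed; all generators use `numpy.random.default_rng(seed)`.
* Empty documents: legal everywhere in the dictionary pathway (empty
  profiles, score 0); the network refuses to classify an empty token
  sequence.
* Emotion-group tie-break: a tie for the maximal rating vetoes
  assignment (no arbitrary winner).

## 8. Known limitations

* Lemmatization is dictionary lookup; out-of-map inflected forms pass
  through unreduced, which understates lexicon matches on highly
  inflected languages unless the basic-form map is comprehensive.
* The skip-gram trainer is adequate for toy and synthetic corpora only;
  for real use import externally trained vectors.
* The recurrent classifier is binary by construction; expert "neutral"
  documents are necessarily scored as errors for it.
* The per-document emotion table of the source is not reproducible
  (original statements and licensed lexicon unavailable); it constrains
  only output shape and range here.
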