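# anotext

Computer-aided text analysis of body-image statements for therapeutic
diagnosis in anorexia nervosa.

Clinicians treating anorexia nervosa ask patients to write a short free
statement about the image of their own body. `anotext` turns such a
statement into quantitative decision-support signals for the therapist:

1. **Document sentiment**, two ways: an order-blind dictionary score
   `S = (P − N)/(P + N)` over polarity-lexicon matches (class = sign S ∈
   {−1, 0, +1}), and a recurrent network — a bidirectional GRU layer (5
   units per direction) feeding a unidirectional GRU layer (5 units) and
   a softmax over {−1, +1}, trained on 100-dimensional word2vec vectors
   with categorical cross-entropy, −(1/N) Σ log p_i[y_i], under Adam
   (β₁ = 0.9, β₂ = 0.999).
2. **Emotion-intensity profile**: intensity in [0, 1] of the five basic
   emotions (happiness, anger, sadness, fear, disgust) from an affective
   word list (NAWL-format-compatible), via a one-level taxonomy that
   assigns each term to its dominant emotion above a threshold.
3. **Difficulty areas**: relative match frequency of six
   clinician-defined dictionaries (self-esteem, acceptance of the social
   assessment, emotions, autoimmune, functioning of the body, body
   image).
4. **Evaluation**: one-vs-rest TPR/TNR/PPV/NPV/F1 tables, stratified
   error percentages by clinical group and expert label, and Wilcoxon
   matched-pairs signed-ranks agreement tests (exact p by enumeration up
   to n = 25, tie- and continuity-corrected normal approximation
   beyond).

Licensed resources (NAWL, the MPQA subjectivity lexicon) are never
bundled; loaders accept user-supplied exports, and a synthetic module
generates format-compatible stand-ins with planted ground truth so the
whole pipeline is testable offline. The per-document label table of the
original clinical evaluation (44 patients, 52 controls) ships as a
fixture, in both a faithful transcription and a variant reconciled to
the published stratified error counts (the two published summary tables
are mutually inconsistent — see `docs/methods.md`).

This is research software for decision support; it claims no clinical
decision authority.

## Worked example

```python
from anotext import RawDocument, prepare_term_bag, score_document
from anotext.lexicons import PolarityLexicon
from anotext.textprep import BasicFormMap

note = RawDocument("patient-1",
    "How did it start? Very simply, one day I understood that since "
    "nobody accepts me, I will accept myself. The problem is that I "
    "hate being fat! Now my day meal is a salad. I feel caught in a "
    "cage without retreat.")

lex = PolarityLexicon({"hate": -1, "fat": -1, "cage": -1, "accept": 1})
bag = prepare_term_bag(note, bmap=BasicFormMap({"accepts": "accept"}))
res = score_document(bag, lex)
print(res.n_pos, res.n_neg, res.value, res.klass)
```

prints `2 3 -0.2 -1`: two positive matches ("accepts", "accept" — both
reduced to the basic form), three negative, score (2−3)/(2+3) = −0.2,
class −1. The dictionary method flags the statement as
negative-sentiment, matching the expert reading of the same example; a
richer lexicon sharpens the score. Emotion and area profiles come from
`profile_document(bag, awl)` and `profile_areas(bag, dicts)`; absent
emotions are reported as missing (not zero), because short notes often
match no affective term.

Evaluating the packaged label fixture:

```bash
anotext evaluate src/anotext/data/table1_labels.tsv --method rnn
```

prints (excerpt)

```
"mean": {"TPR": 0.72, "TNR": 0.8, "PPV": 0.69, "NPV": 0.82, "F1": 0.7}
```

— the network's mean one-vs-rest sensitivity of 0.72 over the positive
and negative labels is the "72% effectiveness" headline figure of the
original evaluation; the per-label rows and the stratified error table
are printed alongside, with Wilcoxon agreement tests between expert,
dictionary and network labels.

Other CLI entry points: `anotext analyze` (JSON-lines per-document
reports; stages switch on when their resource files are passed),
`anotext train` (desk-scale from-scratch training on a synthetic
planted-polarity corpus; raise the learning rate to ~1e−3 — the recorded
default 5e−6 is a fine-tuning rate), `anotext simulate` (synthetic
corpus + lexicons + `truth.json`), `anotext validate-lexicon`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch: the metric
and error tables from the packaged label fixtures (with the Wilcoxon
agreement tests), dictionary-sentiment recovery of planted truth on a
freshly generated 200-document synthetic corpus, the planted
sadness-direction check between synthetic groups, and a from-scratch
training run of the recurrent classifier (100 training documents, 50
held out). A summary is printed to stdout and the JSON result object is
written to `--out`. Runtime is about half a minute on one CPU.
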