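# Methods

This note records the modeling and design choices behind `kiddi`, the
assumptions they rest on, and what the synthetic experiments do and do
not establish.

## Data model

A corpus is a list of dialogues, each with a disease label and turns
that strictly alternate patient/doctor starting with the patient; the
first turn is the self-report. Patient turns carry an optional intent
(`Symptom` with a non-empty symptom list, or `Affirmative` with an
empty one); doctor turns carry no intent, and their symptom list names
what the doctor asked about. Corpora violating these invariants are
rejected, not repaired: silent repair would blur the single resolution
rule everything downstream depends on. Symptom and disease names are
normalized (lowercase, collapsed whitespace) and used as discrete slot
identifiers; vocabularies are sorted lexicographically so indices are
stable across runs. The serialization format is the package's own JSON
dialect (documented in `src/kiddi/corpus_schema.json`); no public
serialization standard exists for this kind of corpus.

**Affirmative resolution.** An `Affirmative` turn means the patient
agreed with the doctor without naming the symptom, so it contributes
the symptom(s) named by the immediately preceding doctor turn. This
single rule is used everywhere a dialogue's symptom set is needed
(knowledge-graph counting and per-conversation filtering) so the two
stages can never disagree. An `Affirmative` turn with no preceding
doctor turn contributes nothing and logs a warning. Patient turns with
no intent (denials, small talk) contribute nothing.

## Knowledge graph

Counting granularity is one dialogue = one case, with set semantics: a
symptom counts at most once per dialogue however often it is mentioned.
`idf` uses the natural logarithm; the base only rescales all weights
uniformly and the weights' sole downstream use is ranking. Guards for
degenerate inputs: a disease with zero symptom occurrences has
`sf = 0` for every symptom and no edges; a symptom never resolved in
any dialogue has no defined `idf` and raises rather than silently
returning 0; a symptom that never co-occurs with another symptom emits
no outgoing symptom–symptom edges. Symptom–symptom edges are stored
directed (row normalization makes them asymmetric); consumers may
symmetrize.

## Selective filtering and the joint graph

Per conversation: resolve the symptom set, keep each symptom's top-K
diseases by sf–idf weight (ties broken lexicographically so runs are
reproducible), and attach one dialog node connected to every symptom
node. Defaults: K = 2; symptom–symptom edges among the included
symptoms are kept (the graph is S–S–D) and can be toggled off for
ablation. Edge weights serve only the top-K ranking: the GAT consumes
topology and node features, with neighborhoods treated as undirected
and a self-loop on every node so even the lone dialog node of a
symptom-free conversation has a defined update. A conversation none of
whose symptoms reach the knowledge graph degenerates to a single-node
graph and still yields a valid prediction.

## Encoders

The encoder contract is a token sequence in, a fixed-width vector
(d2) out. The reference encoder is deliberately small — learned token
embeddings, mean-pooled, then an affine map — because the synthetic
corpora are templated and their entire diagnostic signal is lexical
(which symptom words occur). The empty sequence maps to the learned
bias ("null vector"); unknown tokens map to a reserved id. A
`pretrained_adapter` slot accepts any callable producing width-d2
vectors (e.g. the first-position pooling of a frozen biomedical
transformer); nothing pretrained ships with the package, and the
adapter's output is treated as a constant (frozen) — consistent with a
trainable-parameter count far below the encoder's size at reference
scale. Dialog serialization interleaves turns in conversational order
with `<pat>`/`<doc>` markers (discourse order is the model's premise;
grouping all patient turns before all doctor turns would destroy it).
Entity names (symptom/disease node labels) and the dialog-node feature
share one learned d2 → d1 projection, resolving the width mismatch
between text encodings and graph features.

## Model core and training

GAT: 2 layers, 3 heads whose outputs concatenate so the width d1 is
preserved in every layer; LeakyReLU slope 0.2 (the literature's
default); dropout (rate 0.5) applied to attention coefficients only,
during training only. Additive attention projects into a d3-wide
space. The classifier reads `[graph embedding; attended context]`.
Cross-entropy clamps probabilities at 1e-12 inside the log; argmax
ties break toward the lowest disease index. Training uses Adam,
learning rate 1e-3, batch size 16; the checkpoint with the best
validation accuracy across epochs is retained. Every random stream
(initialization, shuffling, dropout) derives from one seed, and
evaluation is pure, so repeated runs are bit-identical.

Reference hyperparameters (`profiles.full_scale`): d2 = 768, d1 = 384,
d3 = 64, max sequence length 512, 25 epochs. The desk-scale profile
(`profiles.desk_scale`) used by the tests, CLI defaults and the
reproduction script keeps the architecture, optimizer, batch size and
learning rate but shrinks widths to d2 = 32, d1 = 24, d3 = 16 and
doubles the epoch budget to 50: the reference setting fine-tunes over
a frozen pretrained encoder, whereas the desk-scale encoder trains
from random initialization, and its graph-attention modes are still
improving on validation at 25 epochs while linear modes plateau by
epoch 10. The budget is uniform across ablation modes so contrasts
are not biased.

### Ablation wiring

`sre_only` / `de_only` classify from the self-report / dialog encoding
alone; `knowledge_only` from the mean-pooled GAT embedding alone;
`*_linear` concatenate the text encoding with the unweighted mean of
the subgraph's entity-name features (knowledge as a flat vector, no
message passing) — the simplest structure-free infusion consistent
with a "linear" baseline; `*_knowledge` concatenate the text encoding
with the GAT-pooled embedding (no additive attention); `full` is the
complete model. All modes share splits, seeds and the training budget.

### Hierarchical mode

A disease-group classifier (same architecture, group labels) routes to
per-group disease classifiers trained on the group's dialogues with a
group-restricted label space. The grouping is user-supplied (a
disease → group map); no canonical medical-department taxonomy is
bundled. Group accuracy always bounds end-to-end accuracy from above,
since a correct disease implies a correct group.

## Synthetic corpora

The generator plants a symptom profile per disease: a global pool of
`n_common_symptoms` common symptoms shared by *every* disease (the
"cold, cough and fever" confound) plus disease-specific symptoms drawn
from the remaining vocabulary. Dialogues open with a self-report drawn
preferentially from the profile's common symptoms — so self-reports
alone under-determine the disease *by construction* — followed by
doctor inquiries that each name exactly one symptom (making
Affirmative resolution unambiguous). Each remaining profile symptom is
raised with probability `p_elicit` (default 0.7, at least one inquiry):
real consultations cover only part of a textbook profile, and full
elicitation would make the task saturate near perfect accuracy.
Confirmations are expressed as bare agreements with probability
`p_affirmative`; with probability `noise_rate` a confirmed symptom is
replaced by an off-profile one; with probability `p_denial` the doctor
probes an off-profile symptom that the patient denies (an unannotated
turn). The generator's bookkeeping (profiles and per-dialogue gold
symptom sets) is returned alongside the corpus and serves as the
oracle for extraction, counting and recovery tests. Text is templated:
the generator makes no attempt at natural phrasing, negation scope, or
multi-symptom questions.

**What passing tests show — and don't.** The synthetic experiments
verify the pipeline's mechanics exactly (formula-level agreement with
brute-force oracles, gradient correctness, determinism) and reproduce
the qualitative phenomenon that dialog-elicited symptoms dominate
self-reports when self-reports are common-symptom-bound. They do not
show that the model handles real clinical language: templated text has
no paraphrase, negation, or entity-linking difficulty, and the
reference encoder is a bag of words. One directional finding from the
reference setting does not transfer to desk scale: with a trainable
lexical encoder, infusing the filtered subgraph as a flat feature mean
is statistically indistinguishable from infusing it through the GAT
(the flat mean already carries the candidate-disease signal through a
short gradient path, and softmax-normalized attention largely discards
the support-multiplicity signal that structure could add). The
structured-infusion advantage plausibly requires a real corpus and a
frozen pretrained encoder, which are outside this package's scope.

## Numerical choices

Float64 throughout. Masked softmax subtracts the row maximum before
exponentiation and defines fully-masked rows as zero. The autodiff
engine implements exactly the operation set the model needs and is
validated against central finite differences (including one
end-to-end check through encoder, GAT, attention and classifier).
Stratified splitting uses scikit-learn's stratified splitter with
largest-remainder size rounding and falls back to a plain seeded
shuffle when class counts cannot support stratification (e.g.
singleton classes).

## Known limitations

* The learned symptom tagger is a contract only (`symptom_source =
  "learned_tagger"` with a user-supplied tagger); gold annotations are
  the default and the package ships no NLU model.
* Single-label diseases only; the Jaccard metric is implemented
  set-wise so multi-label extensions would not change the harness.
* No external medical ontologies, no smoothing/pseudo-counts in the
  co-occurrence statistics.
* The per-dialogue loop is pure Python over small dense matrices;
  desk-scale corpora (hundreds of dialogues) train in seconds to
  minutes, but the implementation is not built for corpora orders of
  magnitude larger.
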