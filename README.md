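# kiddi — knowledge-infused disease diagnosis from medical dialogues

`kiddi` implements a two-channel, knowledge-infused, discourse-aware
disease diagnosis model for annotated doctor–patient conversations,
together with everything needed to study it end to end: a corpus data
model, a symptom–disease knowledge graph, a per-conversation graph
filter, a trainable model, an evaluation and ablation harness, a CLI,
and a synthetic-corpus generator with planted ground truth so every
stage is verifiable without downloading any dataset.

It is aimed at researchers in medical-dialogue NLP and clinical
decision support who want a compact, fully inspectable reference
implementation of knowledge-graph-infused text classification.

## The model

A consultation is an ordered sequence of turns
`D = <(P_1, D_1), …, (P_n, D_n)>`; the first patient turn is the
*self-report* (the volunteered chief complaints), later patient turns
answer the doctor's symptom inquiries, and each patient turn carries an
intent tag (`Symptom` — the utterance names symptoms; `Affirmative` —
the patient agrees with the doctor without naming the symptom). The
task is to predict the disease label from the conversation.

**Knowledge graph (S–S–D).** Nodes are symptoms and diseases. A
symptom–disease edge is weighted by *symptom frequency – inverse
disease frequency*:

    e(s, d) = sf(s, d) · idf(s)
    sf(s, d) = n_sd / Σ_k n_kd          idf(s) = ln( |D| / #{d : n_sd > 0} )

where `n_sd` counts dialogues of disease `d` whose resolved symptom set
contains `s`. Symptom–symptom edges are row-normalized co-occurrence
proportions `e(s_i, s_j) = n(s_i, s_j) / Σ_k n(s_i, s_k)`.

**Discourse-aware selective filtering (DSF).** The conversation's
symptom set is resolved from the annotations (an `Affirmative` turn
inherits the symptom the doctor just asked about); each resolved
symptom keeps its top-K diseases by sf–idf weight; a *dialog node*
(feature: the projected dialog encoding) is connected to every symptom
node, yielding the joint graph.

**Two channels, fused.** A pluggable encoder produces the self-report
encoding `S` and dialog encoding `C` (with `<sr_start>/<sr_end>` and
`<pat>/<doc>` special tokens). A multi-head graph attention network
runs over the joint graph,

    h_i = LeakyReLU( Σ_{j∈N_i} α_ij W_h h_j ),
    α_ij = softmax_j LeakyReLU( aᵀ [W_h h_i ‖ W_h h_j] ),

and mean-pooling all nodes gives the graph embedding `s`. Additive
attention with `s` as query weighs the two text channels,
`e_i = vᵀ tanh(W_1 h_i + W_2 s)`, `α = softmax([e_1, e_2])`,
`context = α_1 S + α_2 C`, and a softmax layer over `[s; context]`
predicts the disease; training minimizes categorical cross-entropy.

The neural core is implemented on a compact reverse-mode autodiff
engine over numpy (`kiddi.autodiff`), checked against central finite
differences, so the package has no deep-learning framework dependency.

## Worked example

```bash
kiddi synth --out corpus.json --seed 0          # 600 dialogues, 10 diseases
kiddi stats --corpus corpus.json
kiddi build-kg --corpus corpus.json --out kg.json
kiddi train --corpus corpus.json --out model.npz --seed 0
```

The trainer splits 70/10/20, builds the knowledge graph from the
training split, trains the full model at the desk-scale profile and
prints the held-out metrics:

```
wrote model.npz
test accuracy=0.9167 macro_f1=0.9164 jaccard=0.9167
```

i.e. on a synthetic corpus whose self-reports carry only common,
widely shared symptoms, the full-dialog knowledge-infused model
identifies the disease in ~92% of held-out consultations (chance is
10%). The same corpus evaluated with a self-report-only head reaches
only ~9–11% — the doctor's elicited symptoms, not the self-report,
carry the diagnostic signal:

```bash
kiddi ablate --corpus corpus.json --modes full,sre_only,de_linear,de_knowledge --seed 0
```

Library use mirrors the CLI:

```python
from kiddi import GeneratorConfig, generate, split_corpus, build_graph, train, evaluate
from kiddi.profiles import desk_scale

corpus, truth = generate(GeneratorConfig(seed=0))
tr, va, te = split_corpus(corpus, (0.7, 0.1, 0.2), seed=0)
kg = build_graph(tr)
ckpt = train(tr, va, kg, *desk_scale(seed=0))
print(evaluate(ckpt, te, kg).accuracy)
```

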