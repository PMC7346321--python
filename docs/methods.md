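# Methods

## The two-stage model

The system predicts cardiovascular disease (CVD) from EMR free text in two
stages. The first stage is sequence labeling: every character receives a
BIO tag whose entity code combines one of twelve risk-factor types with a
temporal attribute (Continue, During, After, Before; Age and Gender carry
the placeholder None). The default scheme has 42 composite codes and
85 tags. The second stage discards everything except the extracted
(mention, label) pairs and classifies the document from those units alone —
the premise being that most of an EMR is irrelevant to disease status and
the risk-factor inventory plus its temporality carries the signal.

### Extractor

Characters are embedded with skip-gram vectors and encoded by a
bidirectional LSTM (standard cell: input/forget/output gates and a tanh
candidate, no peepholes; forget bias initialized to 1; independent
parameters per direction, forward-then-backward concatenation). A tanh
layer maps each state to per-tag confidence scores, and a linear-chain CRF
with a start row and a full transition matrix scores whole tag paths.
Training maximizes the log-probability of the gold path; the partition
function is computed by the forward recursion in log space, gradients are
the classic marginal-minus-indicator counts from the forward-backward
recursions, and inference is Viterbi with ties broken toward the lowest
tag index (a determinism contract for testing). No hard BIO constraints
are imposed on transitions; the matrix must learn them. At decode time an
`I-x` without a compatible predecessor is repaired to `B-x`, which
preserves recall over dropping the span.

### Classifier

Mentions are packed into fixed units of 7 cells — up to six surface
characters (PAD-padded, truncated beyond six) plus one label token
`B-<code>` — over an extended vocabulary of characters, label tokens, PAD
and UNK. The network is a deep pyramid CNN: a region embedding (a linear
map over the concatenated one-hot vectors of a k-token window; k = 7 spans
exactly one unit, k = 14 two units; for even k the window takes the extra
position to the right; edge windows see PAD), then blocks of two
pre-activation convolutions (rectifier before the linear map, kernel 3,
zero-padded to constant length) wrapped in identity shortcuts, interleaved
with size-3 stride-2 max pooling. Windows are centered at even positions
with −inf padding at both edges so the pooled length is exactly
ceil(n/2); pooling stops once the length would fall below 2. Feature maps
are fixed (250 by default) so shortcuts never need dimension matching. A
final max pool over positions gives one vector per document; the decision
head (the one part the architecture leaves open) is dropout → linear map
to 2 scores → normalized exponential. Dropout (keep rate 0.5) is applied
after the region embedding and on the final vector.

Depth is counted in weight layers: the default depth 15 = 1 region
embedding + 7 blocks × 2 convolutions. Two analytic instruments accompany
the model: `count_macs` gives per-block multiply-accumulate counts
(2·ks·m² per position at length ceil(n/2^ℓ)), and `receptive_field`
unrolls the exact recurrence (each convolution adds (ks−1)·j, each pool
adds 2·j then doubles the cumulative stride j). At power-of-two lengths
consecutive blocks cost exactly half of each other and the total stays
below twice the first block; at arbitrary lengths the ceil rounding makes
both claims asymptotic (ratio ≤ 1/2 + o(1)).

## Training procedures and their rationale

Both trainers are seed-deterministic on a single thread, clip the global
gradient norm at 5.0, and use the exponential schedule
lr · dr^(step/ds).

**Extractor: SGD with momentum 0.9, lr 0.015, decay 0.99 per 500 steps,
10 epochs, per-sentence updates, embeddings fine-tuned.** The choice of
plain SGD is deliberate. The emission scores are tanh-bounded, and an
adaptive optimizer (Adam) reliably drives the pre-activations deep into
the saturated tails — emissions pin at ±1, their gradients vanish, and
whole risk-factor types become permanently undetectable (we observed
entire types locked out with every emission at −1). SGD steps shrink with
the true gradient and are therefore self-limiting near saturation; with
momentum the same data take the model to exact-match F ≈ 0.97 where Adam
plateaus near 0.72. Convergence is still bistable in the early epochs:
whether a given type escapes the all-outside basin depends on
initialization, so held-out F varies across seeds (roughly 0.7–1.0 on the
hardest draws). Max-norm constraints on the emission weights and sharper
learning-rate anneals were evaluated and rejected (both trade the basin
problem for underfitting).

**Classifier: Adam (β₁ 0.9, β₂ 0.999), lr 0.001, batch 64.** Adam is kept
here — the rectified residual network has no saturation trap, and SGD
diverges on it. Beyond the two dropout sites, three standard regularizers
are on by default because the planted-rule task exposes a failure mode the
bare recipe cannot cross: the label is a threshold on the number of
distinct risk-factor types with an active temporal attribute, and from 500
documents the bare network memorizes surface co-occurrences instead
(train accuracy 1.0, held-out ≈ 0.85, errors concentrated exactly at the
2-vs-3 boundary). The defaults are: (1) per-example permutation of whole
7-cell units — the document label is a function of the mention multiset,
so unit order is a known invariance of the task family; (2) uniform
input-token dropout to UNK (rate 0.15, word dropout), which discourages
reliance on any particular co-occurring surface token; (3) decoupled L2
weight decay 1e-4 with an exponential moving average (0.995) of the
weights as the returned model. Weights use He-style initialization for the
rectified convolutions. `reduced_synthetic_config()` is the canonical
down-scaled study configuration (32 feature maps, 3 blocks, 150 epochs,
lr decay 0.9 per 200 steps) used by the tests and the acceptance script.

**Embeddings: skip-gram with negative sampling** (window 5, 5 negatives,
5 epochs, unigram^0.75 noise, linearly decaying lr from 0.025), trained on
the corpus plus each dictionary surface repeated 10× so the characters of
a risk factor co-occur tightly. The returned vectors are the mean of input
and output vectors with the common mean direction removed: on small
corpora the raw input space is strongly anisotropic (all cosines ≈ 1) and
rare-token input vectors are noisy; averaging plus centering makes cosine
similarity track co-occurrence, which is the property downstream code and
tests rely on. The PAD row is frozen at zero.

## The synthetic corpus

Real annotated EMR corpora for this task are private, so the generator
produces documents with the statistical structure both models assume:
geometric filler runs (success probability 0.35) from a 20-letter filler
alphabet, interleaved with a Poisson(5) number of planted mentions. Each
risk-factor type owns three disjoint content characters and three short
surface strings over them (lengths 2–3, so 7-cell packing never
truncates); the temporal attribute is drawn from (C .35, D .25, A .2,
B .2), always None for Age/Gender. Because a surface alone cannot reveal
temporality, each mention is preceded by a one-character temporal marker
(tagged O) — the stand-in for the contextual temporal cues of real
clinical narrative, and the reason the extractor must actually read
context. The document label is the planted rule: positive iff at least 3
distinct risk-factor types carry an attribute in {Continue, During}.
Corpus generation steers class balance to a target prevalence (default
0.8, mirroring the 527:132 class split of the clinical corpus this
emulates) by rejection sampling with an explicit failure bound, and splits
follow the 461:66:132 proportions. Everything is bit-reproducible from a
single PCG64 seed.

What passing on this corpus shows — and what it does not. The generator
provides exact, exhaustively checkable ground truth (every BIO sequence is
valid; decoding gold tags recovers the planted mentions; every label obeys
the rule), so it can falsify the inference code and demonstrate that both
architectures can recover planted structure at realistic model sizes. It
does not emulate real clinical text: no negation, section structure,
spelling variation, annotator disagreement, or ambiguous mention
boundaries. Scores on it are upper bounds of convenience, not estimates of
clinical performance.

## Study sizes and numerical choices

The synthetic studies use 500 training / 200 held-out documents, the
reduced classifier, and seed 13 — sizes chosen so the whole suite trains
in minutes on one CPU. The extractor study uses the generator's natural
document distribution (prevalence steering is a document-classification
concern); the classifier study uses the steered corpus. Held-out classifier
accuracy at these sizes has seed-to-seed spread of a few points (≈ 0.89–
0.96); the pinned-seed configuration sits at 0.96.

Other numerical decisions: CRF computations run entirely in log space and
are stable for scores up to ±10³; Viterbi ties break toward the lowest tag
index; documents with no extracted mentions are classified no-CVD with an
explicit no-evidence flag rather than fed to the network (the classifier
requires at least one unit); unknown mention codes at prediction time map
to UNK label tokens; the text normalizer applies only unicode NFC,
control-character stripping, whitespace collapsing, and replacement of
configured missing-value markers by a single token. Model files are
single-file npz archives with an embedded JSON config header.

## Known limitations

Hand-written numpy training is orders of magnitude slower than framework
code and is sized for the synthetic studies, not for 800k-record corpora.
The extractor's bistable early training (a consequence of the
tanh-bounded emission layer, which is part of the model's definition) is
documented above rather than engineered away. The paper-scale model
(250 feature maps, depth 15) is implemented and tested structurally but
the learning studies use the reduced configuration. Nothing here is a
clinical tool: the classifier threshold (0.5) is uncalibrated and the
synthetic corpus makes no attempt at clinical realism.
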