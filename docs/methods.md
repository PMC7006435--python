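# Methods

## Problem

A clinical SOAP note records an encounter as Header (patient metadata
and the chief complaint / reason for visit), Subjective and Objective
narrative, Assessment (the diagnosis-bearing summary), and Plan.  This
package generates the Assessment from the Header and the
Subjective+Objective narrative, treating the task as conditional
abstractive summarization: the narrative supplies the evidence, the
chief complaint supplies the question being answered.

## Model

Let X = (f₁…fₙ) be the narrative tokens, T = (w₁…wₘ) the header tokens
and Y = (y₁…y_l) the assessment.  Both inputs are embedded through one
shared matrix M ∈ ℝ^{|V|×d} and encoded by separate single-layer
bidirectional LSTMs, giving states H = [h₁…hₙ] and Z = [z₁…zₘ] (each
2·hidden wide).  A single-layer LSTM decoder starts from a learned
linear reduction of the source encoder's final states and consumes only
the previous word's embedding at each step (no input feeding by
default; a config flag can enable it).

At step i with decoder state sᵢ:

1. **Header attention** — αᵢⱼ = softmaxⱼ Vᵀ tanh(W_Z zⱼ + W_S sᵢ + b_z),
   zᵢ* = Σₖ αᵢₖ zₖ.
2. **Attention-over-attention** — the narrative attention logits add a
   steering term from the header context:
   eᵢⱼ = vᵀ tanh(W_h hⱼ + W_s sᵢ + W_z zᵢ* [+ w_c cᵢⱼ] + b),
   βᵢ* = softmax(eᵢ*), hᵢ* = Σₖ βᵢₖ hₖ.  The w_c term is present only
   when coverage is enabled; cᵢ* = Σ_{k<i} βₖ* is the running attention
   total.
3. **Copy gate** — p_gen = σ(W′_h hᵢ* + W′_s sᵢ + W′_y yᵢ₋₁ + b′).
4. **Vocabulary readout** — p_voc = softmax(W₂(W₁[sᵢ; hᵢ*; zᵢ*] + b₁) + b₂),
   a two-layer affine readout.  For the source-only models the zᵢ* block
   is absent.
5. **Final mixture** — over the extended vocabulary (|V| plus one slot
   per distinct OOV source token),
   p(w) = p_gen·p_voc(w) + (1−p_gen)·Σⱼ 1(fⱼ=w)·βᵢⱼ, with copy mass
   scatter-added by extended id so repeated source tokens accumulate.

The three baselines are ablations of the same parameterization:
`seq2seq` (no copy, no header), `pg` (copy, no header), and the
`-coverage` variants add the coverage term and loss.

**Design choice — z\* in the readout.**  The published description
leaves the readout's inputs ambiguous (its weight symbols are not
rendered), and one reading routes header information exclusively
through the attention steering of step 2.  We include zᵢ* in the
readout as well.  The reason is learnability at small scale: with the
attention-only route, the gradient reaching the steering weights is
several orders of magnitude smaller than readout gradients, and on
corpora whose targets are fully header-determined the model converges
to the source-only ambiguity floor without ever using the header.  With
zᵢ* in the readout the direct path trains the header encoder, which in
turn makes the attention steering learnable; the steering term of
step 2 is retained unchanged.

## Training

Teacher-forced NLL, length-normalized per sequence
(−Σ log pⁱ(yᵢ)/l, batch-averaged), with probabilities read at the gold
extended ids and floored at 1e−12 before the log (with a warning).
Coverage training adds λ·Σᵢ Σⱼ min(βᵢⱼ, cᵢⱼ) per sequence with λ = 0.2;
the per-sequence coverage loss lies in [0, l−1], attaining l−1 exactly
when attention never moves.  Following the published recipe the model
is first trained on the NLL alone; the coverage weight w_c is then
added **initialized to zero** — so the extended model reproduces the
pretrained distributions exactly and the phase-2 starting loss is the
phase-1 NLL plus λ times the initial coverage loss — and fine-tuned on
the combined loss.

Optimization is Adagrad with the published learning rate 0.12 and
initial accumulator 0.11 as defaults, gradient-norm clipping at 2.0,
batch size 16, early stopping on validation loss checked once per epoch
with patience 3 (batching, clipping and patience are this package's
choices; the original work does not report them).  Weights initialize
uniform(−0.1, 0.1), embeddings normal(0, 1e−4), all from a seeded
generator.

**Desk-scale accumulator.**  The Adagrad initial accumulator acts as a
floor on the denominator √(acc₀ + Σg²).  At the original corpus scale
typical squared gradients dwarf 0.11; at desk scale (hundreds of notes,
hidden ≈ 24) they are orders of magnitude below it, which turns Adagrad
into plain SGD with a tiny constant step and freezes the
weakly-gradiented header pathway permanently.  The desk-scale
experiments therefore run with acc₀ = 1e−6 (the conventional near-zero
setting), restoring per-parameter normalization.  The coverage
experiment deliberately keeps the published 0.12/0.11 setting: its slow
convergence holds the model in the repetitive-generation regime in
which coverage has something to fix.

## Decoding

Beam search over the extended vocabulary (defaults: beam 10, minimum
length 15, maximum 60, matching the published settings).  The end
symbol is masked while the output is shorter than the minimum; padding
and begin symbols are always blocked; UNK is allowed but never forced.
Finished hypotheses are ranked by log-probability divided by length —
the ranking rule is unstated in the original description, and
unnormalized scores systematically favor the shortest legal output.
Coverage, when present, updates during decoding exactly as in training;
no extra decode-time penalty enters the score.  If nothing finishes
within the maximum length the best unfinished hypothesis is returned
with a warning.  Per-step header and source attention distributions can
be exported as JSON traces for inspection.

## Evaluation

ROUGE-1/2 use clipped n-gram multiset intersection; ROUGE-L uses the
longest common subsequence (dynamic programming).  Recall divides by
the reference count, precision by the candidate count, F1 is their
harmonic mean.  No stemming or stopword removal; candidates and
references pass through the same lowercase punctuation-splitting
tokenizer used for notes.  Corpus scores are macro averages over pairs
(the averaging convention is unstated in the original work; absolute
comparability with its reported scores is impossible anyway because its
corpus is private and its ROUGE options are unreported).

## Synthetic corpus

The generator emulates the structural properties of the private corpus
that the model mechanisms depend on, not clinical language:

* **Conditions** form a complete problems × sites grid (default 20 =
  4×5).  A note's true condition appears in the header as a chief
  complaint phrase.
* **Ambiguity by construction.**  The narrative interleaves findings of
  the true condition (p, s) with findings of the confusion square
  (p′, s), (p, s′), (p′, s′), all rendered from the same per-note
  template pick, so every problem/site phrase occurs with identical
  frequency and phrasing.  A source-only reader faces a symmetric
  multi-way ambiguity; the header resolves it.  This is verified
  directly: a bag-of-words classifier on header+source beats one on
  source alone by a wide margin.
* **Copy necessity.**  Each note carries a surrogate entity token
  (surname + digits, e.g. ``rivera93``).  Digit-bearing tokens are
  excluded from the vocabulary, so the entity is OOV everywhere and can
  only be produced by copying from the source.
* **Noise** (token dropout/swap, default rate 0.02) applies to the
  narrative only; assessments stay deterministic functions of
  (condition, entity).

Desk-scale defaults: sources of 40–90 tokens (25–40 in the acceptance
experiments) instead of 500-token clinical narratives, splits of
2000/200/200 (240/30/40 in the acceptance experiments), vocabulary far
below the 100,000 cap.  The acceptance experiments additionally fix one
assessment template per condition (the default is two) so the target is
a deterministic function of (condition, entity) with no stylistic
variation a model cannot predict, and decode greedily with a minimum
length of 10 against 12–14-token references — the scaled analog of the
published beam constraints (minimum 15 against up-to-60-token
summaries), which keeps the length floor below the reference length
while preventing degenerate early termination.  What passing tests show is that each mechanism
does its designed job under these controlled conditions; they say
nothing about ROUGE levels on real clinical text, where the
header–narrative relationship is far noisier.

## Numerical choices

* All math is float64 on a small reverse-mode tape written for this
  package; gradients are verified against central finite differences
  (tolerance 1e−4 relative with a 1e−8 absolute floor for
  finite-difference noise).
* Attention masking adds −1e9 to padded positions before the softmax.
* min(β, c) ties send the subgradient to β.
* Tokens containing digits are OOV unless they are a single digit;
  the ten digits are always in-vocabulary.  Vocabulary frequency ties
  break lexicographically.
* Truncation (source 500, header 100, target 60 by default) happens
  before OOV indexing, so extended ids never point at truncated
  positions.
* Extended ids have no embedding row; they embed as UNK when fed back
  into the decoder.

## Known limitations

* The attention-only header route is too weakly gradiented to train at
  desk scale (see the z* readout note above); consequently header
  attention localizes on complaint tokens only loosely (its mass
  exceeds the uniform baseline, but the argmax is not reliably the
  single most informative token).
* Pure-numpy training is CPU-bound; the defaults in `ModelConfig`
  (d = 128, hidden = 200) are faithful to the published configuration
  but impractical without reducing scale; the acceptance experiments
  use d = 16, hidden = 24.
* Sentence-level macro ROUGE and the length-normalized beam ranking are
  conventions chosen here; other choices shift absolute numbers.
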