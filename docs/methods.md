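# Methods

## Model

The classifier is a K-layer Graph Isomorphism Network (GIN) with sum
aggregation,

    h_v^(k) = MLP^(k)((1 + ε^(k)) h_v^(k−1) + Σ_{u∈N(v)} h_u^(k−1)),

over attributed molecular graphs, followed by a mean readout of the *last*
layer's node embeddings (no jumping-knowledge concatenation) and a
single-hidden-layer MLP head.  Initial node states are the sums of learned
embedding tables over the categorical atom features (atomic-number code and
chirality tag for chemistry inputs; two small integer codes for synthetic
graphs).  Bond features, when enabled, enter as learned bond embeddings added
to each neighbour message before summation — the convention of pre-trained
molecular GIN encoders; synthetic graphs carry no bond information and run
with this path disabled.  Each layer's MLP is linear–ReLU–linear.  There is no
batch normalization: batch statistics interact badly with per-task functional
adaptation (the inner loop would have to carry running statistics through
gradient steps) and with single-graph batches at test time, and the
desk-scale networks train fine without it.  ε^(k) is fixed at 0 by default
(`learn_epsilon` makes it a parameter).

One head serves both classification modes.  During meta-training's inner loop
its raw outputs are softmax logits under a plain cross-entropy (adapting with
the evidential objective would bake task-specific uncertainty into the
meta-model); everywhere else the same outputs pass through ReLU to become the
evidence vector of a Dirichlet distribution: α = e + 1, strength S = Σα,
class probabilities α/S, uncertainty u = C/S.  The denominator in the
probability and uncertainty expressions is the Dirichlet strength
S = Σ_j (e_j + 1); this is the only reading consistent with the
subjective-logic identity u + Σ_c e_c/S = 1, which the test suite asserts
exactly.

## Loss

The evidential objective has three terms:

* **Dirichlet cross-entropy** — the exact expectation of −log p_y under
  Dirichlet(α): Σ_j y_j(ψ(S) − ψ(α_j)).  Verified in the tests against
  Monte-Carlo integration over Dirichlet samples.
* **Belief regularizer** — mean evidence assigned to false classes,
  (1/N) Σ_i ‖e_i ⊙ (1 − y_i)‖₁.
* **AvUC calibration** — −λ_c Σ_correct p_i log(1−u_i)
  − (1−λ_c) Σ_incorrect (1−p_i) log(u_i), pushing uncertainty down on correct
  predictions and up on errors.  Natural logarithms; u and p are clamped to
  [1e−7, 1−1e−7] before logs, with zero gradient at the clamp; the
  correctness partition (argmax vs label, ties to the lower class index) is a
  constant of the batch.

Total: L = L_dce + λ_b·L_br + L_AvUC(λ_c), with λ_b annealed linearly from λ₀
(default 0.01) to 1.0 over the epoch budget and λ_c = 0.1·λ_b — evidence
acquisition first, calibration pressure late.

**Batch reduction and AvUC weighting.**  All three terms are normalized per
sample, and the assembled AvUC term additionally carries λ_b as an overall
weight.  Both choices matter and were forced by experiment.  ReLU evidence
has a global dead state: once every raw output of a batch is negative, the
evidential gradient is identically zero and training can never recover.  With
batch-summed AvUC at constant overall strength, the incorrect-prediction
branch (weight 1−λ_c ≈ 1 from the first epoch, with gradient magnitude
|log u| ≈ 16 at the uncertainty clamp) dominates the O(1) cross-entropy
before any evidence has been acquired and reliably drives every unit into
that dead state — from-scratch training collapses to u ≡ 1 and chance
accuracy.  Per-sample normalization plus the λ_b anneal makes AvUC the
late-phase calibration term the annealing schedule describes, and training is
then stable.  For the same reason the head's output bias is initialized to
+1, so evidence starts active (u < 1) with live gradients.

## Meta-learning

One epoch = one pass over the training tasks followed by one outer update.
Per task: sample N support molecules uniformly (N is the *total* support
size, not per class; N=1 may be single-class and the inner loop tolerates
it), take one inner gradient step at rate α (default 0.01) on the softmax
support loss, then evaluate the adapted parameters' evidential loss on a
query set.  With query balancing on (the default), the query set contains
exactly M/C molecules per class, sampled without replacement and disjoint
from the support; a task whose pool cannot furnish the balanced query is
skipped for that epoch (or sampled with replacement, per config).  Episodes
are re-sampled every epoch; a `frozen_split` option reuses one draw per task
for the alternative protocol reading.

Task attention scores each task's mean query node embedding (with a mean
readout this equals the mean query graph embedding) through a single-layer
MLP and softmax-normalizes across the meta-batch; the outer objective is
Σ_t A(T_t)·L′_t.  The embeddings entering the attention are treated as
constants of the meta-gradient — the attention MLP parameters receive
gradient, the encoder does not receive gradient through the attention path.

**Second-order gradients.**  The meta-gradient of the query loss through an
inner step u(θ) = θ − α·m⊙g(θ) is computed as a transpose-Jacobian product
v ← v − α·H(m⊙v), with the Hessian-vector product taken as a central finite
difference of the exact support gradient (step ∝ √machine-ε, exact on
quadratics — the property the test suite checks against the closed-form MAML
gradient).  A first-order switch drops the correction.  The outer optimizer
is Adam at rate β (default 0.005) with a global-norm clip of 50 on the
combined meta-gradient; an epoch budget of a few dozen outer steps makes
plain SGD at small rates a non-starter, occasional gradient spikes (norms
~600 against a typical 1–10) motivate the clip, and a non-finite
meta-gradient skips the update rather than corrupting Θ.  `sgd` remains
available.

Meta-testing copies Θ, adapts it on the new task's labeled support under the
full evidential loss (final annealing weights) for up to `inner_steps_test`
steps (default 5) with early stopping on a support-loss plateau (relative
improvement < 1e−6), and emits per-query evidence, probabilities,
uncertainty, and a predict/reject decision at the configured threshold.  The
meta-state is never mutated.

Defaults: K=3, d=64 for desk-scale synthetic work; K=5, d=300 for chemistry
inputs (matching the widely used pre-trained molecular GIN dimensions —
encoder-only checkpoints in that shape can be loaded directly, though
producing them is out of scope).  N=10, M=16, C=2.  M=16 rather than a
smaller query set because M=8 meta-gradients proved noisy enough to
occasionally push the whole network into the dead-ReLU state.

## Synthetic task families

The generator emulates the structure of few-shot molecular property suites:
binary tasks over small attributed graphs where a graph is positive for task
t exactly when it contains task t's structural motif as a subgraph.  Default
motifs are the cycles C3–C8 — pairwise incomparable under subgraph
containment, so no task's positives are accidentally positive for another.
Backgrounds are random recursive trees plus Poisson(1) extra edges
(connected, molecule-like sparsity); sizes are uniform on 10–20 atoms.  A
positive graph is built by fusing a fresh cycle onto exactly one background
node — sharing a single vertex adds the motif cycle and no other cycle, which
keeps the labels clean (fusing onto several existing nodes creates chords and
spurious cycles of other lengths).  The background for a positive uses
correspondingly fewer nodes, so both classes share one size distribution and
positives are not separable by size.  Negative backgrounds are
rejection-sampled to exclude the task's motif.  Labels are Bernoulli
per graph (`positive_fraction`, down to the 0.002 regime of extreme screening
imbalance via presets); `label_noise` flips labels independently and is the
irreducible error floor returned by `bayes_error_estimate`.

Motif nodes carry a distinguished "reactive-center" atom code with
probability 0.9, shared across tasks by default.  Two reasons.  First,
detecting an unattributed cycle is at or beyond the expressive ceiling of a
Weisfeiler-Lehman-bounded encoder, so a purely structural signal cannot be
expected to be learnable by a GIN at any scale.  Second, meta-learning only
helps when tasks share transferable structure (as real toxicity tasks share
toxophore chemistry); with task-specific codes (available via
`per_task_signal_code`) a held-out task's signal is never predictive during
meta-training, and transfer would have to happen purely at the representation
level — far beyond a 30-epoch desk-scale budget.

What passing tests on these tasks shows: the episodic pipeline, the
evidential math, the meta-gradients and the imbalance mechanism all function
end to end on problems whose Bayes error is known (the label noise) and whose
solvability is guaranteed (a brute-force subgraph-isomorphism oracle achieves
100% at zero noise).  What it does not show: performance on real chemistry —
synthetic graphs are not valid molecules, their signal is far cleaner than a
real structure–activity relationship, and no pre-trained encoder is involved.

## Evaluation

ROC-AUC uses the positive-class Dirichlet probability as the score (rank
based, ties at 1/2; single-class label sets raise).  Minority-class precision
is computed at the argmax operating point (for C=2 this is the 0.5
probability cut), with an explicit flag separating "no minority predictions
made" from a true zero.  Threshold curves retain predictions with u ≤ t
(inclusive) and report accuracy among the retained; because the denominator
under rejection is a reporting choice, the curve also carries the
rejections-count-as-errors variant.  Task-averaged numbers are unweighted
means over test tasks.

The canonical imbalance experiment (positive fraction 0.05) compares
meta-training with balanced versus random query sampling at matched seeds and
epochs, and evaluates both arms with a stratified 5-per-class test-time
support set.  With 10 uniform support draws at 5% positives the support is
usually all-negative, adaptation pushes every prediction negative in both
arms, and the training-time mechanism is hidden behind the test protocol;
per-class support is the standard protocol for imbalanced few-shot molecular
benchmarks.

## Numerical and degenerate-input choices

* Uncertainty/probability clamp 1e−7 before logarithms; zero gradient at the
  clamp.
* Argmax ties resolve to the lower class index, deterministically.
* M must be divisible by C under balanced sampling (config validation).
* Empty tasks are loaded but flagged; episode sampling on them raises.
* Unparseable SMILES raise at the single-molecule level and are logged and
  skipped by the batch CSV loader.
* One master seed fans out (via independent seed-sequence children) to
  parameter initialization, episode sampling and task splitting; run
  directories record the resolved config, seeds and library versions, and
  checkpoints restore parameters and the rng stream position bitwise.

## Known limitations

* No self-supervised encoder pre-training; results on real chemistry data
  will reflect a from-scratch encoder.
* The AvUC weighting deviates from a constant-strength reading (see Loss):
  mandatory for from-scratch stability here, but a pre-trained encoder might
  tolerate — and a faithful large-scale reproduction might prefer — the
  constant-strength form.
* Finite-difference Hessian-vector products are exact only on locally
  quadratic objectives; ReLU kinks add O(√ε)-scale noise to second-order
  meta-gradients.
* Binary tasks only; no scaffold splitting, descriptors, conformers or
  regression.
* Meta-batch is all training tasks per epoch (subsampling available), which
  is fine for tens of tasks but not thousands.
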