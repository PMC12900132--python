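# Methods

## Problem setting

Per-segment EEG differential-entropy features form a tensor
`(n_segments, n_channels, n_bands)` with an emotion label per segment
and subject / session / trial metadata.  A *source* domain is labeled;
a *target* domain (held-out trials of the same subject, or a held-out
subject) is unlabeled.  The goal is target-domain emotion accuracy.

## Model

**Graph extractor.**  Channels are graph nodes.  The adjacency is a
free parameter: the stored matrix is unconstrained, and every forward
pass uses `A = (W + Wᵀ)/2` so symmetry is structural rather than
penalized — gradients of any loss w.r.t. `W` are then symmetric, and
RMSprop's elementwise update preserves symmetry exactly (asserted in
tests).  Initialization is uniform on `(−1/√N, 1/√N)`; the bound is
configurable (`adjacency_init_bound`) since a Xavier-style init for a
square matrix can be read with either a `1/√N` or `1/N` bound — we use
`1/√N`.  Normalization is `ReLU`, degree, `D^{−1/2} A' D^{−1/2}` with a
`max(D_ii, 1e−8)` guard: a node whose incident weights are all rectified
to zero yields an exactly-zero row/column instead of a division
blow-up.  All eigenvalues of the normalized operator lie in `[−1, 1]`
(its symmetrized normalization is doubly substochastic), so the
Chebyshev recursion is numerically bounded at any order.  The filter
bank is rebuilt from the live adjacency at every forward pass — never
cached — so gradients always reach `A`.

**Depth and width.**  One graph-convolution layer with Chebyshev order
`K = 3` and 8 output features per channel; both are config keys
(`gcn_layers`, `cheb_order`, `gcn_out_dim`).  `K = 3` is the standard
order for this family of models; the narrow 8-wide output (and the
16-unit discriminator hidden layers) are a deliberate choice: with wide
features and discriminators the domain discriminator separates the
domains almost immediately, the BCE gradient reaching the extractor
saturates to zero, and adversarial adaptation never engages.  Narrow
heads keep the two-player game alive at CPU scale.  An ablation
extractor (`extractor="mlp"`) replaces the graph convolution with two
linear layers on the flattened 310-style vector, matching output
dimensionality so every head is interchangeable.

**Discriminators and reversal schedule.**  Both discriminators are
two-layer perceptrons with Leaky ReLU (slope 0.01 everywhere, the
common default).  The reversal coefficient ramps as
`2(hi−lo)/(1+exp(−α·iter/max_iters)) − (hi−lo) + lo` with
`hi = 0.9, lo = 0.5, α = 10`; it equals `lo` exactly at iteration zero,
is strictly increasing, and approaches but never reaches `hi`.  The
iteration counter advances once per optimizer step against
`max_iters = steps_per_epoch × epochs`.

**Individual branch.**  The literature is genuinely ambiguous about
whether the subject-discriminator branch should reverse gradients
(suppressing subject-specific structure) or cooperate (preserving it);
the architecture diagrams show a reversal layer, while the prose argues
for preserving individual patterns.  We keep the reversal but give the
branch its own, much weaker ramp (defaults `lo = 0.1`, `hi = 0.18`,
about one fifth of the domain branch; `individual_grl_hi/lo` config
keys, `None` shares the domain schedule, `0` disables the gradient
entirely).  Empirically on the bundled benchmark, full-strength reversal
on this branch consistently *hurt* the full model below its own
ablation, while the weak reversal reproduces the expected ordering
(full model best); this is the package's resolution of the ambiguity.
When source and target contain a single subject between them the branch
is disabled automatically (a one-class cross-entropy is undefined) with
a warning.

**Losses.**  All probabilities are clamped to `[1e−7, 1 − 1e−7]` before
logs.  The classification head defaults to one-vs-all BCE on one-hot
labels with per-class sigmoids (the literal multi-class-BCE reading);
`cls_head="softmax_ce"` switches to conventional softmax cross-entropy.
Confident-target selection uses max class probability with threshold
0.9 (`cluster.threshold`), or a top-fraction rule
(`cluster_rule="top_fraction"`).  The cluster term's `d_T` is the domain
discriminator's output on the selected target rows, taken through the
same reversal-fronted forward pass as the domain loss — the
architecture-literal reading in which everything entering the
discriminator passes the GRL; the discriminator itself is thereby pushed
to emit the source label on confident targets, compacting its decision
space.  Routing the term around the GRL (so the extractor directly pulls
targets toward the source side) was evaluated and destabilized training
badly, so it is not offered.  The cluster weight defaults to
`λ = 0.1`: at `λ = 1` the term dominates the adversarial game once many
targets become confident and training collapses; at 0.1 it acts as the
intended mild regularizer.

**Optimization.**  RMSprop with learning rate 5·10⁻⁴, smoothing 0.99,
eps 1e−8 (standard library defaults), and L2 weight decay 1e−4 applied
to every parameter including the adjacency.  Batch 96, split 48/48
between source and target; when the source is larger, the target side
is reshuffled and cycled so every batch sees both domains (the
`make_domain_batches` function itself defaults to strict
once-per-epoch semantics on both sides; training passes
`cycle_target=True`).  Inputs are z-scored per (channel, band) over the
pooled source + target segments — label-free, standard practice for DE
features (`standardize=False` disables).  Reported accuracy is the
final-epoch model's; an optional per-epoch target-accuracy trace is
computed through a callback that never feeds labels into training.  A
non-finite loss aborts with an error naming the step.  All arithmetic
is float64, which keeps the gradient checks and loss oracles tight at
the cost of some speed.

## Protocols

* `subject_dependent`: per (subject, session), the first 9 of exactly 15
  trials are the source and the last 6 the target (16/8 for the
  four-class 24-trial variant).  Sessions with any other trial count are
  rejected rather than silently truncated.
* `loso`: each subject in turn is the whole unlabeled target; all others
  form the source.

Aggregation reports mean and *sample* standard deviation (ddof = 1; one
split gives 0) over splits; confusion matrices are pooled over splits
before row-normalization.  Every number in any artifact is recomputable
from the persisted per-split JSON.

## Synthetic generator

`SynthSpec` defaults — 6 subjects × 1 session × 15 trials × 40 segments,
16 channels × 5 bands, 3 classes — are the package's benchmark, sized
for CPU runs in minutes.  Structure:

* **Communities.**  Channels belong to `min(4, N)` contiguous
  communities.  Class means blend an independent per-channel profile
  with a community-level profile (weight `graph_strength = 0.7`), and
  segment noise mixes a community-shared component with an independent
  one in the same proportion — so cross-channel correlation is higher
  within communities than between (verified statistically in tests).
* **Subject shift.**  Each subject applies an affine map: a channel
  mixing gain `I + 0.2·s·R/√N` and an offset drawn *in the span of the
  centered class-mean directions*, scaled by `subject_shift = 1.2`.
  The offset is therefore decision-relevant (it moves a subject's
  responses along the class axes, which is what breaks source-only
  transfer) while remaining small in norm relative to the segment noise
  (so domains overlap and the domain discriminator cannot saturate
  instantly).  This was calibrated once: with isotropic
  high-dimensional offsets the domains become linearly separable, the
  discriminator wins immediately and *no* configuration of the model
  can adapt — an uninformative benchmark.  With the calibrated defaults
  a source-only classifier loses ≈ 0.12 accuracy on held-out subjects
  relative to held-out trials of seen subjects, and the full adversarial
  model recovers a consistent part of that gap on every tested seed.
* **Trials** cycle through classes in order so prefix/suffix trial
  splits are class-stratified, and each trial holds one class, as in
  film-clip elicitation.

What it does **not** emulate: biophysical EEG structure (1/f spectra,
volume conduction, electrode geometry), temporal autocorrelation within
trials, label noise, or session effects beyond the subject transform.
Passing the benchmark therefore demonstrates that the adversarial
machinery works on a controlled covariate-shift problem of realistic
shape — not that any particular accuracy will be reached on real
recordings.

## Benchmark and problem sizes

The ablation benchmark trains three variants — full model, without the
individual discriminator, and a source-only classifier (no domain
discriminator, no cluster term, reversal pinned to zero) — on all six
LOSO folds for five training seeds at 20 epochs, and compares mean
target accuracies.  Reference means (seeds 0–4): full ≈ 0.691, without
individual discriminator ≈ 0.678, source-only ≈ 0.658, with the full
model ahead on every individual seed.  The graph-vs-MLP extractor
comparison is *not* asserted: on this generator the two are
statistically indistinguishable (the sign flips across seeds), because
the MLP sees the same flattened features and the community correlation
structure does not specifically advantage the spectral filter at this
scale.  Unit and property tests use much smaller sets (2–4 subjects,
4–8 channels, a few epochs).

## Known limitations

* The reference protocol's 1000-epoch training on 62-channel data is
  far beyond the bundled benchmark's scale; defaults here are tuned for
  the synthetic sizes, and real-data use will want wider layers
  (`gcn_out_dim`, `disc_hidden`) and the full epoch budget.
* Adversarial training with a shared optimizer is sensitive to the
  discriminator/extractor capacity balance; the saturation failure mode
  described above reappears if the discriminator is made much stronger.
* The similarity-matrix reading of confident-target selection mentioned
  in the source literature is not formulated anywhere and is not
  implemented; only confidence-based selection is offered.
* MAT v7.3 reading assumes plain numeric per-trial arrays (the layout
  of the DE feature releases and of the bundled fixture writer), not
  arbitrary MATLAB objects.
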