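# Methods

## Model

A consultation sample carries three token-sequence feature arrays (text,
audio, visual), a label (condition class or a continuous assessment score in
[−3, 3]), a per-modality binary flag marking synthetically generated
content, and an environment context vector.

**Encoding.** Tokens are L2-normalised per token, projected to the model
width d_τ, passed through one single-head scaled-dot-product self-attention
block with a residual two-layer feed-forward, and mean-pooled over the
sequence. Mean pooling makes the utterance vector invariant to duplicating
the token sequence, which the tests assert.

**Shared/specific split.** One shared encoder (a two-layer feed-forward
block; a single parameter set applied to all three modalities) maps
utterances to modality-invariant features; three parameter-disjoint specific
encoders produce modality-private features of the same width (d_s = d_u,
asserted at construction). A decoder reconstructs the utterance vector from
the concatenated pair.

**Losses.**

* *Similarity*: mean pairwise CMD between the batch distributions of the
  three shared-feature sets. CMD sums normalised differences of the mean
  vector and the order-2..K central moment vectors (divisor n, K = 5 by
  default). The normalising range width defaults to 1 because the
  representation space is unbounded; it is configurable for bounded spaces.
  Batch-level CMD uses the sample axis; the contrastive terms apply CMD to
  single vectors by reading coordinates as observations of a scalar
  distribution — the only reading with non-trivial higher moments for a
  lone vector.
* *Distinctiveness*: the mean of six absolute cosines (shared–specific
  within each modality; specific–specific across modality pairs), averaged
  over the batch; bounded in [0, 1]. The absolute value makes orthogonality,
  not anti-alignment, the minimiser. Zero-norm vectors contribute cosine 0
  with a warning rather than NaN.
* *Contrast*: per anchor and per (feature type, modality) key,
  max(0, margin + mean CMD to positives − mean CMD to negatives), averaged
  over the six keys and over anchors. The hinge (default margin 0.2) bounds
  an otherwise unbounded objective. Positives and negatives are drawn
  within the mini-batch by label equality (regression: |Δscore| < 0.5);
  anchors lacking either set are excluded from the average, with N = M = 4
  by default and fewer used when the batch runs short.
* *Reconstruction*: batch-mean of the per-modality squared reconstruction
  error (averaged over the three modalities), plus an optional λ/2 decoder
  norm penalty.

The objective is L_task + β₁(L_sim + L_diff) + β₂ L_contrast + β₃ L_recon
with reference weights (0.7, 0.8, 0.5). The L2 regularisation of 1e−5 is
applied once, as AdamW's decoupled weight decay over all parameters; the
explicit λ terms in the reconstruction and task losses exist in the API but
default to zero inside the training objective to avoid double-counting.

**Fusion.** The concatenated [shared; specific] vector is read as a
two-token sequence, self-attended and mean-pooled to ξ_m (attention needs a
sequence axis; the two-token reading is the minimal one). Cross-attention
uses the text vector as query against each non-text modality as a
single-token key/value; with one key the softmax weight is exactly 1, so
the output reduces to the value projection of the attended modality — a
documented consequence of the single-token design, asserted in tests. A
shared gate network maps each cross-attention output to a scalar weight in
(0, 1); a shared calibration network, conditioned on the modality's
synthetic flag, yields c_m ∈ (0, 1). Calibration factors are computed for
all three modalities but applied only to audio and visual — text is the
anchor with weight 1. The calibration head carries no dropout: its gradient
is weak (present only on flagged samples) and accumulates slowly, and
dropout noise in that head drowns it. The environment vector enters through
a learned linear projection scaled by a learned scalar weight.

**Prediction.** A two-layer MLP head with softmax (classification) or
linear (regression) output. Cross-entropy clamps the log at 1e−12.
Continuous scores are evaluated with MAE, Pearson correlation, sign-split
accuracy (Acc-2, negative vs non-negative), binary F1 on that split,
7-bin accuracy (integers clipped to [−3, 3], bin edges at half-integers)
and a predicted-by-true confusion matrix; categorical tasks report
accuracy and macro-F1. The generative outputs (summary, avatar,
explanation) exist only as a no-op hook interface.

## Differentiation and optimisation

No installed package provides reverse-mode differentiation, so the network
trains on a small vectorised autodiff tape written on numpy
(`mmlmh._tensor`): float64 throughout, broadcasting-aware, with the
operations the model needs. The CMD forward pass is exact; the square-root
backward clamps its denominator at 1e−12 so a zero discrepancy does not
produce infinite gradients. Optimisation is AdamW (lr 1e−4 at reference
scale, 1e−3 in the desk-scale profile), batch 32, early stopping on the
validation task loss with patience 10 and best-checkpoint restoration. The
task loss is monitored rather than the full composite because the
contrastive term would make the monitored quantity depend on sampling.
Training is deterministic per seed: one seed sequence spawns separate
streams for initialisation/dropout, batch shuffling and contrastive
selection, so disabling one loss never shifts another's randomness.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
real consultation content:

* a shared latent z (dimension 8 by default) carries the health state —
  class means at regular-simplex vertices scaled by δ (default 3), or a
  linear score read-out plus label noise for regression;
* each channel expresses tanh(A_m(z + η_m) + s·B_m u_m) per token, where
  u_m is a modality-private latent, s the private strength (default 1) and
  η_m a consultation-level channel perturbation (σ_consult = 0.3) drawn
  once per sample: it is coherent across tokens and independent across
  channels, so no single channel is fully reliable and fusing channels
  genuinely helps. Purely per-token noise would average out under mean
  pooling and leave the channels redundant;
* per-token Gaussian noise (σ_m = 0.1) and a fixed random projection lift
  the core to each modality's feature width (32/16/48 at sequence length 8,
  n = 600, by default; the full-scale dimensions are supported via config);
* synthetic-flagged channels (Bernoulli ρ = 0.2 per modality) express the
  shared latent at fidelity 1/κ (κ = 2 by default), mixed with an
  amplitude-matched plausible decoy — for classification, a randomly drawn
  wrong condition. Flagged content is therefore statistically
  indistinguishable from real content but only partly faithful to the
  patient, which is exactly the regime in which a flag-conditioned
  calibration is needed: the flag, not the feature distribution, carries
  the reliability information. Additive-noise corruption was rejected
  because it is amplitude-visible — the feature-driven gates absorb it and
  the loss-optimal calibration then *compensates* the tanh attenuation
  upward rather than down-weighting. An optional constant bias field
  models systematic generator offset (default 0);
* the environment vector is weakly label-associated (effect 0.5, noise 1).

A channel with `informative=False` omits the shared-latent term entirely
and is statistically independent of the label.

What the generator does not emulate: real language/audio/video content,
temporal token structure beyond exchangeability, label noise models other
than Gaussian, and any particular clinical population. Passing tests
therefore show that the machinery recovers the structure it targets when
that structure is present — not that it performs at any level on real
consultation corpora.

## Study fixtures and problem sizes

All studies run in minutes on one CPU at the desk-scale profile
(widths 32, hidden 64, lr 1e−3):

* *attention/gate contracts*: 5 epochs on the default fixture with per-step
  diagnostics;
* *orthogonality dynamics*: 20 epochs, full objective, 5 seeds, default
  fixture; the mean |cos(specific, shared)| falls by an order of magnitude;
* *gate recovery*: visual channel generated label-free, 10 seeds, 8 epochs,
  n = 360; medians of adjusted gates compared on the held-out split;
* *calibration recovery*: ρ = 0.3, κ = 4 (quarter fidelity), score
  regression, 10 seeds, 25 epochs. Regression is used because
  cross-entropy saturates on separable fixtures and removes the gradient
  pressure on the calibration head, while squared error stays sensitive to
  channel reliability throughout training. The gap is measured over the
  applied modalities (audio, visual; the text factor is computed but never
  applied, so it receives no gradient) and over the whole fixture, because
  the 15 % test split leaves too few flagged samples per modality for a
  stable mean;
* *end-to-end learnability*: δ = 4, σ = 0.05, no synthetic flags — the
  corruption-free fixture isolates method error;
* *score recovery*: clean features, private strength 0.3 (keeping the score
  linearly decodable — at full private strength the tanh mixing destroys
  score information, which a ridge oracle on pooled tokens confirms),
  σ_label = 0.25; the MAE bound is 1.5× the label-noise floor, with the
  floor taken as σ_label;
* *ablation ordering*: one noisy channel plus 30 % flags; the full model is
  compared with the no-intra-sample-collaboration ablation over 5 seeds.

## Numerical choices and degenerate inputs

Moments use divisor n (population convention). Softmax subtracts a
detached row maximum. Cosines use a 1e−12 denominator floor. Batches of
size < 2 are skipped (sample-axis moments undefined). A non-finite training
loss aborts with the epoch and offending term named. Attention maps are
recorded as numpy copies at every step when diagnostics are enabled; their
rows sum to 1 within 1e−6 by construction of the softmax.

## Known limitations

The single-token cross-attention makes the text query mathematically inert
(softmax over one key); token-level cross-attention over full sequences is
out of scope. Attention is single-head. The calibration recovery effect,
while consistently positive in direction, is small in magnitude at desk
scale (mean gap ≈ 0.04 in calibration units) and needs tens of epochs to
emerge. Desk-scale defaults are far below the reference dimensions
(768/128/2048 features, sequences up to 1000); nothing in the code caps
the configurable sizes, but runtimes grow accordingly.
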