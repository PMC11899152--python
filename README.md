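# mmlmh — multimodal consultation health assessment

`mmlmh` implements a collaborative multimodal representation-learning and
adaptive-fusion framework for health assessment from virtual consultations,
where each case carries three feature streams — text, audio and visual token
sequences — a per-modality flag marking synthetically generated (AI-rendered)
content, and a context vector describing the virtual environment. It is
aimed at researchers studying multimodal fusion under mixed real/synthetic
data quality: every stage is trainable and testable on a transparent
synthetic data generator, with no external corpora or pretrained encoders.

## The model

Each modality's token sequence is L2-normalised, projected, passed through a
single-head self-attention encoder block and mean-pooled into an utterance
vector ω_m. Two encoder families split each ω_m:

* a **shared encoder** E_s (one parameter set for all modalities) produces
  modality-invariant features γ_m^s;
* **specific encoders** E_u^m produce modality-private features γ_m^u.

Four losses shape this space:

* **intra-sample similarity** — the mean pairwise central moment discrepancy
  (CMD) between the batch distributions of the shared features,
  CMD_K(X,Y) = Σ_k ‖C_k(X) − C_k(Y)‖₂ / |b−a|^k up to order K = 5;
* **intra-sample distinctiveness** — the mean absolute cosine between
  shared and specific features within a modality and between specific
  features across modalities;
* **inter-sample contrast** — a hinged contrastive term on per-vector CMD:
  max(0, margin + mean CMD to same-condition samples − mean CMD to
  different-condition samples);
* **reconstruction** — MSE of a decoder that rebuilds ω_m from
  [γ_m^s; γ_m^u].

Fusion is two-stage and text-anchored: self-attention over the (shared,
specific) token pair gives per-modality vectors ξ_m; cross-attention outputs
feed a gate w_m = σ(W_g·CA(ξ_τ, ξ_m) + b_g); a calibration network
conditioned on the synthetic flag yields c_m ∈ (0,1), and

    ξ_final = ξ_τ + w'_α ξ_α + w'_ν ξ_ν + w_e·P_e(e),   w'_m = w_m · c_m.

An MLP head predicts a condition class (softmax + cross-entropy) or a
continuous assessment score in [−3, 3] (linear + MSE). The training
objective is L_task + β₁·L_intra + β₂·L_inter + β₃·L_recon with reference
weights β = (0.7, 0.8, 0.5), optimised with AdamW and early stopping.
Evaluation reports MAE, Pearson correlation, sign-split accuracy (Acc-2),
F1, 7-bin accuracy (Acc-7) and a confusion matrix.

The package includes a minimal reverse-mode autodiff engine on numpy
(`mmlmh._tensor`, `mmlmh.nn`) that the whole network trains on — CPU-only,
float64, deterministic under a seed.

## Worked example

```python
from mmlmh import (SyntheticDatasetSpec, generate, TrainConfig,
                   MultimodalHealthModel, stratified_split)

ds = generate(SyntheticDatasetSpec(n_samples=600, seed=11))
train, val, test = stratified_split(ds, seed=0)
cfg = TrainConfig.small(task="classification", seed=0)
results = MultimodalHealthModel(train, cfg, validation=val).fit(epochs=15)
print(results.summary())
print(results.evaluate(test).accuracy)
```

prints

```
Multimodal health-assessment model — fit results
====================================================
task                 classification (3 classes)
n train / val        420 / 90
parameters           63942
epochs run (best)    15 (8)
config hash / seed   97ae78a5e2d01127 / 0
wall time            5.8 s
final training losses:
  l_task       0.0949
  l_intra      0.0776
  l_inter      0.1620
  l_recon      0.0965
  l_total      0.3271
validation metrics:
  accuracy     87.7778
  macro_f1     87.6796
```

and a held-out accuracy of 87.8 %. The losses show the composite objective
at work: the orthogonality and CMD terms have pulled the shared/specific
split apart (l_intra 0.08) while the task loss has dropped to 0.09.
`results.fusion_diagnostics(test)` exposes per-sample gates and
calibrations — e.g. a sample whose audio stream is synthetic-flagged gets
c_audio ≈ 0.64 against ≈ 0.82 for a clean one, so its adjusted audio weight
is roughly halved.

A `mmlmh` command-line interface wraps the same pipeline:

```bash
mmlmh simulate --out data.h5
mmlmh train --data data.h5 --out run/
mmlmh evaluate --model run/checkpoint.npz --data data.h5 --report report.json
mmlmh ablate --data data.h5 --out ablation.csv
```

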