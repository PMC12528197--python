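# eegformer

An adaptive-attention transformer for EEG epoch classification, written
for researchers who want an end-to-end, fully inspectable pipeline:
synthetic multi-channel EEG with known ground truth, ICA/band-pass
preprocessing, band-power features, a transformer that models temporal
and spatial structure jointly, and an evaluation suite with a
noise-robustness protocol.  The model and its gradients are implemented
directly in NumPy, so every quantity — attention weights, mask values,
loss terms — is a plain array you can look at.

## The model

EEG recordings (channels × samples, microvolts) are band-pass filtered
(0.5–50 Hz, zero-phase Butterworth), cleaned by Independent Component
Analysis (`X = A S`; components dominated by high kurtosis or sub-4 Hz
power are removed), and cut into 2-s epochs at 256 Hz.

Each channel's epoch is tokenized into P frames, linearly embedded
(`E_c = W_c S_c + b_c`) and summed with the sinusoidal positional
encoding `PE(pos, 2i) = sin(pos / 10000^{2i/d})`, `PE(pos, 2i+1) =
cos(·)`.  A stack of pre-norm encoder layers applies multi-head temporal
self-attention

```
A = softmax(Q Kᵀ / √d_k)
```

modulated by a **learned adaptive mask** `M = σ(logits) ∈ (0,1)`:
`Â ∝ A ∘ M`, row-renormalized so value mixing stays a convex
combination.  The mask trains jointly with the network under

```
L = CE + λ_mask · Σᵢⱼ (1 − Mᵢⱼ) Aᵢⱼ + λ_sparsity · mean(M)
```

— the middle term penalizes attention mass retained in down-weighted
regions, the last keeps the trivial all-open mask from being optimal.
A position-wise ReLU feed-forward block follows attention.  Token
sequences are mean-pooled per channel, a **spatial attention** block
(`A_s(i,j) = exp(e_ij) / Σ_k exp(e_ik)` over scaled dot-product channel
similarities) pools the channel summaries into one vector, and a softmax
head yields class probabilities `P(y=k|x)`.

Evaluation reports accuracy, precision, recall, specificity, F1 and AUC
(rank-based), and a robustness sweep re-scores held-out epochs with
added Gaussian noise at X% of each epoch-channel's standard deviation.

Because public clinical corpora cannot ship with a package, a seeded
synthetic generator stands in for them: classes are defined by relative
band-power signatures (delta/theta/alpha/beta/gamma sources mixed by a
random full-rank matrix), with eye-blink-like frontal transients, mains
contamination and additive sensor noise layered on.  Real EDF
recordings can be read directly.

## Worked example

```python
from eegformer import (ModelConfig, TrainSpec, evaluate,
                       make_classification_task, noise_robustness, train)

data = make_classification_task(n_epochs_per_class=200, n_channels=8, seed=0)
config = ModelConfig(n_layers=2, n_heads=4, d_model=64, d_ff=128, n_classes=2,
                     n_channels=8, seq_len=16, frame_dim=32, seed=0)
result = train(data, config, TrainSpec(lr=0.001, max_epochs=15, patience=5, seed=0))
report = evaluate(result.model, result.test_set)
print(f"held-out accuracy={report.accuracy:.3f}  auc={report.auc:.3f}")
sweep = noise_robustness(result.model, result.test_set, [10.0, 20.0, 30.0], seed=0)
for level, rep in sweep.items():
    print(f"noise {level:>4.0f}%  accuracy={rep.accuracy:.3f}")
mask = result.model.mask_matrix(0)
print(f"layer-0 mask: mean={mask.mean():.3f}  min={mask.min():.3f}  max={mask.max():.3f}")
```

prints (about 30 s on one CPU):

```
held-out accuracy=1.000  auc=1.000
noise   10%  accuracy=1.000
noise   20%  accuracy=1.000
noise   30%  accuracy=1.000
layer-0 mask: mean=0.893  min=0.892  max=0.893
```

The two synthetic classes (alpha- vs theta-dominant signatures) are
separable in band-power space by construction, so the small model
reaches ceiling accuracy on held-out epochs and stays there under
moderate noise; the mask values show how much attention each
position-pair retains (`σ(2) ≈ 0.88` at initialization, pulled down by
the sparsity term and up by the retention term).

The same pipeline is available from the shell:

```
eegformer simulate -o sim/                    # seeded recordings + manifest
eegformer preprocess sim/rec000_alpha.npz -o epochs.npz
eegformer train epochs.npz -o run/            # checkpoint, history, metrics
eegformer noise run/model.npz epochs.npz -o noise.csv
eegformer attention run/model.npz epochs.npz -o maps/   # PNG + NPZ heatmaps
```

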