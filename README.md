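# mcaunet

Automatic gallbladder segmentation on abdominal CT with a **multi-scale
channel attention U-Net** family — for medical-imaging researchers who want a
small, fully inspectable, CPU-trainable implementation of the method and a
synthetic benchmark to exercise it without clinical data.

The gallbladder is a hard target: it occupies roughly 0.55% of the pixels of
an abdominal slice and sits against the liver with weak contrast. The package
addresses this with:

* a CT preparation chain — Hounsfield conversion, window/level (default
  60/400 HU), CLAHE, min–max normalization;
* the model family — baseline U-Net (pinned so that it has exactly
  **1,940,817** parameters), SEU-Net (channel squeeze-and-excitation), and
  MCAU-Net-1/2/3, whose encoder stages are replaced by **MCA blocks**:
  parallel 3/5/7 (or 5/7/9) convolutions fused by a 1x1 convolution, gated by
  channel attention computed from global descriptors at pooling scales 1/2/4;
* training with the soft Dice loss
  `L = 1 − (2·Σ pᵢgᵢ + ε) / (Σ pᵢ + Σ gᵢ + ε)`
  (binary cross-entropy as comparator), Adam, and continuous exponential
  learning-rate decay `lr₀·rate^(step/steps)`;
* a seven-metric evaluation suite — DSC, JSC, PPV, SE, Hausdorff distance,
  RVD, VOE — with cohort aggregation (mean ± sd, median, quartiles, 1.5-IQR
  whiskers);
* a seeded synthetic **phantom generator** emulating the imbalance statistic
  (single hypodense ellipse, ~0.55% of pixels, inside a liver-like textured
  region with look-alike distractors), so everything is testable end to end.

The network layers (convolutions, batch norm, pooling, Adam) are implemented
in a compact NumPy reverse-mode autodiff engine (`mcaunet.nn`), verified
against finite differences; no deep-learning framework is required.

## Worked example

Train MCAU-Net-2 at desk scale on synthetic phantoms and evaluate it:

```python
from mcaunet import data, workflow

spec = data.PhantomSpec(size=(64, 64), seed=42)   # fg target 0.55% of pixels
train_set = data.make_phantom_dataset(200, spec, start_index=0)
val_set   = data.make_phantom_dataset(40,  spec, start_index=200)

cfg = workflow.smoke_config("mcau2", seed=42, epochs=10)  # batch 4, Dice loss
model, record = workflow.train(cfg, train_set, val_set)
print(f"best val DSC {record.best_val_dsc:.3f} at epoch {record.best_epoch + 1}")
```

which prints (about 70 s on one CPU):

```
best val DSC 0.882 at epoch 10
```

i.e. the best checkpoint overlaps the held-out phantom masks with a mean Dice
coefficient of 0.882 — above the 0.70 bar conventionally regarded as
acceptable for organ segmentation. The same split evaluated with the full
metric suite:

```python
agg = workflow.evaluate(model, val_set)
print({m: round(s.mean, 3) for m, s in agg.stats.items()})
```

```
{'dsc': 0.882, 'jsc': 0.794, 'ppv': 0.952, 'se': 0.831, 'hd': 1.068,
 'rvd': 0.141, 'voe': 0.206}
```

DSC/JSC measure overlap (1 is perfect), PPV the fraction of predicted
foreground that is correct, SE the fraction of true foreground recovered, HD
the worst boundary disagreement in pixels, RVD the relative area error, and
VOE = 1 − JSC the overlap error.

A command-line interface mirrors the library:
`mcaunet phantoms`, `split`, `train`, `evaluate`, `compare`, `params`,
`preprocess` (see `mcaunet --help`).

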