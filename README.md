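# icsms — lightweight grape-leaf cultivar classification

`icsms` implements a family of lightweight convolutional classifiers for
fine-grained grape-leaf cultivar identification in cluttered vineyard
scenes, centred on the **ICS-MS** model: a MobileNetV3-Small backbone whose
squeeze-and-excitation gates are replaced by **coordinate attention**
(pooling factorized along the height and width axes, so the gates encode
spatial position as well as channel importance), a multi-branch
**ICS-Inception** fusion stage that concatenates deep 7×7 branches with a
high-resolution texture branch under CBAM dual-attention filtering, and
**joint supervision**

    L = L_CE + λ · L_center ,   L_center = ½ Σᵢ ‖f(xᵢ) − μ_{yᵢ}‖² ,

where cross-entropy drives separability and the center loss (weight
λ = 0.01 by default, centers updated by their own SGD rule at α = 0.5)
pulls each sample's projected feature toward its class centroid.

The design target is budget-exact lightweightness: with an 11-class head
the baseline backbone has 1.53 M trainable parameters, the
coordinate-attention swap 1.37 M, the fused CE-only model 1.12 M, and the
full joint-loss model 1.17 M at 0.21 G multiply-accumulates per 224×224×3
image — all verified by a built-in parameter/MAC auditor against a shipped
target table that also covers ResNet-50 (23.53 M), MobileNetV2 (2.24 M),
MobileNetV3-Large (4.2 M) and ShuffleNetV2 (1.26 M).

Everything runs on a compact numpy autodiff core bundled with the package
(`icsms.nn`): no GPU or deep-learning framework is required. A procedural
synthetic vineyard-leaf generator (11 morphologically separable cultivar
presets, 2–4-element natural backgrounds, controlled occlusion bands)
makes the full pipeline testable without downloading any data. See
`docs/methods.md` for the models, parameter choices and their rationale.

## Worked example

```python
import numpy as np
from icsms import factory, synth
from icsms.datapipe import stratified_split
from icsms.traineval import ArrayDataset, TrainConfig, train_model, evaluate

# 1. audit the flagship model's budget
model = factory.build("ICS-MS", num_classes=11, seed=7)
print(factory.count_parameters(model))          # 1170664  (1.17 M)
print(factory.to_giga(factory.count_macs(model)))  # 0.21

# 2. generate the tiny synthetic benchmark (20 images/class) and train
images, labels, manifest = synth.generate_arrays(per_class=20, seed=7)
manifest = stratified_split(manifest, seed=7)
data = ArrayDataset.from_manifest(manifest, images=images)
cfg = TrainConfig(batch_size=16, epochs=20, lr=1e-3, lam=0.01,
                  image_size=96, seed=7)
model, history = train_model(model, data, cfg)
report = evaluate(model, data, "test", cfg)
print(round(report.accuracy, 1))                # 59.1
```

The parameter count is the exact number of trainable scalars (the rounded
1.17 M is what budget tables print); 0.21 is the per-image compute in G
multiply-accumulates. The final number is held-out accuracy on the tiny
synthetic benchmark after 20 epochs — about 6.5× the 11-class chance rate
of 9.1%, which is the desk-scale signal that the architecture and joint
loss train correctly (real-photograph accuracy requires the external
dataset and GPU-scale training; see `docs/methods.md`).

## Command-line interface

```bash
icsms audit --classes 11              # budget audit vs the shipped table
icsms synth --preset tiny --out data/ --seed 0
icsms train --data data/ --variant ICS-MS --config cfg.yaml
icsms eval --weights model.npz --data data/
icsms crossval --data data/ --k 5
icsms sweep --data data/ --lambdas 0,0.01,0.05,0.1,0.2
```

`synth --preset paper` generates the full 6051-image layout with the
published per-class counts and the 65/25/10 occlusion mix.

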