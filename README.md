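# viewseg

View-routed joint **segmentation and detection** of brain tumors in 2-D
MRI slices — for researchers and engineers who want a fully reproducible,
CPU-scale reimplementation of a view-specific
segmentation-plus-classification workflow, exercisable end-to-end on
synthetic phantoms instead of clinical data.

MRI slices come in three anatomical orientations (axial, coronal,
sagittal) with very different geometry. `viewseg` first classifies each
slice's orientation with a small CNN `g`, then routes it to the U-Net-style
encoder–decoder `f_v` trained for that view, and finally converts the
predicted mask `S` into a tumor-present/absent label `p` with a
classification header `h`:

    v ← g(I)            view ∈ {0 axial, 1 coronal, 2 sagittal}
    S ← f_v(I)          per-pixel tumor probability map
    p ← h(S)            image-level tumor label

Training minimises a composite objective

    L_total = (1 − λ)·L_seg + λ·L_cls
    L_seg   = w·L_Dice + (1 − w)·L_Tversky(α, β)
    L_cls   = γ·L_BCE + (1 − γ)·L_IoU

with defaults `w = 0.4, α = 0.7, β = 0.3, γ = 0.7, λ = 0.2` and smoothing
`ε = 1e−6`; the view classifier minimises inverse-frequency weighted
cross-entropy. Evaluation binarizes probability maps at 0.65 and reports
per-image IoU/Dice plus image-level detection precision/recall/F1. See
`docs/methods.md` for the full model description, the synthetic phantom
generator, and every numerical convention.

The networks run on a compact NumPy layer stack (`viewseg.nn`) with
hand-written backward passes and AdamW — no GPU or deep-learning
framework required; every build and training run is bit-reproducible
from integer seeds.

## Worked example

Generate phantoms, train one per-view model, and score it:

```python
from viewseg import (PhantomSpec, generate_dataset, split_dataset,
                     SegClassConfig, build_segclass_model,
                     TrainConfig, train_segclass, evaluate, ViewLabel)

samples = generate_dataset(300, view_mix=(1, 0, 0), tumor_rate=0.7,
                           template=PhantomSpec(image_size=64), seed=11)
train, val, test = split_dataset(samples, seed=11)

model = build_segclass_model(SegClassConfig(base_channels=6), seed=0,
                             view=ViewLabel.AXIAL)
cfg = TrainConfig(epochs=15, batch_size=8, learning_rate=1e-3, seed=0)
model, history = train_segclass(model, train, val, cfg)

res = evaluate(model, test, tau=0.65)
print(res["overall"])
```

On the 30 held-out axial phantoms this prints (about a minute of
training on one CPU):

```
MetricsRecord(iou=0.9357, dice=0.9658, f1=1.0, precision=1.0,
              recall=1.0, accuracy=1.0, extra={'n': 30, 'pixel_f1': 0.958})
```

i.e. the predicted masks overlap the ground truth at Dice 0.97, and every
one of the 30 images is correctly called tumor/no-tumor.

The same workflow is available from the shell:

```sh
viewseg synth --n 300 --tumor-rate 0.7 --seed 0 --out data/
viewseg train-view --data data/ --out runs/classifier.npz
viewseg train-seg  --view axial --data data/ --out runs/axial.npz
viewseg infer --bundle runs/bundle/ --input data/ --output out/
viewseg sweep --param lambda --values 0.2,1.0 --data data/ --view axial
```

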