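# cambnet

Classification of breast-cancer molecular subtype — **luminal**
(hormone-receptor-positive, luminal A/B) versus **non-luminal**
(HER2-overexpressing, triple-negative) — from DCE-MRI tumor patches, for
researchers studying non-invasive alternatives to biopsy-based
immunohistochemical subtyping. Radiologically, luminal masses tend to be
irregular and spiculated while triple-negative disease often shows a
well-defined round mass with ring (annular) enhancement; the package
implements a network built around exactly these cues, together with the
full pipeline around it:

* **CAMBNet**, a cross-attention multi-branch CNN (~26k parameters): a
  shared 3×3 stem feeding a residual shallow-feature branch (1×1→128,
  depthwise 3×3, squeeze-and-excitation, 1×1→16), a depthwise bottleneck
  branch (16→8→16), and an asymmetric-convolution branch (1×1→4, then
  alternating 1×3/3×1 through 4-8-8-8-16). The two tumor-locating branches
  exchange single-path attention — channel weights from one gate the
  other, spatial weights the reverse — before additive fusion,
  concatenation with the shallow branch, and a deep feature-extraction
  head (maxpool, 1×1→128, stride-2 depthwise, SE, 1×1→64, maxpool, GAP,
  dropout, linear 64→2).
* **ROI preprocessing**: contour extremes → minimum bounding box → 10 px
  margin (clipped at the frame) → crop → bilinear resize to 64×64 →
  per-channel normalisation (x − 0.5)/0.5.
* **Training**: patient-wise stratified 80/20 split (no patient crosses
  sets), 15% of training patients held out for validation checkpointing,
  optional 5-fold patient-level CV, RMSprop at lr 0.002 × 0.95^⌊e/10⌋,
  batch 8/1, cross-entropy, L2 1e-4, per-kernel max-norm 2.0, dihedral
  (rotation/diagonal-flip) augmentation.
* **Evaluation**: Acc/Pre/Rec/F1 from confusion counts (macro-averaged
  headline, per-class retained), midrank AUC, and subgroup analyses
  stratified at age-at-menarche 14 years and tumor size 20 mm under three
  relabelings (luminal vs non-luminal, TN vs rest, luminal A vs rest).
* **Explainability**: per-stage feature-map grids and Grad-CAM saliency
  with a quantitative tumor-localisation score.
* **Synthetic phantoms**: clinical DCE-MRI cohorts of this kind are not
  redistributable, so a seeded generator renders two-class lesion phantoms
  (spiculated vs ring-enhanced) with contour masks and per-patient
  metadata (menarche age, tumor size) that exercise every stage of the
  pipeline, including the subgroup machinery.

The network, its training loop and Grad-CAM run on a small numpy
autodiff engine included in the package (`cambnet.nn`), with convolution,
pooling and batch-norm primitives verified against finite differences in
the test suite.

## Worked example

```python
from cambnet.synthetic import generate_cohort
from cambnet.training import TrainConfig, train_on_cohort
from cambnet.evaluation import evaluate

cases, meta = generate_cohort(n_cases=60, seed=3)
model, history, plan, patches = train_on_cohort(cases, TrainConfig(max_epochs=10, seed=3))
test = [p for p in patches if p.patient_id in set(plan.test_ids)]
print(evaluate(model, test).as_percent_row())
```

prints

```
{'Acc (%)': 100.0, 'Pre (%)': 100.0, 'Rec (%)': 100.0, 'F1 (%)': 100.0, 'AUC (%)': 100.0}
```

— after 10 epochs on 60 phantoms the held-out 12 patients are classified
perfectly (phantom classes are separable by construction; clinical data is
far harder, see `docs/methods.md`). Asking where the model looked:

```python
from cambnet.explainability import gradcam, localization_score
from cambnet.preprocessing import extract_bounding_box, resize_mask
from cambnet.model import predict_proba

case = next(c for c in cases if c.patient_id == "P0032")   # a test patient
patch = next(p for p in patches if p.patient_id == "P0032")
target = int(predict_proba(model, patch.data[None])[0].argmax())
sal = gradcam(model, patch, target)
mask64 = resize_mask(case.mask, extract_bounding_box(case.mask))
print(round(localization_score(sal, mask64), 3), "vs uniform", round(mask64.mean(), 3))
```

prints `0.827 vs uniform 0.379`: 83% of the saliency mass falls inside the
tumor contour, against 38% for a spatially uniform map — the model's
attention concentrates on the lesion.

The same pipeline is scriptable from the shell:

```sh
cambnet simulate --n 160 --seed 0 --out cohort/
cambnet preprocess --in cohort/ --out patches/
cambnet train --data cohort/ --seed 0 --out ckpt/
cambnet evaluate --ckpt ckpt/checkpoint.npz --data cohort/ --split ckpt/split.json --out results/
cambnet explain --ckpt ckpt/checkpoint.npz --image cohort/P0000_ch0.png \
    --image cohort/P0000_ch1.png --image cohort/P0000_ch2.png \
    --mask cohort/P0000_mask.png --out saliency.png
cambnet run-all --seed 0 --out runs/demo       # everything in one go
cambnet summary                                 # per-stage shape table
```

`cambnet summary` prints the realised per-stage input dimensions next to
the reference architecture table for eyeball diffing.

## Layout

```
src/cambnet/
  synthetic.py        phantom cohort generator
  preprocessing.py    ROI crop / resize / normalise
  nn/                 numpy autodiff engine, layers, RMSprop
  model.py            the CAMBNet architecture
  training.py         splits, schedule, augmentation, training loop
  evaluation.py       metrics, AUC, subgroup analyses
  explainability.py   feature grids, Grad-CAM, localisation score
  config.py, cli.py, pipeline.py   YAML config, CLI, orchestration
docs/methods.md       model, assumptions, parameter choices, limitations
```
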