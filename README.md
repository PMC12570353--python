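# virtualstain

**Weak-label virtual IHC staining: tile-level melanocyte detection in H&E,
trained from aligned serial IHC sections.**

Pathologists assess melanocytic atypia on H&E-stained tissue, but
annotating individual melanocytes on H&E is slow and unreliable — even
experts disagree. Immunohistochemistry (IHC) marks melanocytes
biochemically: antibodies against SOX10 (nuclear) or MelanA/MelPro
(cytoplasmic) deposit brown DAB chromogen on melanocytic cells. This
package implements the full pipeline that turns an archival pair of slides
— one H&E section and one IHC-stained serial section of the same tissue
block — into a melanocyte classifier that needs only H&E at inference
time:

1. **extract & match** tissue sections from each whole-slide image
   (`virtualstain.slides`),
2. **register** the IHC section onto its H&E partner with a similarity +
   coarse B-spline registrar, gating poorly aligned pairs
   (`virtualstain.register`),
3. **label** every 256 × 256 px H&E tile (64 × 64 µm at 0.25 µm/px) from
   the warped IHC: color-deconvolve RGB into hematoxylin/eosin/DAB optical
   densities, remove ink and hemorrhage artifacts, and apply the stain
   rule — positive with ≥ 2 discrete DAB nuclei (SOX10) or ≥ 3%
   DAB-positive area (MelanA/MelPro) (`virtualstain.labeling`),
4. **assemble** patient-stratified 5-fold datasets (stride 128 training /
   256 evaluation tiles, 70/30 train/val injection of melanocyte-free
   negative tiles) (`virtualstain.dataset`),
5. **train & evaluate** stain-specific tile classifiers with early
   stopping, scored by AUROC and AUPRC (`virtualstain.training`; the
   convolutional network, with the activation/gradient access saliency
   needs, lives in `virtualstain.nn`),
6. **visualize** with sliding-window prediction heatmaps and best-case IHC
   label maps (`virtualstain.heatmap`),
7. **explain & compare** models via Guided Grad-CAM / integrated
   gradients, salient-blob detection (≥ 100 px), and cross-stain blob
   IoU/Dice agreement with a mismatched-pair null baseline
   (`virtualstain.saliency`).

Because patient slides cannot ship with the code, the package includes a
first-class synthetic fixture generator (`virtualstain.fixtures`): paired
pseudo-H&E / pseudo-IHC sections with known melanocyte nests, chromogen
rendering through the same Ruifrok–Johnston stain model the labeler
inverts, controllable misalignment, and ink/hemorrhage artifacts. Every
stage is tested against that ground truth.

## The statistics at the core

For a tile with DAB-positive pixel set from the matched IHC region, the
labels are

```
SOX10:   y = 1  iff  #{discrete DAB nuclei} >= 2
MelanA:  y = 1  iff  |DAB pixels| / 256^2   >= 0.03
```

Classifiers are scored with AUROC (pairwise rank statistic, midrank tie
credit) and AUPRC (step-integrated precision–recall, also reported as a
fold over the prevalence baseline). Cross-stain explanation agreement is
measured blob-wise: attribution maps are binarized at 0.2, opened/closed,
and components ≥ 100 px from the two models are matched by nonempty
intersection and scored with IoU = |A∩B|/|A∪B| and Dice = 2|A∩B|/(|A|+|B|),
calibrated against a null of randomly mismatched melanocyte-positive
tiles.

## Worked example

Train and evaluate on the default synthetic study (10 patients, one
768 × 768 px section pair each, cytoplasmic IHC):

```python
from virtualstain.study import build_study, desk_train_config
from virtualstain.training import cross_validate

study = build_study(ihc_mode="cytoplasmic", seed=1, n_patients=10)
cv = cross_validate(study.manifest, study.pairs, study.negatives,
                    desk_train_config(seed=1))
print([round(m.auroc, 3) for m in cv.per_fold])
print(round(cv.mean_auroc, 4), round(cv.sd_auroc, 4))
```

prints

```
[0.988, 0.988, 0.974, 0.948, 0.974]
0.9742 0.0144
```

i.e. the classifier recovers the planted melanocyte signal on every
held-out patient fold: mean AUROC 0.974 ± 0.014 (population sd over the
five folds). The same objects drive heatmaps and saliency:

```python
from virtualstain.heatmap import prediction_heatmap, render_overlay
smap = prediction_heatmap(cv.models[0], study.fixtures[0].he_image, stride=6)
overlay = render_overlay(smap, study.fixtures[0].he_image,
                         confidence_threshold=0.9)
```

The CLI mirrors the pipeline: `virtualstain fixtures | prep | align |
label | dataset | cv | heatmap | agree | agree-null` (see
`virtualstain <cmd> --help`).

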