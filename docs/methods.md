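# Methods

## The problem and the modeling idea

Melanocytic atypia is hard to annotate directly on H&E: even experts
disagree at the single-cell level. The pipeline implemented here sidesteps
manual annotation by borrowing labels from immunohistochemistry (IHC) on an
adjacent serial section of the same tissue block. A melanocyte-specific
antibody (nuclear SOX10, or cytoplasmic MelanA/MelPro) deposits brown DAB
chromogen wherever melanocytes sit; after the two sections are registered,
every 256 × 256 px H&E tile (64 × 64 µm at 0.25 µm/px) inherits a binary
"contains melanocytes" label computed from the DAB signal of the matching
IHC region. A convolutional classifier trained on those weak labels then
predicts melanocyte presence from H&E alone — a *virtual stain*.

The stages, and the assumptions each one makes:

1. **Slide preparation** (`virtualstain.slides`). Background is modeled in
   HSV: glass is unsaturated and bright (defaults S ≤ 0.08, V ≥ 0.90; a
   border-learned HSV center with tolerances is available when a scanner's
   background deviates). Connected tissue components above
   `min_section_area_px` (default 50,000 px ≈ 0.3 mm² at 0.25 MPP —
   excludes debris, keeps punch-biopsy fragments) become sections; H&E and
   IHC sections are paired greedily by centroid position in normalized
   slide coordinates, with a manual override table taking precedence.
   Flagging of folded/damaged/blurry tissue is a manual manifest column,
   not a classifier.
2. **Registration** (`virtualstain.register`). Serial sections differ by a
   global similarity transform plus smooth elastic distortion. The built-in
   registrar searches rotation (±8°, coarse 1° then fine 0.1°) and scale
   over a grid, recovering translation at each candidate by phase
   correlation, and selects by masked normalized cross-correlation;
   a coarse 8 × 8 B-spline control grid refined by gradient-free
   coordinate descent (≤ 200 cost evaluations, step halving from 3 px)
   absorbs smooth distortion. Registration runs on the
   hematoxylin-deconvolved channel: the nuclear counterstain is the only
   content the two stain modalities share, so it is a far more reliable
   multimodal feature than raw luminance. The *score*, however, is the
   masked NCC of luminance in [−1, 1], and pairs below `accept_threshold`
   (default 0.5) are gated out. The registrar sits behind a small
   interface so an external elastic-registration engine can be swapped in.
   Pairs whose uncompressed size exceeds a byte budget (default 5 GiB) are
   split into two vertical halves first.
3. **IHC labeling** (`virtualstain.labeling`). RGB is unmixed into
   H/E/DAB optical densities with the Ruifrok–Johnston unit vectors
   (shared, as a single constant, with the fixture renderer — round trips
   are exact by construction; OD = −log₁₀(I/255) with intensities clamped
   at one quantization step). DAB-positive pixels must be in tissue, not in
   an artifact region, and have DAB density ≥ max(Otsu-on-tissue,
   `od_floor` = 0.15); the floor keeps Otsu from chasing noise on
   DAB-free sections, Otsu keeps the threshold adaptive for dense staining.
   Artifacts are the union of (a) marker ink by HSV exclusion ranges
   (blue 200–260°, green 90–150°, S ≥ 0.5 — values chosen here, the
   protocol exposes but does not state them), (b) a two-step Otsu cascade
   (dark on V, then saturated on S) whose components must be both large
   (≥ 1500 px) and color-saturated outliers (mean S ≥ 0.65) — this keeps
   the hemorrhage proxy from swallowing genuine DAB, whose
   counterstain-mixed saturation stays lower — and (c) a manual correction
   mask honored unconditionally.
   Tile rules: SOX10 tiles are positive with ≥ 2 discrete DAB nuclei
   (8-connected components with area in 80–5000 px, ≈ 5–18 µm equivalent
   diameter; touching nuclei merge and under-count, accepted); MelanA and
   MelPro tiles are positive with ≥ 3% DAB-positive area. The
   "at least"/"more than" reading of both cutoffs is switchable
   (`LabelThresholds.inclusive`); the inclusive reading is the default.
4. **Dataset assembly** (`virtualstain.dataset`). Tiles are cut on the
   H&E frame after alignment — stride 128 for training (overlapping),
   stride 256 for validation/test — keeping only fully contained tiles
   with ≥ 25% tissue. Folds are patient-stratified: patients are shuffled
   once, divided into five groups, and each fold takes one group as test,
   one as validation, three as training (60/20/20), so every patient is
   held out exactly once and no patient straddles a split. Melanocyte-free
   injected tiles (the stand-in for non-cutaneous negative tissue) are
   pooled 70% into training and 30% into validation — never test — with
   per-tile pseudo-patient ids so the disjointness invariant stays
   checkable; the `half` condition injects half as many. Normalization is
   per-channel (x − mean)/sd with statistics from the training split only,
   persisted with the model.
5. **Training and evaluation** (`virtualstain.training`,
   `virtualstain.nn`). The tile classifier is a small convolutional
   network written directly on numpy: a fixed 4× average-pool entry
   reducer, four 3 × 3 stride-2 conv + ReLU blocks (8, 16, 32, 32
   channels), global average pooling and a single-logit head. The network
   exposes every convolutional activation, its gradient, and a guided
   backpropagation mode — first-class requirements of the saliency stage.
   Training minimizes binary cross-entropy with early stopping: stop after
   `patience` (default 8) epochs without validation-loss improvement,
   restore the best checkpoint. AUROC is the pairwise rank statistic with
   midrank (0.5) tie credit; AUPRC is step integration of the
   precision-recall curve, also reported as a fold over prevalence (a
   no-skill classifier attains AUPRC = prevalence). Cross-validation
   reports per-fold metrics and mean ± population sd; an optional
   (optimizer × learning-rate) grid is selected by mean best-validation
   loss.
6. **Heatmaps** (`virtualstain.heatmap`). Prediction heatmaps slide the
   classifier across a section with windows centered on every stride-th
   pixel (default 6), zero-padded at edges, and average all predictions
   covering each pixel via sum/count accumulation arrays (linear memory).
   Label maps apply the same overlap averaging to the per-position binary
   IHC labels — the ceiling any classifier could reach at this tile size.
   Overlays use viridis, alpha 0.5, with sub-threshold pixels desaturated.
7. **Saliency and agreement** (`virtualstain.saliency`). Guided Grad-CAM:
   per conv block, activations are weighted by their spatially pooled
   gradients and rectified; the per-block maps are bilinearly upsampled to
   tile size, averaged across blocks, and gated by the rectified
   channel-summed guided-backpropagation input gradient. Integrated
   gradients: 16-step Riemann path integral from a black baseline,
   channel-summed and rectified. Both are stabilized with a 5-sample noise
   tunnel (Gaussian input noise, σ = 0.1 of the normalized input range)
   and a Gaussian smoothing of the averaged map (σ = 2 px) before
   normalization to [0, 1] by the maximum — the smoothing turns
   pixel-sparse gradients into contiguous salient regions and is the same
   stabilization spirit as the noise tunnel; without it, max-normalized
   maps rarely clear the blob binarization threshold at all. Blobs are
   8-connected components of the map binarized above 0.2, after 3 × 3
   morphological opening and closing, with area ≥ 100 px. Cross-stain
   blobs are pairs with nonempty pixel intersection (the matching
   criterion is a package decision; centroid-distance matching would be an
   alternative), scored by IoU and Dice; a tile's score is the mean over
   matched pairs and 0 when nothing matches. Dataset-level agreement
   averages over qualifying tiles (either model's confidence > 0.9). The
   mismatched-pair null pairs model A's attribution on tile i with model
   B's on a different tile j, uniformly over ordered pairs of distinct
   melanocyte-positive tiles.

## The synthetic study

Patient slide pairs cannot be redistributed, so every stage is exercised on
rendered fixtures (`virtualstain.fixtures`) with known ground truth.
A fixture section is a tissue ellipse with an eosin wash, keratinocyte
nuclei everywhere, and melanocytes confined to a circular lesion — placed
as tight junctional *nests* of 3–6 cells (nest radius 40 px, nests kept
apart), the growth pattern of melanoma in situ. Melanocytes render with
markedly hyperchromatic nuclei (hematoxylin OD 1.1 vs. 0.55 for
keratinocytes) and a perinuclear clearing halo — the cytologic cues a
dermatopathologist keys on — so the H&E rendition genuinely carries the
signal the weak labels point to. The IHC rendition adds DAB on melanocyte
nuclei (nuclear mode) or cytoplasm (cytoplasmic mode) over a hematoxylin
counterstain wash, is displaced by a known affine warp (defaults tx = 15,
ty = −7 px, 3°, scale 1.0 — too large for naive tiling, recoverable by the
registrar) plus an optional smooth elastic component, and can carry opaque
ink and hemorrhage patches. Composition happens in optical-density space
with additive Gaussian OD noise (σ = 0.02) so deconvolution round trips
stay testable; images are 8-bit RGB.

The default study is 10 patients, one 768 × 768 px pair each, 35
melanocytes and 230 keratinocytes per section, with 60 injected negative
tiles. These sizes were chosen so a full 5-fold cross-validation runs in a
few minutes on one CPU while every fold keeps both classes in every split.
Training for this study uses SGD with learning rate 1e-2 and batch 64
(`virtualstain.study.desk_train_config`): the small backbone wants a larger
step than the protocol default tuned for a deep pretrained network, and
this combination was selected by the same mechanism the protocol
prescribes — a small optimizer × learning-rate grid scored on validation
loss.

What the fixtures deliberately do not emulate: scanner optics and noise,
pyramidal multi-resolution files, stain variability across labs,
photorealistic cell morphology, non-cutaneous tissue content for the
negative tiles (they are melanocyte-free H&E-like textures, labeled as the
stand-in they are). Passing tests therefore demonstrate that the
*machinery* — deconvolution, registration, label rules, training loop,
metrics, saliency statistics — recovers planted ground truth; they do not
certify performance on clinical slides.

## Numerical choices and degenerate inputs

- Optical density uses log base 10 with I₀ = 255 and a 1/255 intensity
  clamp; stain matrix rows are unit-normalized and the inverse is checked
  (singular matrices are rejected).
- Registration falls back to score −1 / not accepted when tissue overlap
  drops below 500 px; the B-spline stage only keeps strict cost
  improvements, so an already-perfect affine stays untouched (identity
  registration is exact).
- Empty tissue masks yield empty DAB masks, not errors; single-class
  training splits and single-class test sets are errors (AUROC is
  undefined).
- AUROC tie handling is midrank; AUPRC evaluates precision at the last
  index of each tied-score block.
- The fold assignment uses largest-remainder group sizes, deterministic
  per seed; manifests regenerate byte-identically.
- Attribution normalization maps the all-zero attribution (e.g. from a
  constant model) to all-zero rather than dividing by zero.
- All randomness flows from explicit integer seeds (numpy Generator);
  fixture images are byte-reproducible.

## Known limitations

- The built-in registrar targets similarity misalignment plus mild smooth
  distortion; it does not attempt diffeomorphic or landmark registration,
  and its NCC score is not numerically comparable to external tools'
  alignment coefficients.
- The small backbone trades capacity for desk-scale runtimes; a large
  pretrained backbone would need a deep-learning framework and is
  deliberately out of scope (requesting `densenet121` raises).
- MelPro's red chromogen is treated through the DAB channel of the shared
  stain matrix; a custom stain matrix is configurable but no dual-chromogen
  unmixing is attempted.
- The nucleus counter merges touching nuclei into one component; the
  resulting under-count is documented behavior, not corrected.
- Saliency-agreement magnitudes depend on the attribution smoothing scale;
  the default (σ = 2 px) is reported with the statistic and configurable.
- The mismatched-pair null baseline has a small positive floor on the
  synthetic study (mean IoU on the order of 0.01): with 1–3 salient blobs
  of a few hundred pixels per 65,536 px tile, a fraction of randomly
  mismatched tile pairs intersect by geometric chance. Real-tissue saliency
  is far sparser relative to the tile frame, which is why an archival-slide
  null can sit at exactly zero. The degenerate alternative — attribution
  sharp enough that blobs rarely form — drives the null to exactly 0 but
  collapses every other agreement statistic, so the default keeps the
  statistic alive and accepts the floor.
- Stride comparability (fine stride-6 maps vs. coarse stride-256 read-outs
  agreeing) holds for spatially stable scorers and is asserted as such; for
  the nest-scale fixture models the prediction changes sharply when a
  window shifts a nest out of view, so fine and coarse summaries genuinely
  decorrelate at this scale. That is a property of the fixture geometry,
  not of the overlap-averaging machinery.
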