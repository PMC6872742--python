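# seg2surv

Survival prediction from segmentation-trained deep image features, for
researchers studying imaging biomarkers in oncology (PET/CT of lung tumors
in particular).

## The idea

Training a convolutional encoder-decoder network (a 3D U-Net) to segment
tumors requires only images and physician contours — no outcome data. Yet
the network's *bottleneck*, the most-compressed layer between encoder and
decoder, must summarize everything about the tumor needed to redraw it:
size, shape, texture, and its peritumoral surroundings. `seg2surv`
implements the full pipeline that turns that observation into a prognostic
model:

1. **Segment.** Train one 3D U-Net per modality (CT, PET) on tumor
   contours; segmentation quality is measured by the Sørensen–Dice
   coefficient DSC = 2|A∩B|/(|A|+|B|).
2. **Harvest.** Run each patient's 96×96×48 ROI (1 mm isotropic, CT clipped
   to [−500, 200] HU, PET to [0.01, 20] SUV) through the trained encoders;
   the bottleneck yields 6×6×3×512 = 55,296 features per modality, 110,592
   for the pair.
3. **Reduce.** Cluster the features by k-medoids under Pearson correlation
   distance d(x,y) = 1 − R(x,y), choosing k by the Silhouette method over
   10 restarts per k; keep the medoid features (survival-blind reduction).
4. **Select & fit.** Squared-loss LASSO, min‖y − Xβ‖² + λ‖β‖₁ with λ from
   inner cross-validation, picks the survival-related medoids (y: 1 =
   alive, 0 = dead); a logistic model y = (1 + e^−(β₀+Σβᵢxᵢ))⁻¹ predicts
   survival at a fixed horizon. Evaluation: 6-fold cross-validation with
   class-balanced test folds, reporting accuracy, sensitivity (on death
   cases), specificity, and AUC with 95% CIs.
5. **Interpret.** Activation maximization synthesizes each selected
   neuron's preferred input pattern; guided backpropagation builds voxel
   risk maps R(X) = Σₘ α⁽ᵐ⁾A⁽ᵐ⁾(X) with α⁽ᵐ⁾ the rectified gradients of the
   predicted death probability w.r.t. the bottleneck activation maps.

No patient data ship with the package. A phantom-cohort generator
(`seg2surv.synthetic`) produces PET/CT-like volumes — lobulated,
texturally heterogeneous tumor blobs with vessel-like tubes — whose
survival labels follow a known logistic model over latent tumor volume and
heterogeneity, so every stage is testable end to end with no downloads.
The network stack (3D convolutions, backprop, Adam) is implemented
directly in numpy and verified against finite differences.

## Worked example

The numbered scripts under `analysis/` run the study end to end at desk
scale (48×48×24 phantoms, 4-level networks) and write small summary tables
to `results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_train_segmentation.py
python 03_extract_features.py
python 04_cluster_features.py
python 05_survival_cv.py
python 06_visualize.py
```

Output of `01_simulate_cohort.py` and `02_train_segmentation.py`:

```
simulated 120 phantoms at (48, 48, 24) voxels (1 mm isotropic)
survival prevalence at 2OS: 0.508
tumor volume range: 2-1790 voxels (median 320)
mean tumor volume: dead 533 vs alive 254 voxels (planted negative volume effect)

CT: held-out DSC 0.869 ± 0.087 over 10 phantoms; bottleneck (6, 6, 3, 32)
PET: held-out DSC 0.704 ± 0.068 over 10 phantoms; bottleneck (6, 6, 3, 32)
```

Larger tumors die more often by construction, and the networks segment
unseen phantoms well above chance, so their bottlenecks encode tumor
geometry. `05_survival_cv.py` then shows the features carry that signal
into prognosis — and that the pipeline is honest about noise:

```
moderate: AUC 0.743 (95% CI 0.651-0.835), accuracy 0.685, k per fold [2, 3, 2, 3, 3, 3], features selected [2, 3, 2, 3, 3, 3]
strong: AUC 0.864 (95% CI 0.807-0.921), accuracy 0.778, k per fold [2, 4, 3, 3, 4, 3], features selected [2, 3, 3, 3, 2, 3]
null: AUC 0.500 (95% CI 0.500-0.500), accuracy 0.500, k per fold [4, 3, 4, 3, 3, 2], features selected [0, 0, 0, 0, 0, 0]
```

The planted moderate effect (−2.0 SD⁻¹ volume, −1.2 SD⁻¹ heterogeneity;
ideal-observer AUC ≈ 0.88) is recovered at AUC 0.74 from a handful of
unsupervised medoid features; tripling the effect raises recovery to 0.86;
permuting the labels collapses it to exact chance, with LASSO selecting
zero features in every fold (the intercept-only fallback). `06_visualize.py`
interprets the strong-effect fit: it synthesizes activation-maximization
templates for each selected bottleneck neuron and reports that
guided-backprop risk maps concentrate inside the tumor:

```
risk maps on PET (modality of the selected features)
  P000: mean risk inside tumor 0.0219 vs outside 0.0086
  P001: mean risk inside tumor 0.0056 vs outside 0.0027
  across 10 phantoms: mean risk inside tumor 0.0087 vs outside 0.0037
```

## Layout

- `src/seg2surv/` — library: `synthetic`, `preprocess`, `nn`/`unet`,
  `features`, `cluster`, `survival`, `interpret`, `io`/`config`/`pipeline`.
- `analysis/` — numbered study drivers (thin wrappers over the library).
- `tests/` — unit, property, and acceptance suites.
- `docs/methods.md` — model, parameter, and design documentation.
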