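# pettex

Robustness of PET textural indices to the choice of tumor segmentation
method and to the observer, exercised end-to-end on a synthetic FDG-PET
phantom cohort.

## The problem

Radiomic texture analysis of FDG-PET tumors promises prognostic biomarkers,
but the indices depend on upstream choices that are not standardized: how
the tumor volume of interest (VOI) is delineated, and who delineates it.
Before a texture index can carry clinical meaning, its variability across
segmentation methods and its reproducibility between observers have to be
quantified. This package implements that robustness study as a tested,
reusable pipeline:

1. **Delineation** by three methods used in head-and-neck PET:
   - a fixed threshold at 40% of the regional SUVmax (voxels ≥ 0.4·SUVmax);
   - an SBR-adaptive threshold `t = a/SBR + b` (SBR = lesion SUVmax over
     the mean SUV of a background shell), with `(a, b)` calibrated on
     noiseless blurred sphere phantoms, iterated to a fixed point;
   - a gradient-edge method placing the boundary at the maximum of the
     radial gradient magnitude along rays cast from the observer's click.
2. **Quantification**: SUVmax, metabolic tumor volume (MTV), and 31
   textural indices from four 3D matrices after absolute resampling to 64
   gray levels over 0–30 SUV — GLCM (distance 1, 13 directions: Homogeneity,
   Energy, Contrast, Correlation, Entropy, Dissimilarity), GLRLM (13
   directions: SRE … RP), NGLDM (26-neighborhood: Coarseness, Contrast,
   Busyness) and GLZLM (3D zones: SZE … ZP). VOIs below 64 voxels (2.12 ml
   at 4.07 × 4.07 × 2 mm voxels) are excluded.
3. **Statistics**: Pearson correlation with greedy complete-linkage
   grouping at |r| > 0.8 and selection of one group representative not
   correlated with SUVmax/MTV; Bland–Altman volume comparison between
   methods; Friedman and Wilcoxon signed-rank tests of inter-method
   variability; inter-observer ICC(2,1) with Landis–Koch labels.

Patient images of this kind are not public, so the package ships a
first-class synthetic cohort generator: ellipsoidal tumors of 0.5–60 ml
with signal-to-background ratio ≈ 23.5 ± 7.4, textured uptake, optional
necrotic cores, partial-volume blur, noise, and two simulated observers
whose only difference is a jitter of the segmentation seed click.

## Worked example

The numbered drivers under `analysis/` run the study stage by stage:

```sh
python analysis/01_simulate_cohort.py   # phantom cohort + manifest
python analysis/02_calibrate_adaptive.py
python analysis/03_run_study.py         # the full robustness study
python analysis/04_jitter_sensitivity.py
```

`analysis/03_run_study.py` prints (seed 1):

```
cohort: 43 patients; complete under all methods/observers: 29
exclusions (VOI below the 64-voxel floor, either observer):
  fixed40    14
  adaptive   14
  gradient   13
correlation groups: 12; independent indices selected: ['Homogeneity',
  'Contrast_glcm', 'Correlation', 'LGRE', 'LRLGE', 'GLNUr', 'Coarseness',
  'Contrast', 'Busyness', 'LZLGE']
MTV Bland-Altman biases (ml):
  gradient - fixed40: +3.09 (LoA -3.88..10.06)
  adaptive - fixed40: +1.56 (LoA -1.62..4.74)
  gradient - adaptive: +1.54 (LoA -2.57..5.65)
SUVmax inter-observer ICC (all methods): 1.000
least reproducible texture index: Contrast_glcm under gradient (ICC 0.925, excellent)
```

Reading: a third of the cohort is too small for texture analysis; the
fixed 40% threshold yields systematically smaller volumes than the
adaptive and gradient methods (positive biases); SUVmax is perfectly
observer-reproducible because every method's VOI contains the hottest
voxel, while texture indices degrade under the gradient method, whose
contour depends on where the observer clicked. CSV tables
(`groups.csv`, `selected.csv`, `variability.csv`, `reproducibility.csv`,
`bland_altman.csv`) and Bland–Altman plots land in `results/study/`.

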