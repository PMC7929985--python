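# Methods

This note documents the models and procedures ccm3d implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Image-processing chain

The nuclei channel (2PEF) is processed in four steps:

1. **Threshold.** Default is Otsu's method computed over the whole stack's
   intensity histogram — parameter-free and reproducible; a fixed numeric
   threshold can be supplied instead and is recorded alongside the result
   either way. A constant-intensity stack has no foreground/background
   separation and is rejected with an error rather than thresholded
   arbitrarily.
2. **Small-area removal.** 2D connected regions with area < 9 px
   (3 px × 3 px) are removed *slice-wise*, before any 3D labelling; the
   removal is strict, so a region of exactly 9 px survives. This reading —
   2D area, per binary image — follows the processing description
   literally; whether the original implementation linked 2D regions across
   slices afterwards or labelled in full 3D is not documented, and full-3D
   labelling is used here.
3. **3D labelling and centroids.** Connected components are labelled with
   26-connectivity by default (6 and 18 are available). The coarse 1 µm
   z-step makes diagonal one-voxel bridges across slices common, which
   26-connectivity tolerates. Centroids are unweighted means of member
   voxel indices scaled by the anisotropic calibration; physical
   coordinate = 0-based index × spacing (voxel centres). Per-depth counts
   assign each nucleus to the slice containing its centroid, treating the
   distribution as a point pattern.
4. **Distances.** Each nucleus's minimum distance to any other nucleus is
   computed in physical µm with a k-d tree; the result is exactly the
   brute-force O(n²) answer (asserted in tests up to 500 points). Ties in
   nearest-neighbour distance need no tie-breaking because only the
   distance value is reported. Depth-binned medians use 10 µm bins by
   default.

Touching nuclei merge into a single component: there is no watershed
splitting, no deconvolution and no depth-attenuation correction. This is a
deliberate scope restriction, shared with the procedure being modelled.

**Thickness.** The collagen channel (SHG) is reduced to a per-slice mean
intensity profile. Background mean and sd are estimated from the three
outermost slices at each end of the stack; a slice contains detectable
collagen when its mean exceeds background mean + k·sd with k = 3. The
longest contiguous run of passing slices defines the slab; thickness is
run length × z-step. k = 3 is the usual "clearly above noise" criterion;
no detectability rule is documented for the original measurement, so this
one is the package's own. A perfectly constant positive profile (signal
everywhere, no background to estimate) is treated as the degenerate
full-extent case. If no slice passes, the function raises instead of
returning a zero thickness.

**CV.** The coefficient of variation is 100·sd/mean, from a sample
(`coefficient_of_variation`, sd with ddof = 1) or from summary statistics
(`cv_percent`). It is scale-invariant and used to compare sample-size
reproducibility across preparation methods.

## Clonogenic survival model

Counts of colonies (≥ 50 cells in the wet-lab counting rule, which is a
laboratory criterion and plays no computational role here) are modelled as

    colonies_i ~ Poisson( cells_i · PE · exp(−(α·D_i + β·D_i²)) )

a Poisson log-linear model with offset log(cells_i), intercept log(PE) and
coefficients −α, −β on D and D². This is the standard maximum-likelihood
formulation for colony-formation assays. Defaults and their rationale:

- **PE as intercept.** PE is estimated within the fit from the dose-0
  dishes by default. An externally measured PE can be fixed instead
  (`pe=`), matching workflows where plating efficiency is assayed
  separately.
- **α, β ≥ 0** enforced by default (`constrain=False` to disable): the
  linear-quadratic interpretation — α for directly lethal lesions, β for
  accumulated sublethal lesions — requires non-negative rates.
- **Optimizer.** L-BFGS-B on the negative log-likelihood with analytic
  gradient, seeded by least squares on −log(per-dose mean SF) against
  (D, D²), then Newton refinement with the analytic Hessian to a parameter
  tolerance of 1e-9 (active bounds respected). Noise-free data generated
  from the model is recovered to machine precision.
- **Uncertainty.** Standard errors and the α–β covariance come from the
  inverse observed information at the optimum. When a constrained
  coefficient sits at 0 the reported SE is the unconstrained curvature
  there and should be read with care.
- **Identifiability guards.** At least three distinct doses are required;
  all-zero doses are rejected.

Colony counts are validated non-negative but may be fractional so that
idealized expected-value tables can be represented and refit exactly.

**Curve comparison.** Two arms are compared by a deviance-based F-test:
the separate model fits (intercept, α, β) per arm; the joint model shares
(α, β) but keeps per-arm intercepts, since plating efficiencies are
arm-specific nuisance parameters. With Dev the Poisson deviance,

    F = [(Dev_joint − Dev_sep)/2] / [Dev_sep/(n − 6)],  p = P(F_{2, n−6} > F).

Identical data in both arms gives F = 0 and p = 1 exactly (deviance
differences below 1e-7 relative are treated as numerical ties). Under null
simulations at the default design (5 doses, 3 dishes, 10⁴ cells, PE 0.37)
the empirical type-I error at nominal 0.05 is ~0.056 over 500 replicates.

**Enhancement metrics.** With a control and a treated fit:

- SER at dose D* (default 2 Gy): `100·(1 − SF_treat(D*)/SF_ctrl(D*))`,
  i.e. the percent reduction of survival caused by the sensitizer.
- DEF at level s (default 0.10): `D_ctrl(s)/D_treat(s)` where D(s) solves
  αD + βD² = −ln s (positive quadratic root; linear solution when β = 0).

Both definitions are interpretations fixed by this package; evaluated at
the rounded published coefficient pairs (0.48, 0.03) vs (0.60, 0.02) they
give 18.1% and 1.122, which differ from the summary values printed
alongside those coefficients (16% and 1.09) — rounded inputs cannot
regenerate summaries computed from unrounded fits, and the package
documents this rather than adjusting either side. Swapping the arms maps
DEF to 1/DEF and SER to its percent-change mirror; both identities are
tested.

**Survival bands.** The uncertainty envelope evaluates SF at the four
corners (α ± se_α, β ± se_β) and takes the pointwise min/max — the
literal "shade by the standard deviations of the coefficients"
construction, chosen over the delta method for reproducibility of the
published-style bands. The band always contains the central curve because
SF is monotone in both coefficients for D ≥ 0.

## Synthetic-data generator

`generate_stack` emulates a paired 2PEF/SHG acquisition:

- **Geometry defaults** mirror the reference instrument: 350 µm square
  field, 0.192 µm lateral pixels, 1 µm z-steps, a 122 µm collagen slab
  with 10 µm margins above and below.
- **Nuclei** are hard spheres of radius 5 µm rasterized on the anisotropic
  grid and Gaussian-blurred (σ = 0.5 µm) — the simplest intensity model
  whose centroid is analytically the sphere centre, which is what makes
  ground-truth centroid accuracy a meaningful test.
- **Placement** is uniform inside the slab with hard-core rejection
  sampling (bounded attempts; an infeasible packing raises an error naming
  the achieved count). The default density, 900 nuclei with a 10 µm hard
  core, yields a median nearest-neighbour distance of ~15 µm, matching
  HeLa-like samples; ~350 nuclei with a 14 µm core reproduce the ~22 µm
  fibroblast-like spacing. At the default density a few percent of nuclei
  nearly touch and merge downstream, as they would in the real pipeline.
- **Signal model:** background 10, sphere amplitude 100, additive Gaussian
  noise sd 5 clipped at zero. No acquisition SNR is documented for the
  system being emulated; these values give a clearly bimodal histogram on
  which Otsu thresholding is reliable, and they are deliberately stated
  here as the regime the pipeline is validated in. The collagen channel is
  a z top-hat over the slab with soft one-slice (partial-volume) edges at
  amplitude 60 over the same background and noise.

Not emulated: optical scattering and depth-dependent attenuation,
non-spherical or variable nuclei, cell growth or movement, detector physics
(Poisson shot noise, PSF anisotropy). Passing tests therefore demonstrate
correctness of the analysis chain under a clean, known-truth imaging model
— not robustness to every artefact of real multiphoton data.

`generate_clonogenic_data` draws Poisson counts per dish with mean
`cells · PE · SF(D)`; defaults (α = 0.48, β = 0.03, PE = 0.37, 10⁴ cells,
3 dishes per dose, doses 0–6 Gy) reproduce the reference 3D experiment's
design scale. Both generators are pure functions of their spec, which
carries the seed; identical specs reproduce outputs bit for bit.

## Problem sizes in tests and the acceptance script

Large-field synthetic checks (100-nucleus recovery, thickness, distance
oracles) run at 0.5 µm lateral sampling rather than the acquisition's
0.192 µm: a full-resolution 350 µm field is ~430 M voxels per channel, and
the coarser grid (≈68 M voxels) changes none of the checked properties —
sub-voxel centroid accuracy, exact distance equality, slice-level
thickness recovery. The generator itself supports full resolution, which
remains the default in `StackSpec`. Simulation studies use 50 replicates
for parameter recovery and 500 for F-test calibration.

## Uptake and oxygen calculators

Gadolinium arithmetic uses M_Gd = 157.25 g/mol (standard atomic weight;
not stated in the source being reproduced) and a default stoichiometry of
10 Gd atoms per particle, derived from the stated 1 mmol/L Gd ↔ 0.1 mmol/L
particle equivalence for the 5 nm gadolinium-chelate particles. Particle
count = (mass/M_Gd)/gd_per_np · N_A; uptake % = 100 · recovered moles /
incubated moles; per-cell load is reported in mol/cell (the published
"pmol/L per cell" unit is dimensionally a per-cell amount labelled as a
concentration and is not reproducible from the rounded printed masses, so
the unambiguous unit is reported instead).

pO₂ conversion is % = 100 · mmHg/reference, with the reference pressure
defaulting to 760 mmHg but configurable: the published 143 mmHg ↔ 19.4%
pairing implies a reference near 737 mmHg, while 112 mmHg ↔ 14.7% matches
760 — the instrument's reference is not stated, so it is a parameter. The
published conversion formula as printed ("/100") reads as a division, but
every numeric pairing beside it implies multiplication by 100, which is
what the package implements.

## Known limitations

- No splitting of touching nuclei; detected counts undercount at high
  density (documented above, quantified by the generator's ground truth).
- The thickness criterion assumes the outermost slices are background; a
  slab flush with the stack ends would bias the background estimate.
- The F-test's denominator degrees of freedom use the separate-model
  parameter count (n − 6 for two arms); small designs near n = 6 are
  rejected rather than tested.
- SER/DEF from fits inherit the fits' coefficient uncertainty; no
  uncertainty propagation onto the metrics themselves is provided.
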