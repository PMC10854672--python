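# Methods

## The ALK Signaling Index

Endothelial cells respond to BMP9/BMP10-class ligands and to fluid shear
stress by phosphorylating SMAD1/5/9, which then translocates from the
cytosol to the nucleus. `asipipe` quantifies this translocation per cell
from two-channel confocal stacks (DAPI + pSMAD1/5/9 immunofluorescence) as
the **ALK Signaling Index**

    ASI = pSMAD_nuc / (pSMAD_nuc + pSMAD_cyt),

where `pSMAD_nuc` and `pSMAD_cyt` are median pixel intensities over the
nuclear ROI and over a thin perinuclear annulus. At dynamic equilibrium the
SMAD pool is homogeneous and the ASI is 0.5; complete nuclear translocation
drives it to 1.0. Because the ASI is a ratio of two medians of the same
channel, it is exactly invariant to any positive rescaling of the pSMAD
intensities (illumination, exposure, gain), which is what makes per-cell
values comparable across fields and runs.

### ROI construction

Both channels are max-projected over z. Nuclei are segmented from the DAPI
projection: global threshold (Otsu by default; the IsoData "Default"
variant is selectable for macro compatibility), hole filling, watershed on
the Euclidean distance transform with h-maxima markers (h = 2 px) to split
touching nuclei, an area filter (50–10 000 px²), and border exclusion.
Border-touching nuclei are dropped by default because their annuli would be
truncated and bias the cytoplasmic median.

The cytoplasmic ROI is deliberately *not* a segmented cell body: it is a
band outside the nuclear boundary (default width 3 px, inner offset 0),
confining the measurement to the thickest part of the cytoplasm and
avoiding regions where endothelial cells overlap. The band is derived from
the exact Euclidean distance transform — a pixel belongs to cell *k*'s
annulus iff its distance to nucleus *k* lies in (offset, offset + width] —
which is identical to the set difference of two Euclidean dilations, and is
tested pixel-for-pixel against a brute-force per-pixel distance oracle.
All nuclear pixels of every cell are excluded from every annulus; annuli of
adjacent cells may overlap each other (medians are robust, and only nuclear
contamination systematically biases the ratio). The band geometry can be
stated in pixels or µm (`AnnulusSpec(unit="um")` plus a pixel size); the
two conventions coincide only at a specific magnification, so the package
supports both with pixels as the default. `annulus_offset_sweep` re-runs
the quantification at several inner offsets to confirm the ASI is not
driven by a bright perinuclear compartment.

A cell whose nuclear and annulus medians are both zero carries no
localization information and is excluded with reason `zero_signal` rather
than being forced to 0.5. Intensities are treated as raw camera units; a
constant-background subtraction flag exists for real data but is off by
default.

### Numerical conventions

Medians of even-sized pixel sets use the midpoint rule. Masks and label
maps use 0-based, pixel-centered coordinates in the projection's frame.
Watershed markers are the maximal plateaus of the grayscale h-reconstruction
of the distance transform (8-connected); marking only maximal *pixels*
would split near-equal discrete ridge maxima of a single convex nucleus
into separate markers and over-segment.

## Dose–response model

Per-cell ASI values are fit against ligand concentration (pg/mL) or
shear-stress magnitude (dyn/cm²) with the four-parameter logistic

    r(d) = bottom + (top − bottom) · d^h / (d^h + EC50^h),

parameterized so that d = 0 evaluates exactly to `bottom` — untreated or
static observations anchor the lower asymptote without log-axis
workarounds. On a shear-stress axis the midpoint is the EF50. Fitting is
trust-region least squares over multi-start initial guesses (bottom/top
from the 5th/95th response quantiles, EC50 from the dose bracketing the
half-maximal per-dose mean, Hill slope in {0.5, 1, 2}); ties in SSE are
broken toward the smallest |hill|. The midpoint can be optimized in
log10(EC50) (default, the GraphPad log-agonist convention) or directly in
linear dose; the two parameterizations describe the same curve and agree to
1e-6 relative on noise-free data. Hill slopes are restricted to (0.05, 10)
— the responses modeled here increase with dose. Flat data is returned
with `converged=False` (midpoint unidentifiable) instead of raising.
Fits use per-cell points pooled across fields; condition-mean fitting is a
caller choice (pass the summarized table).

### EC50 comparison

Whether conditions share an EC50 is tested with the extra sum-of-squares
F test. The alternative model fits each condition's four parameters
freely; the null model shares a single EC50 while bottom/top/hill stay
per-condition (the contrast is on the EC50, which is the question being
asked). With K conditions and N total cells,

    F = ((SSE_null − SSE_alt)/(df_null − df_alt)) / (SSE_alt/df_alt),

with df_alt = N − 4K and df_null = N − (3K + 1), referred to
F(K−1, df_alt). After the null fit, each free fit is re-polished starting
from the null solution and the better SSE kept, so the nested-model
inequality SSE_null ≥ SSE_alt holds by construction rather than by luck of
local optima. Under simulated equal-EC50 nulls (8 doses, 50 cells/dose,
ASI noise sd 0.03) the test's rejection rate at α = 0.05 is calibrated to
0.05 ± 0.02 over 500 replicates in the acceptance suite.

`fold_sensitivity` summarizes how much flow lowers the half-maximal ligand
concentration: the mean of static-condition EC50s over the mean of
flow-condition EC50s, with a one-significant-figure rounding helper for
reporting.

## Morphometrics

* **Junction tortuosity** `(L − P)/P`: L is the polyline arc length of a
  traced bicellular junction, P the straight-line distance between its
  vertices. Zero iff straight; invariant to rigid motions and uniform
  scaling. Paths are accepted as traced polylines; automatic junction
  extraction from phalloidin images is out of scope.
* **Puncta counting**: max z-projection, IsoData global autothreshold,
  binary watershed on the distance transform (ImageJ binary-watershed
  semantics, intensity is not used for the split), connected components,
  exclusion of components below 1 µm², optional normalization per nucleus
  (nucleus counts come from the DAPI segmentation of the same field).
  Because the threshold is derived from the intensity histogram, the count
  is invariant to positive intensity rescaling.
* **Apical/basal actin**: average-intensity projection of the two z-planes
  nearest the requested surface, summarized by the median. Stack
  orientation is never guessed — an explicit `plane_map` is required, and a
  2-plane stack (which must serve both surfaces) is flagged as degenerate.

## Synthetic-microscopy generator

The raw imaging behind the assay is not redistributable, so every
downstream stage is validated against a seeded generator whose ground truth
is known exactly.

* **Fields**: ~100 elliptical nuclei per default field (the assay images
  roughly 80–120 cells per run), radii 8–14 px, eccentricity ≤ 0.6, placed
  by rejection sampling with 36 px minimum center spacing in a 512² field.
  Cytoplasm is a 10 px shell around each nucleus — the pipeline only ever
  samples a 3 px annulus, so full cell bodies are unnecessary; shared shell
  pixels are assigned to the nearest nucleus. Nuclear pixels of cell k get
  `asi_k · total` and its shell `(1 − asi_k) · total` (total = 200 a.u.),
  so the rendered nuclear:cytoplasmic partition reproduces the requested
  ASI exactly. The all-nuclear limit (ASI = 1.0, zero cytoplasmic signal)
  requires an explicit flag and zero noise.
* **Noise**: additive Gaussian, clipped at zero, applied once to the
  rendered 2-D content and scaled through the z-brightness profile (each
  plane is the same image at a plane-dependent brightness, maximal at the
  central plane), so the max projection recovers the noisy 2-D image
  exactly. Real confocal noise is mixed Poisson–Gaussian and independent
  per plane; a max projection of independently noisy planes carries a
  positive bias that the ROI medians inherit. The analysis is median-based
  and therefore robust to the *distributional* simplification, but passing
  recovery tests on this generator does not bound projection-induced bias
  on real multi-plane stacks. The DAPI channel gets a 1 px Gaussian blur
  (segmentation realism); the pSMAD partition is rendered crisp by default
  so the noise-free round trip is exact, with a blur option available.
* **Determinism**: all randomness flows from the scene seed through named
  `SeedSequence` substreams (placement stream, one stream per cell keyed by
  index, separate noise streams), so identical configs give bit-identical
  arrays and cell placement is independent of evaluation order.
* **Dose–response tables**: per-cell responses `4PL(dose) + N(0, sd)` on
  an 8-point dose grid (default truth: bottom 0.5, top 0.75, EC50 17,
  hill 1, sd 0.03, 100 cells/dose — the magnitudes of the static BMP9
  assay). The default shear grid spans 0.05–40 dyn/cm²; the flow-response
  test truth uses EF50 = 2.8 dyn/cm² with hill 2, steep enough that the
  curve is saturated at 19 dyn/cm² as observed in such assays.
* **Junctions**: straight segments (L = P), semicircles (L = πP/2), and
  sine paths whose continuous arc length comes from numeric quadrature;
  polyline length increases monotonically toward it under refinement.
* **Puncta**: disks of 2 µm² and 0.5 µm² at 0.2 µm/px on a dark
  background, non-overlapping except for an optional flagged touching pair
  used to test the watershed split; rasterized areas are checked never to
  cross the 1 µm² exclusion threshold.

What the generator does **not** emulate: optics (PSF, photobleaching,
chromatic shift), realistic cell shapes or confluency, intensity gradients,
per-plane noise, or flow physics. Tests passing on synthetic scenes
validate the *computational* pipeline — segmentation, ROI logic, the ASI
formula, the fitting and testing machinery — not the biology or the imaging
physics of any particular microscope.

## Problem sizes in the test and acceptance suites

Segmentation recovery runs 20 seeded scenes of 10–120 nuclei in 620²
fields; ASI recovery uses 80-cell fields at noise up to 10% of the total
pSMAD signal; F-test calibration uses 500 null replicates at the simulated
assay design (8 doses × 50 cells); EC50 bias uses 200 replicates at 8
doses × 100 cells. These sizes give binomial/Monte-Carlo error comfortably
inside the asserted bands while keeping the default suite fast on one CPU.

## Known limitations

* Pixel size is always an explicit input; no magnification metadata is
  assumed, and the px-vs-µm annulus conventions only coincide at one
  specific pixel size.
* The IsoData threshold implementation is scikit-image's; ImageJ's
  "Default" is a close variant and counts are pinned on synthetic fixtures,
  not guaranteed bit-identical to Fiji on arbitrary real images.
* `run_pipeline` orchestrates simulated end-to-end runs; real stacks are
  quantified through the library/CLI (`quantify`, `fit-dose`, ...) rather
  than the `run` subcommand.
* No 3-D segmentation, no learned models, no 5PL asymmetry, no Bayesian
  dose–response machinery.
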