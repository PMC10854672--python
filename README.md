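# asipipe

Single-cell quantification of BMP/ALK1 pathway activity in endothelial
cells from two-channel confocal stacks, with sigmoidal dose–response
analysis of the resulting per-cell readout against ligand concentration or
fluid shear stress.

Endothelial cells transduce BMP9/BMP10 ligand binding and shear stress into
phosphorylation of SMAD1/5/9, which translocates from cytosol to nucleus.
`asipipe` measures that translocation per cell as the **ALK Signaling
Index**

```
ASI = pSMAD_nuc / (pSMAD_nuc + pSMAD_cyt)
```

where `pSMAD_nuc` and `pSMAD_cyt` are the median pSMAD1/5/9 intensities
over the DAPI-segmented nucleus and over a 3-pixel perinuclear annulus
(the cytoplasmic ROI — no cell-boundary channel required). ASI = 0.5 at
equilibrium; → 1.0 at complete nuclear translocation. Per-cell ASI values
are fit against dose *d* with the four-parameter logistic

```
r(d) = bottom + (top − bottom) · d^h / (d^h + EC50^h)
```

(EF50 when *d* is shear stress in dyn/cm²), and EC50s are compared across
conditions with the extra sum-of-squares F test (shared vs per-condition
EC50). A seeded synthetic-microscopy generator with exact ground truth
(nucleus masks, per-cell true ASI, puncta inventories, junction polylines)
makes the whole pipeline testable without raw imaging data. Morphometric
validation tools — junction tortuosity `(L−P)/P`, CtxB puncta counting
with a 1 µm² size exclusion, apical/basal F-actin intensity — are
included.

Intended users: imaging/vascular-biology groups quantifying
nuclear-translocation readouts at single-cell resolution, and anyone
needing a tested reference implementation of annulus-based N/C ratio
quantification plus nested-model EC50 comparison.

## Worked example

```python
import numpy as np
from asipipe import *

# a seeded ~100-cell field with ground-truth ASI 0.75 and additive noise
cfg = SceneConfig(pixel_size=0.3, n_cells=100, seed=7, true_asi=0.75,
                  noise_sd=10.0)
scene = simulate_scene(cfg)
result = quantify_field(scene.dapi_stack, scene.psmad_stack)
print(f"cells retained: {len(result.retained)}")
print(f"mean ASI: {result.asis.mean():.4f}  (ground truth 0.75)")

# dose-response: a 28-fold EC50 shift between static and flow conditions
static = generate_dose_response(DoseResponseTruth(
    bottom=0.5, top=0.75, ec50=17.0, hill=1.0, noise_sd=0.03,
    n_cells_per_dose=100, seed=1, condition="static"))
flow = generate_dose_response(DoseResponseTruth(
    bottom=0.5, top=0.75, ec50=0.6, hill=1.0, noise_sd=0.03,
    n_cells_per_dose=100, seed=2, condition="flow"))
fs_fit, fl_fit = fit_4pl(static), fit_4pl(flow)
print(f"static EC50: {fs_fit.ec50:.2f} pg/mL   flow EC50: {fl_fit.ec50:.3f} pg/mL")
cmp = compare_ec50_f_test([static, flow])
print(f"extra-SS F test: F({cmp.df_num}, {cmp.df_den}) = {cmp.f_stat:.1f}, "
      f"p = {cmp.p_value:.3g}")
fs = fold_sensitivity([fs_fit.ec50], [fl_fit.ec50])
print(f"flow-induced sensitivity increase: {fs.fold:.1f}-fold "
      f"(~{fs.fold_rounded:.0f}-fold)")
```

prints

```
cells retained: 100
mean ASI: 0.7499  (ground truth 0.75)
static EC50: 17.25 pg/mL   flow EC50: 0.601 pg/mL
extra-SS F test: F(1, 1592) = 610.7, p = 2.17e-114
flow-induced sensitivity increase: 28.7-fold (~30-fold)
```

The quantification recovers the generator's ground-truth ASI to well under
0.01 despite 5% additive noise; the 4PL fits recover both EC50s within a
few percent; the F test rejects the shared-EC50 null decisively; and the
fold-sensitivity summary (mean static EC50 / mean flow EC50) reports the
simulated ~28-fold shift.

A CLI mirrors the library (`asipipe simulate|quantify|fit-dose|fit-flow|
compare-ec50|tortuosity|puncta|run`); `asipipe run --config cfg.json`
executes an end-to-end simulated experiment and writes per-cell CSVs, fit
JSONs and a checksummed run manifest. Exit codes: 0 success, 2 validation
error, 3 stage failure.

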