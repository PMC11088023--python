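# dynpet

Dynamic FDG-PET quantification for lung-lesion characterisation:
irreversible two-tissue compartment kinetic modelling, image-derived input
functions, SUV lesion segmentation, and the diagnostic statistics layer
(group tests and ROC cut-offs) — plus synthetic phantom and cohort
generators so the whole chain is testable at desk scale.

## The problem

Static FDG-PET summarises a lesion by its SUVmax, which is confounded by
scan timing, blood glucose and inflammation: granulomas and tuberculosis
can be as FDG-avid as carcinoma. A dynamic acquisition (here a 65-min chest
scan partitioned into 28 frames: 6×10 s, 4×30 s, 4×60 s, 4×120 s, 10×300 s)
lets one fit a compartment model and recover absolute kinetic rates that
separate perfusion/delivery from irreversible trapping — and trapping, not
delivery, is what distinguishes malignancy.

## The model

FDG in tissue is described by a free compartment C1 and a trapped
(phosphorylated) compartment C2 with no dephosphorylation (k4 = 0):

    dC1/dt = K1·Cp(t) − (k2 + k3)·C1
    dC2/dt = k3·C1
    CT(t)  = (1 − vB)(C1 + C2) + vB·Cp(t)

with K1 [ml/g/min] delivery, k2 [1/min] efflux, k3 [1/min] phosphorylation,
and Cp(t) the arterial blood curve, measured image-side from a 10-mm
ascending-aorta ROI on six consecutive slices of the 0–60 s composite.
The macro-parameter

    Ki = K1·k3 / (k2 + k3)   [ml/g/min]

is the net influx (trapping) rate. Estimation double-integrates the ODEs
into a linear form, CT = θ1∫Cp + θ2∫∫Cp − θ3∫CT with θ ≥ 0, solved by
Lawson–Hanson non-negative least squares per voxel — fast enough for
parametric imaging. A conventional nonlinear fit and a Patlak graphical fit
are kept as independent cross-checks. Lesions are segmented as the
26-connected region above 40% of SUVmax; VOI summaries of the K1/k2/k3/Ki
maps feed a statistics layer (Shapiro-gated Wilcoxon/Welch comparisons,
Youden-optimal ROC cut-offs with bootstrap CIs).

## Worked example

```python
import numpy as np
from dynpet import (PhantomSpec, make_phantom, extract_idif, fit_voxelwise,
                    combine_frames, segment_lesion, extract_lesion_record,
                    suv_volume)

img, truth = make_phantom(PhantomSpec(noise_level="moderate"), seed=1)
idif = extract_idif(img)                      # aorta ROI, auto-placed
maps = fit_voxelwise(img, idif, np.ones(img.shape3d, bool))
late = combine_frames(img, (2100.0, 3900.0))  # last 30 min composite
suv  = suv_volume(late, img.meta["injected_dose_MBq"], img.meta["body_weight_kg"])
voi  = segment_lesion(suv, seed=(21, 21, 8), fraction=0.40)
rec  = extract_lesion_record(maps, suv, voi)
print(f"Ki {rec.ki:.5f} ml/g/min (truth {truth['lesion']['ki']:.5f}), "
      f"SUVmax {rec.suv_max:.2f}, VOI {voi.n_voxels} voxels")
```

prints

```
Ki 0.02327 ml/g/min (truth 0.02323), SUVmax 3.47, VOI 81 voxels
```

i.e. the pipeline recovers the phantom lesion's true net influx rate
(0.0232 ml/g/min, a typical malignant value) within a fraction of a percent
at moderate noise, inside an 81-voxel VOI found by the 40% threshold.

The same flow is available from the shell:

```
dynpet simulate-phantom --out-prefix ph --noise moderate --seed 1
dynpet quantify --config run.toml
dynpet simulate-cohort --design malignancy --out cohort.csv --seed 1
dynpet cohort-stats --cohort cohort.csv --grouping malignancy
```

`cohort-stats` on the calibrated benign/malignant cohort reproduces the
expected clinical pattern: SUVmax, k2, k3 and Ki separate the groups
(Ki AUC ≈ 0.88 in the seeded example) while K1 does not (p ≈ 0.6).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it generates a
moderate-noise phantom, extracts the IDIF, fits voxel-wise parametric maps,
segments the lesion at 40% of SUVmax, extracts the lesion record, then
simulates the calibrated cohort and prints its comparison/ROC report,
writing the results JSON to `--out`.
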