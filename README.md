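# alignedstrain

Temporally aligned myocardial strain from short-axis cine CMR, with
fibrosis classification from segmental strain features.

Frame-by-frame strain curves from cine CMR are not comparable between
patients: cycle lengths and sub-phase durations differ, so clinical
practice falls back to a single peak or end-systolic value and discards
diastolic deformation. This package aligns strain at five automatically
detected cardiac key frames — ED (end-diastole), MS (mid-systole), ES
(end-systole), PF (peak filling), MD (mid-diastole) — and computes
Green-Lagrange radial/circumferential strain (`Err`, `Ecc`) on the
16-segment AHA model in two schemes:

* **ED2K** (composed): each key frame relative to end-diastole,
  `E = 1/2 (F^T F - I)` with `F = I + grad u`;
* **K2K** (sequential): each key frame relative to its cyclic
  predecessor, isolating sub-phase deformation such as early-diastolic
  relaxation.

That yields a 320-entry feature vector per patient
(Ecc/Err x ED2K/K2K x 5 sub-phases x 16 segments) used for segment-wise
group statistics (Welch's t-test with Holm-Bonferroni correction) and a
grid-searched LGE+/- classifier. The pipeline stages are: key-frame
detection from a blood-pool contraction-relaxation curve -> deformable
registration of the key-frame volumes (SSIM + Dice + smoothness
objective, spatial-transformer warping) -> strain projection and AHA
aggregation -> feature selection and classification.

Everything is verified on a synthetic contracting-annulus phantom whose
motion, key frames and segmental strain have closed forms, including
configurable per-segment hypokinesis standing in for fibrotic (LGE+)
myocardium. It is intended for methods work on strain pipelines —
researchers who need a controlled testbed with exact ground truth rather
than a clinically validated tool.

## Worked example

Render a phantom with hypokinetic (synthetic LGE+) segments 5 and 11 at
attenuation h = 0.5, and extract aligned segmental strain from its
ground-truth displacement fields:

```python
import alignedstrain as a
from alignedstrain.registration import DisplacementFieldSet

spec = a.PhantomSpec(hypokinetic_segments={5: 0.5, 11: 0.5}, seed=0)
ph = a.render_phantom(spec)
print("key frames:", ph.keyframes.as_dict())

fields = DisplacementFieldSet.from_analytic(spec, ph.keyframes)
table = a.segmental_strain(fields, ph.masks, ph.keyframes, spec.spacing)
es = table.query("scheme == 'ED2K' and phase == 'ED-ES'").set_index("aha_segment")
print(es.loc[[2, 5, 11], ["Err", "Ecc"]].round(3))
```

```
key frames: {'ED': 29, 'MS': 5, 'ES': 11, 'PF': 17, 'MD': 23}
               Err    Ecc
aha_segment
2           -0.138 -0.138
5           -0.073 -0.060
11          -0.069 -0.066
```

The healthy segment 2 shows the full end-systolic strain of the phantom's
15% contraction, `(0.85^2 - 1)/2 ~ -0.139`; the hypokinetic segments show
roughly half the deformation — exactly the signature the downstream
Welch-Holm screening and classifier pick up.

Fitting the deformable registration instead of using the analytic bypass
(about 20 s on one CPU for the default 30 x 8 x 64 x 64 stack):

```python
spec = a.PhantomSpec(seed=0)
ph = a.render_phantom(spec)
res = a.fit_registration(ph.cine, ph.masks, ph.keyframes)
print(res.dice_table().query("pair == 'ED-ES'").round(3).to_string(index=False))

truth = DisplacementFieldSet.from_analytic(spec, ph.keyframes)
print("median endpoint error vs ground truth: %.2f voxels"
      % res.endpoint_error(truth)["median"])
```

```
scheme  pair  dice_identity  dice_warped
  ED2K ED-ES          0.653        0.999
median endpoint error vs ground truth: 0.19 voxels
```

Registration lifts the warped-myocardium Dice from 0.65 (identity) to
~1.0 and tracks the analytic displacement to a fifth of a voxel.

The same workflow is available from the shell:

```sh
alignedstrain phantom generate --config spec.yaml --out phantom/ --seed 0
alignedstrain keyframes detect --masks phantom/masks.nii.gz --out kf.json
alignedstrain pipeline --cine phantom/cine.nii.gz --masks phantom/masks.nii.gz --out run/
```

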