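# lvgpm — murine LV function from sparse cine-CMR slices

`lvgpm` quantifies global left-ventricular (LV) function in mouse
cine-CMR studies — end-diastolic and end-systolic volume (EDV, ESV),
stroke volume (SV = EDV − ESV), ejection fraction (EF = SV/EDV) and LV
mass (LVM) — from **sparse** imaging slices, using 3D guide-point
modelling (GPM): a smooth parametric surface model of the ventricle is
fitted to contour data from any subset of short-axis (SAX) and long-axis
(LAX) slices and interpolates coherently between them. Because the model
supplies the missing geometry, a six-slice (4 SAX + 2 LAX) or even a
four-slice (2 SAX + 2 LAX) acquisition can replace the standard ~10-slice
contiguous stack, cutting scan time — and anesthesia burden — by ~40%.

The package is aimed at small-animal CMR groups who want to test, on
ground-truth phantoms, when reduced-slice protocols are safe: they are
accurate for symmetric ventricles, while the four-slice protocol
overestimates mass once a large akinetic infarct makes the ventricle
regionally heterogeneous.

## The model

Each ventricular surface (endocardial and epicardial) is a radial field
in an axially stretched frame aligned with the LV long axis:

    S(μ, θ) = c + λ(μ, θ) · [ sin(πμ)(cos θ u₁ + sin θ u₂) + κ cos(πμ) a ]

with μ ∈ [0, 1] running apex → base, θ circumferential, κ the axial
elongation, and λ(μ, θ) a tensor-product spline (clamped cubic in μ ×
periodic cubic in θ). Fitting minimizes the penalized least squares

    Σᵢ wᵢ (λ(μᵢ, θᵢ) − rᵢ)² + α₁ ∫|∇λ|² + α₂ ∫|Hλ|²

over the spline coefficients, which is linear; (μᵢ, θᵢ, rᵢ) are guide
points radially projected onto the parameter domain. Cavity and wall
volumes are computed by divergence-theorem quadrature of the fitted
surface up to the mitral-valve plane (the total-least-squares plane
through the four mitral landmarks); LVM = 1.05 mg/µl × (epi − endo)
volume. The reference "standard" method is per-slice voxel-count area
summation over the contiguous SAX stack with per-slice ED/ES frame
selection. Bland-Altman agreement (bias ± 2 SD) and one-way
repeated-measures ANOVA with Bonferroni post-hoc tests compare methods.

A beating-phantom generator supplies ground truth: truncated-ellipsoid
mouse ventricles (control preset: EDV ≈ 64 µl, LVM ≈ 105 mg, EF ≈ 63%;
chronic-infarct preset: EDV ≈ 162 µl, LVM ≈ 113 mg, EF ≈ 20%, akinetic
area 35–48% with regional aneurysm and wall thinning), acquired as 7–9
contiguous 1 mm SAX slices plus two LAX views at 50 µm pixels.

## Worked example

```python
from lvgpm import (control_spec, make_phantom, acquire_study,
                   slice_summation, analyze_gpm)

truth = make_phantom(control_spec(seed=0, noise_sd_mm=0.0, jitter=False))
study = acquire_study(truth)          # 7 SAX + 2 LAX, 20 frames

std = slice_summation(study)
gpm4 = analyze_gpm(study, "four")     # 2 SAX + 2 LAX only
print(f"truth EDV {truth.true_edv:.1f} ul, EF {100*truth.true_ef:.1f}%, "
      f"mass {truth.true_mass:.1f} mg")
print(f"std   EDV {std.edv_ul:.1f} ul, EF {std.ef_pct:.1f}%, "
      f"mass {std.lvm_mg:.1f} mg")
print(f"gpm4  EDV {gpm4.edv_ul:.1f} ul, EF {gpm4.ef_pct:.1f}%, "
      f"mass {gpm4.lvm_mg:.1f} mg")
```

prints

```
truth EDV 64.0 ul, EF 62.9%, mass 105.3 mg
std   EDV 64.2 ul, EF 63.2%, mass 102.0 mg
gpm4  EDV 63.8 ul, EF 63.0%, mass 108.5 mg
```

i.e. on a symmetric ventricle the four-slice model-based analysis matches
the 7-slice standard summation within a few percent of the analytic
truth. The same pipeline is scriptable from the shell:

```bash
lvgpm simulate --preset infarct --seed 1 --out study.json
lvgpm reduce --study study.json --protocol six --out six.json
lvgpm analyze-gpm --study six.json --out report.json
lvgpm run --preset control --seed 7 --out bundle/   # all four methods
```

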