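# Methods

## Surface model

Both ventricular surfaces are star-shaped radial fields about a shared
long-axis frame. A surface point is

S(μ, θ) = c + λ(μ, θ) · d(μ, θ),
d = sin(πμ)(cos θ u₁ + sin θ u₂) + κ cos(πμ) a,

where `c` is the frame center, `a` the unit long-axis direction (toward
the apex), `(u₁, u₂)` a transverse orthonormal pair, and κ > 0 a
dimensionless axial elongation. μ = 0 is the apex pole, μ = 1 a basal
pole beyond the valve plane (everything basal of the mitral plane is
truncated before volumes are reported, so the basal pole is a
parameterization convenience, not anatomy). With this stretched radial
map a *constant* field λ ≡ a₀ is an exact prolate spheroid with
semi-axes (a₀, a₀, κa₀); spheres (κ = 1) and the truncated-ellipsoid
closed forms used as oracles are therefore represented exactly, which a
true focal prolate-spheroidal coordinate cannot do for the sphere limit.

λ(μ, θ) is a tensor product of clamped cubic B-splines in μ and uniform
periodic cubic B-splines in θ. The two coefficient rows at μ = 0 and
μ = 1 are tied to single values, which closes the surface at the poles
(the tied row times the partition-of-unity θ basis is a constant).
Because both bases are non-negative partitions of unity, coefficient-wise
bounds transfer to the field: positivity and epicardial ≥ endocardial are
enforced (and, after fitting, repaired if violated) on coefficients.

**Basis size.** Default 6 × 12 control values per surface. Smaller grids
(4 × 8) cannot represent a chronically infarcted ventricle with an
aneurysmal bulge even from full-slice data — the protocol comparison then
measures representation error rather than slice sparsity, which is the
quantity of interest. 6 × 12 keeps full-slice recovery error below 2% on
both phantom presets while leaving the reduced protocols genuinely
under-determined between slices.

## Fitting

Guide points are all contour points of the included slices mapped to 3D;
LAX contours are clipped at the per-frame mitral-valve plane. Points are
projected radially in the stretched frame: (μᵢ, θᵢ) from the point's
polar/azimuthal angles, rᵢ its stretched radius. The coefficients then
solve the linear penalized least-squares problem

min Σ wᵢ (λ(μᵢ, θᵢ) − rᵢ)² + α₁ S₁(λ) + α₂ S₂(λ),

S₁ and S₂ being Gauss-Legendre × trapezoid quadratures of the integrated
squared first and second parametric derivatives. The outer
project/re-solve loop is kept for interface parity with nearest-point
projection schemes; under radial projection with a fixed frame geometry
it converges on the second pass and the objective is non-increasing by
construction.

**Smoothing weights.** α₁ = α₂ = 0.005 (data weights 1 per contour
point, ~10³ points per frame and surface). The weights sit near the
noise floor of the contour data (σ ≈ 0.025 mm, half the reconstructed
pixel): large enough to determine the field where slices are missing,
small enough not to flatten real regional remodelling — at α = 0.5 the
penalty competes with the aneurysm's curvature and biases even
full-slice volumes by ~10%.

**Frame geometry.** Estimated once per study at end-diastole and shared
by all frames (keeping the fit linear and ED/ES coherent): axis from the
mitral centroid to the apex (most apical LAX endocardial point; most
apical SAX centroid extended half a slice if no LAX data); transverse
seed from the first mitral landmark, so rigid motions of the study rotate
the frame with it and fits are rotation-equivariant; center and mean
radius from the quadratic relation r²(z) = α + βz + γz² satisfied exactly
by ellipsoids, using per-slice mean radii plus the basal ring radius.

**Basal pole anchor.** The region beyond the mitral ring carries no
data; the curvature penalty extrapolates the declining radius inward and
the fitted pole can fall short of the valve plane, making the truncated
volume ill-defined. When the unanchored pole reaches less than 0.3 mm
past the most basal datum, the fit is repeated with one pseudo-
observation (weight 25) holding the pole 1.2 mm beyond it. The anchor
only shapes the truncated-away region; it is skipped whenever the data
already determine a sufficient pole, so in-span data are recovered
exactly.

## Volumes, mass, derived indices

Enclosed volume up to the mitral plane uses the divergence theorem with
the reference point placed *on* the plane, so the planar cap contributes
nothing and only the curved surface is integrated (composite
Gauss-Legendre in μ per meridian — the crossing μ_c(θ) found by
vectorized bisection — trapezoid in the periodic θ). On truncated
ellipsoids the result matches the closed form to better than 1e-6 at
quadrature order 8; an independent voxel-counting oracle (20 µm voxels)
agrees to 0.2%. Volumes are µl (= mm³), lengths mm, and
LVM = 1.05 mg/µl × wall volume. The model-based report takes EDV/ESV as
the global max/min of the per-frame cavity volume and averages wall
volume over all frames (an ED/ES-average option exists); the standard
method selects ED/ES per slice and averages ED and ES wall volumes. SV
and EF derive from EDV/ESV; EF is stored as a fraction and printed as %.

Surface/plane intersections use one-root-per-meridian bisection when the
plane separates the poles, paired meridians for long-axis planes through
the axis, and a marching-squares level-set trace (with per-vertex edge
bisection polish) for non-monotone cuts such as a slice clipping only an
aneurysmal bulge lobe.

## Phantom generator

The phantom emulates a mouse cine-CMR study at contour level — it
supplies geometry and motion with analytic truth, not MR images (no
k-space, intensity, or gating artefacts; noise enters only as isotropic
in-plane Gaussian perturbation of contour points, default σ = 0.025 mm).

Geometry: truncated ellipsoid, basal plane at 0.55·c above center. The
control preset (endo semi-axes 1.952/1.952/4.605 mm, wall 0.958 mm,
short-axis contraction fraction 0.358) was solved from the
truncated-ellipsoid closed form and quadrature to the healthy C57Bl/6
group means (EDV 64 µl, LVM 105 mg, EF 63%); the chronic-infarct preset
(2.304/2.304/4.338 mm, wall 0.903 mm, contraction 0.264, aneurysmal
bulge 1.5 mm with 50% wall thinning inside a raised-cosine window
centered at θ = π/4, μ = 0.29) to the infarcted means (EDV 162 µl,
LVM 113 mg, EF 20%). The scar window is calibrated per phantom so the
measured akinetic mid-wall area hits a target fraction (35–48%); a
validator keeps the window apical of the valve plane so the aneurysm
never crosses it. The scar center sits between the two LAX view planes —
aligning pathology exactly with an imaging plane is a measure-zero
coincidence that would flatter reduced-slice protocols. Presets add
per-seed biological scatter (≈5% SD on linear dimensions) matching the
reported cohort SDs; `jitter=False` gives the group-mean animal.

Motion: raised-cosine time course over 20 frames (frame 0 = ED, minimal
cavity at mid-cycle = ES); endocardial short semi-axes shrink by the
contraction fraction with 0.4× accompanying long-axis shortening; inside
an akinetic scar the endocardium is frozen at ED. The epicardium follows
by ray-wise wall-volume conservation in the stretched frame,
λ_epi = (λ_endo³ + λ_epi,ED³ − λ_endo,ED³)^{1/3}, which conserves the
closed-shell wall volume exactly. The wall volume *below the fixed valve
plane* still varies ~6% over the cycle because wall material crosses the
plane — as in real slice-based analyses, and the reason mass is reported
as the ED/ES average. Truth volumes come from the quadrature; a 20 µm
voxelization cross-checks them to <0.5%.

Acquisition: SAX planes perpendicular to the axis, first plane half a
slice below the basal plane, continuing while the ED endocardium is cut
(7–9 slices at 1 mm for the presets); two orthogonal LAX planes through
the axis; mitral landmarks are the basal-ring intersections with the LAX
planes. Everything is reproducible from one seed.

What passing phantom tests do **not** show: robustness to segmentation
bias, papillary muscles/trabeculation (the cavity convention includes
them; phantoms contain none), through-plane motion artefacts, arrhythmic
gating errors, or operator variability in guide-point placement.

## Standard analysis details

Areas are pixel-center counts inside the contour polygon times the pixel
area, on a lattice anchored at the lab origin (areas are additive across
sub-stacks). Noise-level micro self-intersections of generated contours
are repaired (`buffer(0)`) when the repair changes the area by less than
max(0.5%, 0.01 mm²); larger topology violations raise an error naming
slice and frame. A slice contributes fully whenever its contour is
non-empty — no partial-volume correction, mirroring voxel-count manual
analysis; this drives the known small end-slice bias of the method
(≲4% of EDV at 1 mm slices). Infarct size is the mid-wall area fraction
whose endocardial ED→ES excursion is below τ = 0.1 mm (64 × 64 parameter
grid by default), expressed in % of the below-base mid-wall area.

## Statistics

Bland-Altman limits are bias ± 2·SD literally (the convention of the
agreement plots being reproduced), not 1.96·SD. The repeated-measures
ANOVA uses explicit within-subject sums of squares; for two methods
F = t²_paired to machine precision. Sphericity is assumed by default
(no correction is mentioned by the protocol being reproduced); a
Greenhouse-Geisser option exists. Post-hoc comparisons are paired t
tests with Bonferroni multiplication — whether the original post-hocs
were contrasts within the ANOVA or separate paired tests is not
documented; the separate-test reading was chosen as the more common
practice. Monte-Carlo calibration (5 subjects × 4 methods, 2000 null
replicates) keeps the type-I error within [0.035, 0.065] at α = 0.05.

## Problem sizes and numerical choices

Default problem sizes: 20 frames, 80 contour points per SAX contour (160
per LAX), truth surfaces on a 32 × 48 spline grid, fits on 6 × 12,
quadrature order 8 with 256 meridians, rasterization at 50 µm,
voxel oracles at 20–50 µm. Ties in ED/ES frame selection break to the
earliest frame; degenerate mitral input collapses coincident landmarks
and fits the plane if ≥3 distinct points remain; tangent or missing
plane/surface intersections return an empty contour flagged degenerate
rather than raising.

## Known limitations

- Surfaces must be star-shaped about the frame axis; extreme aneurysms
  that fold past the radial map are out of reach of the parameterization.
- The frame geometry (axis, center, elongation) is fixed per study;
  severe mis-estimation on pathological anatomy is compensated only
  through the spline field.
- One global θ/μ smoothing weight pair; no spatially adaptive
  regularization at scar borders.
- Temporal coherence comes only from shared geometry and warm-starting;
  there is no explicit temporal penalty.
- The four-slice mass overestimation on infarcted phantoms is reproduced
  at sign/ordering level; its magnitude depends on how much regional
  remodelling hides between the acquired planes and is smaller here than
  with interactive sparse guide points, because automated dense contours
  carry more information per slice.
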