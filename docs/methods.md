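# Methods

This note documents the models, algorithms, defaults and design choices in
`kidneymorph`, and what the synthetic cohorts do and do not establish about
real data.

## Geometry

**Mesh extraction.** Binary masks are zero-padded by one voxel and iso-surfaced
with marching cubes at level 0.5; vertex coordinates map to world millimetres
through the NIfTI affine (0-based voxel indices). If the iso-surface has
several connected components the largest is kept with a warning — tiny
fragments are below the QC volume floor anyway. Winding is normalised so the
signed volume is positive (outward normals).

**Smoothing.** The Laplacian filter is the uniform-weight umbrella operator:
each pass moves every vertex toward its one-ring centroid by the relaxation
factor. Defaults are 10 passes at relaxation 0.5; both are config-exposed
because the upstream description names only "a Laplacian filter". Uniform
weights are the simplest faithful reading; surface area is non-increasing per
pass on the shapes used here (asserted numerically, not proved).

**Per-vertex geometry.** Vertex area is one third of incident triangle areas
(so vertex areas sum exactly to surface area — TFCE extent relies on this);
normals are area-weighted face-normal averages, unit length, globally
outward. The vertex adjacency graph doubles as the TFCE connectivity and the
noise/smoothing operator.

## Correspondence

Rigid alignment is Kabsch least-squares rotation + translation (never scale:
size is signal, not nuisance). With matched topologies it is one-shot
Procrustes on vertex pairs; otherwise closest-point iteration with a
linearised point-to-plane metric (50 iterations max, 1e-6 mm tolerance).
Affine alignment is the least-squares 3×4 map, exact when the target is an
affine image of the source.

The non-rigid template-to-subject step is a **smoothness-regularised
closest-point deformation**: template vertices are iteratively pulled toward
their closest points on the subject surface, with the displacement field
diffused over the template one-ring graph each iteration (stiffness annealed
from 10 smoothing passes to 1), then projected exactly onto the subject
surface. A final refinement intersects the line through each template vertex
along its outward normal with the subject surface and keeps the hit nearest
the iterated estimate: for any deformation applied along template normals —
the synthetic generator's model — the correspondence is exact to machine
precision, which is what makes the analytic S2S oracle possible. No claim of
numerical equivalence with B-spline free-form image registration is made; the
contract (dense, smooth, surface-accurate map preserving topology) is the
same, and a residual above 0.5 mm flags the subject.

Closest-point queries use a KD-tree over triangle centroids with exact
point–triangle projection on the k = 8 nearest candidates.

Template construction is the iterative mean: rigidly align all meshes to the
current reference, average vertex positions, repeat (3 iterations or until
the mean shift < 1e-3 mm). The reference (first mesh by default) fixes the
topology.

## Signed S2S distance

Magnitude is the Euclidean distance between corresponding vertices; the sign
is the sign of the offset's projection on the template outward normal
(positive = outward). Sign via normal projection rather than point-in-mesh
parity is cheap and stable for near-parallel correspondences; parity checking
would only matter for correspondence angles above ~60°, which the propagation
residual check already flags.

## Vertex-wise inference

**Model.** Ordinary least squares per vertex, `t = β̂ / SE` with `n_s − p`
degrees of freedom. Continuous covariates (and, in study-style analyses, the
S2S columns themselves) are standardised to population-SD units; binary flags
stay 0/1, so their coefficients are shifts in S2S SDs. Interaction columns
are products of the already-standardised parents. Rank-deficient designs are
rejected naming the collinear columns. Perfect-fit vertices (zero residual)
would give infinite t; they are capped at ±1e3 with a warning so TFCE stays
finite on degenerate synthetic inputs.

**TFCE.** `TFCE(v) = Σ_{h = dh, 2dh, …, ≤ t_v} e_v(h)^E · h^H · dh`, where
`e_v(h)` is the surface area (mm², summed vertex areas) of the
supra-threshold connected component containing `v`. Defaults E = 1, H = 2,
`dh = max|t|/100` per map — standard practice for surface data with
area-based extent; all config-exposed. Positive and negative excursions are
enhanced separately and recombined with sign, because the summary tables
report signed significance areas. The implementation is a descending-
threshold union-find sweep (numba-compiled, exact, not approximate); tests
pin it against an independent brute-force loop over thresholds and
graph-library connected components.

**Permutation.** Freedman–Lane: fit the reduced model without the target
column, permute its residual rows, add back the reduced fit, refit the full
model, TFCE-enhance the permuted t-map. Vertex-wise add-one p-values
`p(v) = (1 + #{|TFCE_perm| ≥ |TFCE_obs|}) / (1 + n_perm)` (minimum attainable
`1/(1+n_perm)`), then BH-FDR across vertices per covariate. Plain label
permutation is available as a config alternative. The study-scale default is
1,000 permutations; tests and the acceptance script use 200–500.

**Summaries.** Median (IQR) of β̂ split by coefficient sign plus significance
areas as % of vertices. Whether the published tables take medians over
significant vertices only or over all vertices is ambiguous in the source
material; both variants are computed (`scope="significant"` /
`scope="all"`), with `significant` the default. A sign side with no
significant vertex yields NaN medians — the table's blank cell. The mm
rescaling is simply `β̂_std × median per-vertex S2S SD`; with the published
inputs this reproduces −1.0, −0.89, 0.60, 0.59 and 0.18 mm. The published
right-kidney hypertension value (0.15 mm) does not equal 0.07 × 2.95 = 0.21;
the discrepancy is recorded and deliberately not reconciled.

## Shape model

Centred PCA (full SVD, deterministic — no randomised solver at these sizes)
of the chosen representation: S2S scalars (default for survival), flattened
coordinates, or their concatenation; which representation the original
analysis used is not resolvable, hence the switch. Eigenvalues use the n−1
denominator; training scores therefore have variance equal to the
eigenvalues. Mode signs are arbitrary in PCA, so each mode is oriented along
the mean shape when that projection is meaningful (a size mode then grows
with +SD) and otherwise by making its largest-magnitude loading positive.
Mode reconstructions are `mean + c·√λ_k·e_k`.

## Survival

Cox proportional hazards via partial likelihood with Efron tie handling
(better than Breslow with many ties); Wald 95% CIs `exp(β̂ ± 1.96 SE)`.
Continuous predictors are standardised by default so hazard ratios are per
SD, matching the vertex-wise convention (the source does not state its
scaling; the choice is a flag). Follow-up time runs from baseline to the
earliest of event, death, or administrative end; prevalent cases must be
excluded upstream and are rejected. The FDR family is all predictors ×
outcomes × kidneys collected in one run. Near-separation (SE > 100) flags the
estimate instead of failing.

## Phenotypes and QC

CKD-EPI 2009 exactly as printed (κ = 0.7/0.9, α = −0.329/−0.411, the 1.018
female and 1.159 Black multipliers); the equation is continuous at Scr = κ
and strictly decreasing in creatinine and age. Creatinine conversion requires
an explicit unit tag (µmol/L ÷ 88.42 → mg/dL) and never guesses — a silent
unit mix-up shifts eGFR by orders of magnitude, and biobank field units are a
known trap. The blood-pressure rule is an OR across the SBP ≥ 140 and
DBP ≥ 90 thresholds. QC order is fixed: missing covariates first, then
either-kidney volume < 30 ml among the remainder, reproducing the published
5,272 / 305 partition semantics; extreme S2S values (outside the 0.1/99.9%
quantiles) are flagged, never excluded.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the imaging physics. The template is a bent ellipsoid ("bean", semi-axes
18 × 30 × 55 mm) meshed from a welded UV sphere with the grid chosen to hit
the requested vertex count (within 10%). Subjects displace template vertices
**strictly along outward normals** by standardised-covariate effects plus
spatially correlated Gaussian noise; because the deformation is along
normals, the true signed S2S matrix is known exactly and is returned for
oracle tests.

Noise is i.i.d. vertex noise diffused over the mesh graph, with the pass
count set from the correlation length (default 10 mm; the real within-cohort
spatial covariance of S2S is unknown — this is a free parameter, not an
inference), rescaled so the median per-vertex SD matches `noise_sd` (default
3.0 mm, the scale reported for population kidney S2S data). Raw i.i.d. noise
would make cluster enhancement unrealistically powerful.

Covariate distributions default to the study population's summary statistics
(age 64 ± 7.5 clipped to 44–82, BMI 26.5 ± 4.3, 48.3% male, 3.1% non-white,
disease prevalences of the reported order); creatinine is drawn lognormal per
sex so a small fraction falls below the eGFR-60 CKD criterion, and the
disease flags are then derived through the same classification rules the
phenotype module applies to real data. Event times are exponential with
hazard `h0·exp(xᵀ log HR)` (default h0 = 0.05/yr, chosen so desk-scale
cohorts contain enough events to fit), censored administratively with
staggered follow-up uniform over `3.7 ± 2.3` years — median ≈ 3.7 years, IQR
≈ 2.3 years, matching the reported follow-up.

One root seed drives per-stage child streams (covariates, noise, phenotype
derivation, survival), so each stage is reproducible in isolation and a fixed
seed reproduces cohorts bit-identically.

**What passing tests show — and don't.** The synthetic model satisfies the
analysis assumptions exactly (linear effects, Gaussian vertex noise,
proportional hazards, exact correspondence). Passing calibration, power and
recovery tests therefore validates the implementation, not the assumptions;
on real data, correspondence error, non-Gaussian noise, nonlinear effects and
confounding all remain possible and are outside what these tests can
establish.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by the package's own
choice: meshes of ~130–600 vertices (4,000 available and used for the
template-scale check), cohorts of 60–500 subjects, 200–500 permutations, 200
null replicates for calibration, 300–500 replicates for CI coverage. The
null-calibration KS test uses one randomly chosen vertex per replicate:
vertices within one map are spatially correlated, and pooling them would
invalidate the i.i.d. KS reference; the pooled FDR check uses all vertices as
the BH procedure itself does.

Other numerics: population SD (not n−1) for covariate standardisation;
add-one permutation estimator (never p = 0); TFCE quadrature error is O(dh),
i.e. ~1–2% at 100 steps for the constant-field analytic case; ties in the
TFCE sweep break by stable sort order, which cannot change component
membership (equal values join the same component at their shared threshold).

## Known limitations

- Vertex-wise models are linear; no spatial mixed models or nonlinear fits.
- The non-rigid step is a surface-based stand-in for volumetric free-form
  registration; only the contract, not the numerics, matches.
- No competing risks or time-varying covariates in the survival module.
- Mode interpretation (size, angle, length/width) is left to visual
  inspection of ±3 SD reconstructions; no automatic anatomical labelling.
- PLY output carries geometry only; per-vertex scalar maps go to legacy VTK
  or CSV.
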