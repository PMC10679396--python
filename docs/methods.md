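# Methods

This note records what the package computes, the choices made where the
procedure was genuinely open, and what the synthetic studies do and do not
demonstrate.

## Geometry and rasterization

All volumes live on axial, axis-aligned voxel grids in physical mm; voxel
(i, j, k) is centred at `origin + (i·dx, j·dy, k·dz)`. Structures are closed
planar polygons per axial slice. Rasterization marks a voxel as member iff
its **centre** lies inside the slice's polygon(s) under the **even–odd**
rule with a half-open edge convention (an edge owns its lower-y vertex).
This makes membership deterministic, invariant to vertex-order reversal,
unambiguous for centres level with a vertex, and checkable against a
per-voxel brute-force oracle. Clinical TPSs do not publish their fill rules,
so voxel counts at structure boundaries may differ from a clinical system by
a boundary layer; volumes in cc are `count · dx·dy·dz / 1000` with no
partial-volume weighting. Oblique or rotated grids and deformable
registration are out of scope.

## Gas density and GIGED

Gas HU statistics are the arithmetic mean and sample SD (n−1 denominator;
the estimator choice is ours) of the voxel HU inside a mask. Cohort-level
aggregation tests normality of the per-patient mean HU per structure with a
two-sided Kolmogorov–Smirnov test against a normal with the sample's own
mean and SD (plain KS p-value is reported; with estimated parameters it is
conservative — the Lilliefors caveat). Organ pairs (stomach/small-bowel/
large-bowel gas) are compared with a two-sided Wilcoxon–Mann–Whitney test:
exact enumeration when the smaller sample has n ≤ 8 and there are no ties,
otherwise the normal approximation with tie correction.

The calibration curve is an ordinary-least-squares line through the
scanner's (HU, RED) points restricted to [−1000, 0] HU; points outside the
segment are ignored. The default curve is the two points (−1000 HU, 0.0)
and (0 HU, 1.0): the minimal physically anchored line (air and water),
which maps −620 HU to RED 0.38. **GIGED is computed from the pooled
(voxel-count-weighted) across-patient mean HU of GAS**, not per patient,
and is reported to two decimals. Whether GAS contains gas outside the three
organ partitions is left explicit: the partitions are subsets of GAS and
any residual is simply the set difference.

## Gamma analysis

`gamma_2d` implements the 2-D gamma index: for each reference pixel at or
above the low-dose threshold (default 10% of the reference plane's global
maximum — global normalization, the plan-QA default; local normalization is
not offered), the minimum over nearby evaluated positions of
`sqrt((Δd/δ)² + (r/dta)²)`, with δ the dose tolerance (default 1% of the
normalization dose) and dta the distance criterion (default 1 mm). The
evaluated dose is probed by bilinear interpolation on a polar disc of
offsets with step `0.1·dta` and radius `3·dta` (both configurable), visited
in order of increasing distance with an early stop once the distance term
alone exceeds the worst current gamma. The discretized search can only
**overestimate** the continuum gamma; on steep fields with a 1% tolerance
the per-pixel overestimate can reach a few tenths, but the passing rate
agrees with an exhaustive `0.01·dta`/`5·dta` brute-force search to well
within half a percentage point on the test ensembles, and running the
implementation itself at the oracle's settings reproduces the oracle
exactly.

Plan comparison extracts the axial, sagittal and coronal planar slices
through the grid planes nearest the GTV centroid (nearest-slice, no
interpolation — "projection" here means the planar section, the standard
reading for plan QA on a low-field MR-linac) and averages the three plane
GPRs. The first-named plan of a comparison is the reference; gamma is
asymmetric and both directions are never mixed.

## DVH metrics and AGV

Cumulative DVHs are exact voxel-counting histograms (default bin width
0.01 Gy). Dq is the highest dose covering at least q% of the structure
volume, linearly interpolated between bins; Vd is the covered fraction at
dose d. Metric deltas are field-wise first-named-minus-second. The active
gas volume is the cc of GAS voxels receiving **at least** 5% of the
prescription dose (inclusive threshold, literal prescription dose — not
Dmax). Which plan's dose defines the isodose is not fixed by the protocol;
the package defaults to APLAN (the clinical-convention override) so the AGV
is computable before any comparison outcome, and the choice is a function
argument reported in CLI output.

## Cohort trend and the 90% threshold

For each comparison the package fits OLS of GPR (%) on AGV (cc) — the line
as plotted, with its R² and Pearson r — and interpolates the AGV at which
the trend crosses a GPR of 90%. Two estimators of that crossing exist and
differ whenever R² < 1: the forward-fit closed form `(90 − intercept)/slope`
and the **inverse (calibration) regression** of AGV on GPR evaluated at
90%. The package reports the inverse-regression value as `agv_at_90`
(predicting the AGV working point from a GPR level is a calibration
problem, and it is the estimator consistent with the reference cohort's
published thresholds of 41, 60 and 139 cc); the forward closed form is kept
alongside as `agv_at_90_from_gpr_fit`. Thresholds are rounded to the
nearest cc. No outliers are excluded (the largest-AGV patient, 432.63 cc,
stays in), and the linear fit is a descriptive trend, not a claim that the
GPR–AGV relationship is linear. Note the packaged cohort carries
integer-rounded GPRs, so correlations recomputed from it can differ in the
second decimal from values derived from unrounded data.

## Synthetic data

The generator emulates the study conditions with no external data:

- **Phantom**: ellipsoidal body (~0 HU, Gaussian texture SD 15 HU) in air;
  three ellipsoidal organ regions (ST/SB/LB); ellipsoidal gas pockets
  placed inside their organs without mutual overlap, voxel HU drawn from
  Normal(−620, 90) clipped at −1000 HU; spherical GTV (12 mm radius) with a
  3 mm isotropic PTV margin. Default grid spacing is 4 mm (2 mm in the
  HU-recovery studies) — coarser than a clinical 1.27 × 1.27 × 1.25 mm CT;
  this is the package's default study size, chosen so a 21-patient cohort
  runs in minutes, and every geometric quantity is resolution-checked by
  construction rather than by matching clinical voxel counts.
- **Beams**: 24 coplanar beams equispaced outside two blocked 20° sectors
  centred at 120° and 240°; prescription 40 Gy at the 80% isodose.
- **Toy dose engine** (a declared scientific stand-in, not a Monte Carlo
  reimplementation): per beam, primary dose attenuates as
  `exp(−μ_eff · radiological depth)` with the radiological depth the line
  integral of RED along the beam (μ_eff = 0.06 cm⁻¹, a megavoltage-like
  effective attenuation), shaped laterally by the PTV's beam's-eye-view
  projection dilated 5 mm and smoothed with a 4 mm Gaussian penumbra. An
  ERE-like term perturbs dose at high→low RED interfaces along the beam
  axis: a source proportional to the RED drop and to
  `max(0, 1 − RED_gap/0.5)` boosts the upstream (solid) side and
  suppresses the cavity, decaying exponentially with a 10 mm range. The
  0.5 scale encodes that measured depth-dose distortions vanish once the
  cavity density reaches about half of water; the gain (0.6) sets the
  perturbation to the tens-of-percent scale seen at low-field tissue–air
  interfaces. Beam geometry is parallel (no divergence), there is no
  build-up region, and no magnetic-field transport is modelled.
- **Plan triplets**: CT → RED through the calibration curve; GAS overridden
  to 0.0012 / 1.000 / GIGED; identical beam weights for all three plans,
  with the single normalization factor fixed on the unmodified baseline
  calculation (no re-optimization).
- **Slab experiment**: a 30 cm solid-water cube with a 3 cm variable-RED
  slab starting 7.5 cm deep, a fixed 10 × 10 cm² beam delivering 10 Gy at
  the 15 cm isocentre, 3 mm voxels; each gap RED's dose is gamma-compared
  (1%/1 mm) on the plane through the beam axis against the air-gap dose.
  The gap thickness is our choice (the source setup does not fix it).

Passing the synthetic studies shows the pipeline's *relations* hold —
GPR falls as AGV grows for every comparison, the triplet collapses to
identical plans when the gas is absent or the overrides coincide, dose
differences stay localized to the gas slab, and the slab GPR drops fastest
at low gap RED — not that the engine's absolute passing rates match a
clinical Monte Carlo. Absolute GPR-vs-RED values of a commercial engine and
cohort HU statistics of real patients are explicitly not reproduction
targets of the synthetic stack.

## Numerical choices and degenerate inputs

- Dose ties at thresholds are inclusive (≥) throughout.
- Gamma passes at γ ≤ 1 with a 1e-9 slack for float noise; offsets sampled
  outside the evaluated grid are ignored (never treated as agreeing).
- Empty masks error in statistics/centroid/DVH contexts; an empty GAS
  structure is valid and yields AGV = 0 and identical plan triplets.
- Constant samples error in KS and Pearson (undefined) rather than
  returning a value.
- The Mann–Whitney exact/asymptotic switch is at min(n) ≤ 8 without ties.
- RTDOSE writing quantizes at the declared grid scaling (round-trip error
  ≤ half a quantum); CT writing stores HU + 1024 as unsigned 16-bit.
- All generation is seed-deterministic end to end; cohort simulation draws
  child seeds below 2³¹ from one master generator.

## Known limitations

Axial axis-aligned grids only; no couch or gantry tilt; no beam divergence,
build-up, scatter kernels or magnetic-field transport in the toy engine; no
plan optimization (the triplet deliberately reuses one fluence); no
biological indices; the reference cohort ships with integer-rounded GPRs.
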