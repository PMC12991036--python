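# Methods

This document records the governing equations, the synthetic-femur design,
and the modelling decisions behind `femursweep`, in the order the pipeline
applies them.

## 1. Synthetic femur generation

The femur is an implicit solid: the union of a spherical head, a tapered
neck capsule, a profiled shaft tube, two condylar spheres and a bridging box,
meshed by Delaunay tetrahedralisation of exact surface samples plus a
jittered interior grid (`grid_spacing` controls the element count; the
default 5.5 mm gives ≈ 37k elements). Default dimensions sit inside adult
ranges: 400 mm shaft, 35 mm diaphyseal outer diameter at the isthmus, 51 mm
head, 122° neck–shaft angle, 90 mm intercondylar width.

The outer-radius profile along the shaft — subtrochanteric flare (22 mm),
isthmus (17.5 mm at 55% of shaft length), distal metaphyseal flare (24 mm) —
and the cortical-thickness profile (6 mm through the diaphysis, tapering to
3.5 mm at both ends) were fixed once, from textbook anatomy, **before any
finite-element result was computed**, and were not adjusted afterwards
(see the known-deviations section).

Two material modes:

* **two-phase** (Sawbones-like): an explicit cortical–trabecular boundary;
  cortical E = 16 700 MPa, trabecular E = 155 MPa, ν = 0.3.
* **heterogeneous**: a smooth synthetic density field rendered into an HU
  voxel image (`synthesize_hu_image`) with three calibration phantom rods at
  0 / 0.075 / 0.150 g/cm³, then mapped back through the calibration chain.

## 2. QCT calibration chain

From phantom ROI means, ordinary least squares gives ρ_QCT = a + b·HU.
Then

* ρ_ash = 0.0633 + 0.877·ρ_QCT
* ρ_app = ρ_ash / 0.626
* E = 6850·ρ_app^1.49 MPa, ν = 0.3

ρ_QCT is floored at 10⁻³ g/cm³ before the power law so air/marrow voxels
keep a tiny positive modulus. Element HU values are partitioned into at most
100 equal-width bins; each bin's representative HU defines one material set,
mirroring the 70–100 valid sets reported for cadaver models.

The three published phantom calibrations are reproduced exactly at the
printed slope precision (6.799/6.975/6.657 × 10⁻⁴ g·cm⁻³/HU). Note the
published intercept column header ("a (10⁻⁵)") matches only the first
subject and the printed values drop the sign; the fitted intercepts are
−0.01453, −0.006381 and −0.004882 g/cm³. Published R² values are displayed
with three decimals (values rounding to 1.000 printed as 0.999); the fits
agree within one unit in the last printed digit.

## 3. Anatomical frame, registration, stations

The hip joint centre is a least-squares sphere fit of the femoral-head
surface nodes; the condyle centres are sphere fits of the condylar surfaces;
the knee joint centre starts at their midpoint. The shaft axis joins
diaphyseal cross-section centroids; the medial direction is re-derived from
the hip-centre offset (so mirrored meshes register correctly). The mesh is
rigidly registered: hip centre at the origin, shaft axis +z (superior),
medial +x, coronal plane x–z. The mechanical axis joins the hip and knee
centres.

Stations are selected without manual input: k-means (fixed seed) over node
coordinates into five regions; clusters containing head or condyle surface
nodes are discarded; the remaining diaphyseal nodes are re-clustered into
three subregions whose centroids — ordered proximal → distal — define the
transverse planes of the lesion sweeps.

## 4. Finite elements and the stance load case

Constant-strain linear tetrahedra; per-element isotropic material. Surface
node sets are tied rigidly to 6-DOF reference points (head → hip reference;
each condyle → its own reference) by master–slave elimination
(u_s = u_r + θ×d). Both condyle references are fully fixed; the stance load
**R = 7.5 × 68 kg × 9.81 m/s² = 5003.1 N** acts at the free hip reference
along the mechanical axis. The reduced system is solved by sparse LU;
reactions come from the internal-force residual at the fixed ties, and the
global equilibrium residual is verified below 10⁻⁸ (typically 10⁻¹²).
Unit-modulus element matrices are cached, so a lesion case costs one sparse
low-rank update K₀ + ΔK and one factorisation; knee-balancing iterations
reuse a single factorisation (only the load direction changes).

**Knee balancing.** The knee centre is moved in the condylar plane
(medial–lateral, then antero-posterior) by bracketed root finding until the
medial condyle carries 55 ± 0.1% of the total reaction magnitude and the hip
displacement lies in the coronal plane (|u_y|/|u| < 10⁻³). On the default
femur this converges in ~14 re-solves to a medial share of 54.994%.

## 5. Lesions and metrics

Lesions are 10 mm spheres; every element whose centroid falls inside has its
modulus replaced by 50 kPa. Sweep paths run medially → laterally in 1 mm
steps through each station, in the transverse plane, covering every centre
whose sphere still intersects bone; centres whose sphere pokes past the
outer surface are flagged and excluded from structural solves.

* **Elasticity-loss (Eq. 1)**: (Σ V_i E_i¹ − Σ V_i E_i⁰) / Σ V_i over the
  lesion elements (MPa, negative).
* **Stiffness-loss (Eq. 2)**: R₁/U₁ − R₀/U₀, where R is the applied-force
  magnitude and U the **magnitude** of the hip-reference displacement,
  lesioned vs lesion-free (N/mm).
* **TCI**: depth of lesion-sphere penetration past the cortical–trabecular
  interface along the sweep direction (two-phase meshes), capped at the
  lesion diameter.
* **Cortical volume loss**: total volume of cortical-labelled lesion
  elements.
* **Strain probes**: principal strains averaged over spherical probes along
  the station's medial–lateral line. The probe radius defaults to 1.5 mm in
  `probe_strain`; the sweep pipeline uses 4 mm because desk-scale meshes
  (≈5 mm elements) leave 1.5 mm spheres empty.

Losses are normalised per femur by the largest magnitude, giving values in
[−1, 0]; the summary reports the extreme elasticity- and stiffness-loss with
station and medial/lateral side. For heterogeneous models (no explicit
interface) `detect_tci_case` locates a target TCI from the first run of
strictly increasing elasticity-loss records.

## 6. Known deviations at desk scale

All analysis below was performed **after** the generator was frozen; per the
project's no-tuning rule the geometry, seeds and thresholds were left
unchanged, and the two affected acceptance tests fail deliberately.

1. **Stiffness-loss maximum lands distal, not mid.** On the default femur
   the largest |Eq. 2| is −17.8 N/mm at the distal station (medial side)
   versus −8.1 N/mm at mid; the literature expectation is a mid-shaft
   maximum. The work-conjugate stiffness loss R²/(F·u) puts mid and distal
   medial maxima nearly equal (−24.25 vs −24.37 N/mm), so the discrepancy
   is a property of the magnitude-based definition on this straight-shaft
   geometry, not of the solver.
2. **Positive Eq. 2 values on the lateral side.** The baseline hip
   displacement is bending-dominated (u = [1.237, 0, −0.490] mm; only 41%
   of |u| lies along the load). Lateral cortical lesions rotate the
   displacement vector medially and can *shrink* its magnitude, producing
   "losses" up to +8.56 N/mm. The conjugate metric is negative for every
   lesion (variational monotonicity holds in the energy norm), confirming
   this is the metric, not the mechanics.
3. Properties that do hold on the default femur: medial maxima ≥ lateral at
   the proximal and mid stations; trabecular-confined lesions below 0.7% of
   the femur maximum; peak |ε_min| > peak ε_max in every lesion case; and
   Spearman rank correlation 0.995 between normalised elasticity-loss and
   normalised cortical volume loss across inside-bone, cortically involved
   positions (positions whose sphere extends past the outer surface are
   excluded: there the shrinking lesion volume saturates Eq. 1 while the
   destroyed cortical volume falls).
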