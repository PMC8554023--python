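# Methods

## Vector formalism

Clinical cylinders `C @ φ` (diopters at a meridian in [0, 180), TABO
convention) are mapped to double-angle vectors `(C cos 2φ, C sin 2φ)`.
Every sum, difference and centroid in the package passes through this one
representation (`core.py`); there is no cross-cylinder trigonometry
anywhere else, so a single code path carries the algebra.  Inputs at
exactly 180° normalize to 0°, and a zero-magnitude cylinder takes the
canonical axis 0 so equality is well defined.  The centroid obeys the
triangle inequality `|centroid| ≤ mean |·|`, with equality only for
collinear axes — the reason mean absolute error and centroid error are
reported side by side.

## Plane conversions

*Spectacle → cornea.* `D/(1 − v·D)` with vertex distance `v = 0.012 m`
(configurable).  Applied to the cylinder magnitude; the axis is
unchanged.  The map is strictly amplifying for positive cylinders and has
an exact inverse used by the generator.

*IOL plane → cornea.* A nested vergence chain in the aqueous (reduced
index 1.336; vergences in D against distances in mm, hence the constant
1336): focal distance of the cornea, transfer by ELP to the IOL plane,
addition of the IOL cylinder, transfer back, minus K.  Identities used
as verification anchors: ELP → 0 collapses the chain to the identity, and
for ELP > 0 the corneal-plane effect is strictly smaller than the
labelled cylinder.  ELP is taken directly as the postoperative anterior
chamber depth unless an offset is configured.

The cylinder can be converted *meridionally* — difference of the two
principal powers, flat `P₀` and steep `P₀ + D_IOL`, each propagated
through the chain — or *scalar-wise*, plugging the cylinder straight in.
With an IOL base power `P₀ = 0` the two coincide algebraically; the
meridional path takes an `iol_base_power` argument because the base
(spherical) power of the implant, when known, shifts the operating point
of the nonlinear chain.  Default: meridional with `P₀ = 0`.

## Composition signs

Back-solving preoperative astigmatism from postoperative observables
requires `actual = residual/cornea − SIA + toric/cornea`: the
postoperative cornea equals the preoperative cornea plus SIA, and the
toric correction plus manifest residual account for what remains.  This
(+1, −1, +1) composition is the default because it is the only one that
closes the noiseless synthetic pipeline exactly.  A literal unsigned
(+1, +1, +1) "vector sum" is selectable (`signs_mode="literal"`); runs
using it carry an explicit flag, and a dedicated test shows it misses a
known truth by `2·SIA`.  The toric contribution is the corneal-plane
cylinder oriented at the recorded 1-month postoperative IOL axis.

## Mode extraction

The corneal power map is a polar grid (default 0–4.5 mm radius at 0.1 mm,
360 meridians at 1°) of total refractive power with an apex origin and a
recorded pupil-center offset.  Per mode the samples are:

- **ring d**: nodes whose (re)centered radius is within half a radial
  step of d/2, unit weight;
- **zone d**: nodes within d/2, weighted by the node's polar area element
  `r·Δr·Δθ`.

Pupil recentering uses exact Euclidean geometry on the existing nodes —
powers stay attached to their nodes, only coordinates are re-expressed —
with an optional bilinear resampling path.  When the offset is exactly
zero the grid coordinates are used directly; round-tripping radii through
cosine/sine would let floating-point rounding split a boundary ring
across the selection edge.

The per-mode astigmatism is the weighted least-squares fit of
`K(θ) = a₀ + a₁ cos 2θ + a₂ sin 2θ`; cylinder `2·√(a₁² + a₂²)` (steep
minus flat power) at steep meridian `½·atan2(a₂, a₁)`.  At least three
distinct meridians are required or the design is rank-deficient.  The
device's internal algorithm is proprietary; this sinusoid is the standard
keratometric model and is documented as an emulation, not a device clone.

## Topography classification

Asymmetry indices are read on the 5-mm screening ring: the steep axis
from the whole-ring fit; I-S as power at the inferior intersection
(downward vertical component in right-eye-view coordinates) minus the
superior one; S-I as its negation; SRAX as the acute angle between steep
axes refitted separately on the superior and inferior half-rings.
Asymmetric iff I-S > 1.5 D, S-I > 2.5 D or SRAX > 22° — strict
inequalities, so the boundary values remain symmetric.

Bowtie diameter operationalizes the clinical reading of a color map with
0.25 D steps: along the steep meridian (fitted on the central 2-mm zone,
since a small bowtie need not reach the 5-mm ring), each lobe extends to
the farthest contiguous radius whose power exceeds the flat-meridian
power at the same radius by ≥ 0.25 D; the diameter is the tip-to-tip sum.
Types: A ≤ 5 mm < B ≤ 7 mm < C (inclusive upper bounds).  The contrast
threshold is configurable; equivalence with a human reading of the color
map cannot be established from first principles and is a stated
limitation.  Irregular astigmatism grades: mild < 0.3 μm ≤ moderate
< 0.5 μm ≤ severe.

## Synthetic generator

One cornea is `K(r, θ) = K₀ + g·r + A(r, θ)·cos 2(θ − φ_half) + ε`,
where the amplitude `A = C(r)/2` carries a radial profile (constant, or a
cutoff with optional linear taper; a hard cutoff at radius c yields a
recovered bowtie diameter of exactly 2c), plus an inferior-half amplitude
offset that raises the inferior steep point by `lobe_asymmetry` diopters
(so I-S recovers that value), and per-half axes `φ ± skew/2` (so SRAX
recovers the skew).  `ε` is i.i.d. N(0, noise_sd²) per node.

A cohort draws per-eye marginals from normals truncated at zero (or
physiologic bounds) — preoperative cylinder 2.09 ± 0.74 D, SIA magnitude
0.55 ± 0.38 D, pupil diameter 2.69 ± 0.55 mm, ELP 3.18 ± 0.46 mm, net
corneal power 43.5 ± 1.4 D — with steep axes uniform on [0, 180) by
default (a with-the-rule von Mises concentration is available), SIA at a
temporal incision meridian, and a pupil offset of 0.15 mm SD per
component.  39% of eyes are built asymmetric (half I-S-driven at 2.0 D,
half SRAX-driven at 30°); symmetric eyes receive bowtie cutoffs 2.25 /
3.0 / 4.0 mm in proportions 6:18:12, matching the bowtie subtypes of the
population being emulated.  K and ELP defaults are documented
assumptions: the population's own K and postoperative chamber-depth
statistics are not reported beyond the anterior chamber depth, which is
used for ELP.

The forward optics then run the package's own operators: the toric
cylinder is back-solved (closed-form inverse of the vergence chain) from
the planning-mode measurement plus the surgeon's anticipated mean SIA at
the incision, implanted with a N(0, 5°) axis error; the postoperative
cornea is the preoperative one plus the SIA vector (exact, because the
keratometric fit is linear in the map, so a radially uniform additive
term shifts all 16 modes by the same vector); and the manifest residual
is *derived* — postop minus toric effect, plus N(0, 0.25 D) per
double-angle component of manifest noise, inverted to the spectacle
plane.  Residual astigmatism and IOL cylinder are therefore emergent
marginals (≈ 0.53 ± 0.32 D and ≈ 2.7 ± 1.0 D at large n), near but not
identical to the emulated population's 0.62 ± 0.41 and 2.39 ± 1.00 —
the generator reproduces the drawn marginals exactly and the derived ones
only as closely as the assumed optics allow.

Two measurement paths exist: the default analytic path computes the 16
mode values in closed form (exact for symmetric, centered corneas; used
for large-n calibration), while `with_maps=True` builds each map and
extracts the modes numerically, which is required for centration,
asymmetry and map-noise effects to reach the measurements.  Everything is
reproducible bit-for-bit from the seed.

What the generator does **not** emulate: posterior-surface/total-power
discrepancies, radially varying steep-axis torsion within a lobe,
epithelial or tear-film fluctuation between visits (postop mode values
share the preop map's noise draw), IOL rotation over time, and optical
blur of the manifest refraction beyond additive Gaussian noise.  Passing
tests therefore certify the algebra, the conversions and the extraction
geometry — not that any particular analysis mode is clinically superior
on real corneas; beyond the bowtie cutoff the synthetic cornea turns
spherical, which exaggerates ring/zone divergence at large diameters
relative to real eyes.

## Statistics

Median absolute errors are compared with the paired Wilcoxon signed-rank
test and means with the paired t-test, mirroring how such cohorts are
conventionally reported; a Shapiro–Wilk-gated policy is available.  The
signed-rank p uses the exact null for ≤ 25 nonzero differences, the
normal approximation beyond.  All-zero differences make the statistic
undefined; the comparison is flagged degenerate and reported as p = 1.
No multiplicity adjustment is applied by default.  Sample size for the
paired design uses the Guenther-corrected normal approximation
`n = (z_{1−α/2} + z_{pow})²(σ/δ)² + z²_{1−α/2}/2`, divided by the Pitman
ARE 3/π for the Wilcoxon variant and rounded up (0.20 D, 0.50 D, 0.05,
0.80 → 51 and 54 eyes); uncorrected-normal and noncentral-t variants are
exposed.

## Numerical choices

- Double-angle round trips and oracle agreements are held to 1e-9 D.
- Ring tolerance is half the radial grid step; selection edges carry a
  1e-9 mm tolerance so grid-construction rounding cannot flip a node.
- The least-squares fit uses `numpy.linalg.lstsq` on the √weight-scaled
  design; the sinusoid basis is orthogonal over complete meridian circles,
  so mean-power gradients cannot leak into the cylinder estimate.
- Degenerate inputs raise (empty centroids, rank-deficient fits,
  vergence steps through zero — each named) rather than returning NaN;
  sub-threshold topographies are flagged not-applicable instead.
- Test problem sizes: 1,000-case oracle sweeps, 50-eye full-map closure
  cohorts, 10,000-draw calibration and Rayleigh checks, 1,000-replicate
  type-I simulations at 30 pairs.

## Known limitations

- The bowtie-diameter contrast rule is an operationalization of a manual
  color-scale reading.
- The vergence chain treats the cornea as a single thin refractive
  surface of power K; no thick-lens corneal model.
- Analysis modes share a single postoperative measurement per eye (the
  SIA pairs it with one configurable preoperative mode), so SIA is not
  mode-resolved.
- No spherical-equivalent / power-vector (M, J0, J45) refraction algebra:
  only the cylinder component is analyzed.
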