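# Methods

`earset` re-creates a computed-tomography grain-set phenotyping pipeline
for cereal ears: from a reconstructed 3D grey-value volume to per-grain
digital traits, virtual seed weights, the virtual 2 mm sieve and
seed-weight-versus-ear-position profiles. Because real scan data of this
kind is rarely shareable, the package ships a first-class phantom
generator with exact ground truth, so every stage is validated by
parameter recovery rather than by eyeballing.

## The volume contract

All stages operate on a `Volume`: a `uint16` grey array in `(z, y, x)`
order (z vertical) with two mandatory metadata fields, the voxel spacing
(µm) and a linear `grey_per_absorption` scale. Grey values are *never*
interpreted without the scale; absorption (1/mm, for the effective beam
spectrum) is `grey / grey_per_absorption`. This mirrors the normalization
contract of production FBP reconstructions in which grey values represent
physical absorption. World positions are `(index + 0.5) x voxel size`;
bounding boxes are half-open; region labelling uses 26-connectivity,
the surface operator 6-connectivity.

## Phantom generator

The generator emulates a reconstructed wheat ear:

- **Layout.** A vertical rachis cylinder (radius 0.8 mm, chaff-level
  attenuation) carries spikelets every 3.2 mm, alternating sides
  (phyllotaxis 180°, configurable), each bearing up to two grains fanned
  in azimuth. Grain long axes tilt ~35° up-and-outward. Awns are thin
  rods (radius 0.15 mm) on a configurable fraction of seeds.
- **Grains.** Superellipsoids (exponent 2 by default, i.e. ellipsoids;
  larger exponents give angular grains) with semiaxes drawn from
  (2.2–3.0, 1.3–1.7, 1.0–1.4) mm, bracketing single-grain volumes of
  roughly 8–30 mm³ — the range reported for drought- and
  drought-plus-heat-stressed wheat. A configurable fraction (default
  15%) is scaled down below the 2 mm sieve width, emulating shrivelled
  small seeds. Optional carvings: a half-cylindrical crease channel along
  the long axis on the rachis-facing side (enlarged crease cavities are a
  stress symptom), a spherical germ notch at the basal pole, and a
  low-frequency boundary perturbation ("shrivel").
- **Contacts.** Non-touching seeds are guaranteed a ≥0.25 mm
  surface-to-surface clearance via the superellipsoid support function;
  a requested fraction of seeds is deliberately placed in touching pairs
  (slight interpenetration, verified by 26-connectivity contact after
  rasterization and demoted if contact failed). Impossible packings
  raise an error naming the first non-placeable seed; a voxel size that
  resolves any semiaxis with fewer than 4 voxels is rejected.
- **Intensities.** Grain attenuation 0.80 (the mean physical absorption
  reported for wheat grain; treated as 1/mm in this package's units),
  chaff 0.35, strictly lower — the two-class density assumption the
  segmentation relies on. The peak absorption maps to grey 60000
  (headroom for noise) and Gaussian grey noise (default SD 3000 = 5% of
  the seed grey level) is added before quantization.
- **Truth.** Per seed: centre, semiaxes, analytic superellipsoid volume
  (voxelized volume where carvings/shrivel/touch trimming make the
  closed form unavailable), voxel count, minimal Feret width (measured
  on the truth mask with the same width definition as the trait stage),
  flags, and a voxel-exact label volume. True weight uses a configured
  density factor of 1.6e-3 g per (mm³ x absorption unit), chosen so a
  23 mm³ grain at absorption 0.8 weighs ~0.03 g, matching reported
  single-grain weights.

Defaults are the desk-test study conditions: 100 µm voxels (production
scans use ~31 µm; only the voxel knob changes), 20–60 seeds per ear.
Identical spec + seed gives bit-identical output.

What the phantoms do *not* emulate: partial-volume blur at grain
boundaries, beam hardening and scatter, cone-beam artefacts, glume
wrapping around grains, non-convex grain poses. Passing recovery tests
therefore demonstrates the pipeline's correctness under idealized
reconstruction, not its accuracy on any particular scanner.

## Simplified reconstruction

The production system scans helically with a cone beam; everything
downstream needs only a normalized absorption volume, so the recon module
substitutes a parallel-beam, slice-stacked geometry that is verifiable
against closed forms (Beer–Lambert projections of cubes and disks). Two
production properties are reproduced faithfully:

- **Per-projection I₀ normalization.** The unattenuated intensity is
  detected per projection as the median of the top decile of
  border-column pixels (the specimen never fills the detector laterally).
  If the candidate border columns disagree by >2% there is no stable air
  region; a warning is emitted and the global maximum is used. A
  perfectly uniform specimen covering the whole detector is
  *in principle* indistinguishable from air at lower I₀; the fallback
  triggers on any thickness variation. Normalization makes the
  reconstruction invariant to primary-beam drift (verified at 10%
  sinusoidal drift, ≤0.1% RMS change).
- **16-bit grey mapping.** The volume's maximum absorption maps to grey
  60000; the scale is always written to the sidecar.

Filtering is a Hann-windowed ramp at Nyquist (`skimage.transform.iradon`).
A homogeneous disk reconstructs to within 5% of its true µ in the core at
720 angles; reconstruction is linear in µ to ~2%.

## Segmentation

1. **Ear separation** (automated; `expected_ears` guards correctness):
   foreground at the midpoint of the two 3-class Otsu thresholds —
   above the air-noise tail yet including the rachis — is block-max
   pooled at 8×, bridging the sub-millimetre gaps between grains, glumes
   and rachis so each ear is one coarse component. Components are ordered
   left-to-right; each gets a principal-axis estimate oriented bottom-up.
2. **Grain/chaff separation**: a 3-class intensity split
   (air | chaff | grain) on absorption. The class above the chosen
   threshold must average at least `grain_floor_absorption` (default
   0.5/mm — wheat grain sits near 0.8, chaff well below 0.5); this
   absolute floor is what lets a fully aborted ear (rachis + awns only)
   come back grain-free instead of mislabelling chaff, and it is
   legitimate precisely because volumes are absorption-normalized. If
   both upper classes reach the floor, the split landed inside the grain
   mode (chaff-free volume) and the lower threshold is used. An explicit
   `grain_threshold` overrides auto-detection.
3. **Opening and splitting**: per connected component (26-connectivity),
   a morphological opening with a ball of radius ⌈0.3 mm / voxel⌉
   (via two local distance transforms) removes residual thin structures.
   The opened mask only decides *whether* the component is grain and
   *where* watershed markers go (distance-transform maxima, Gaussian
   σ = 1 smoothed, separated by ≥1.5 mm, depth ≥2 voxels); the final
   regions partition the *original* thresholded component, so measured
   widths and volumes reflect the real grain mask rather than its opened
   erosion — without this, the opening shaves crease lips and biases
   near-cutoff sieve decisions. Components or fragments below 27 voxels
   are dropped as debris. Regions produced by splitting are flagged
   `touches_another`.

Per-component processing (rather than full-volume morphology) keeps a
50-ear desk-scale population under ~2 minutes on one CPU.

## Traits

- **Minimum covering sphere** — exact, via Welzl's randomized incremental
  algorithm. Large voxel sets are first reduced to convex hull vertices;
  above 64 points a violator-driven refinement runs Welzl on a small
  active set and adds the farthest uncovered point until coverage — the
  result is still exact (the active set's minimum sphere covers all
  points and cannot exceed the full minimum). An exhaustive
  support-subset oracle in the test suite confirms 1e-9 agreement.
- **Aspect (spherical) ratio** — radius of the equal-volume sphere over
  the minimum-covering-sphere radius of the voxel centres, clipped to 1;
  1 for a sphere, →0 for a thin rod. A single voxel is defined as 1
  (sphere-like); the 27-voxel floor keeps this case out of real runs.
- **Surface** — count of region voxels with a 6-neighbour in the
  background; surface/volume is the relative surface (near 0 for a ball,
  near 1 for a one-voxel plane).
- **Minimal width (virtual sieve)** — minimum over 256 deterministic
  Fibonacci-sphere directions of the projected centre span plus *half*
  the voxel footprint; half, because the digitized surface cuts boundary
  voxels roughly through their centres, so a full cube support would
  overestimate the underlying body's width by about one voxel. Measured
  error against a 4096-direction oracle is <1% and rotation scatter
  <3% for seed-like ellipsoids (128 directions showed ~5% scatter, hence
  256). Seeds below the cutoff (default 2.0 mm) in every direction are
  sieved out; retained + omitted always equals the total.
- **Virtual weight** — the per-voxel absorption sum times the voxel
  volume (algebraically identical to volume x mean attenuation over the
  same mask), multiplied by a calibration factor. The centre of mass is
  the absorption-weighted mean position computed in the same pass.
- **Calibration** — a single factor fitted through the origin
  (`k = Σva / Σv²`) on paired per-ear virtual sums and hand-threshed
  weights, by default on a ~10% ear subset; a scalar because the
  physical relation has no offset (zero seeds weigh nothing). The fit is
  unbiased under multiplicative noise (Monte-Carlo checked).

`mean_attenuation` is reported in the volume's absorption unit and never
in raw grey; no claim is made that it converts to g/cm³.

## Ear profiles and evaluation

Seeds are ordered by the scalar projection of their centre of mass onto
the ear axis (axis sign fixed so the vertical component is positive:
bottom seed is always normalized position 0, top seed 1; a single seed
sits at 0). The weight-position profile pools all seeds (big and small)
across ears into 20 equal bins by default (resolution configurable; the
last bin is closed), reporting per-bin mean virtual weight; empty bins
are missing, not zero, and bin means times counts re-sum exactly to the
pooled weight. Evaluation against reference measurements reports r² as
the squared Pearson correlation of per-ear totals (weight, and sieved
seed count); a constant reference vector leaves r² undefined and it is
reported as missing. Group summaries average single-seed traits per ear
first and only then across ears of a group.

## Verification strategy and problem sizes

The reference accuracy figures were established on 291 real scanned ears
that are not publicly deposited, so the test suite reruns each claim as a
scaled-down synthetic analogue with exact truth: 50 ears of 20–60 seeds
(about 1900 seeds) at 100 µm voxels, ~10% of seeds in touching pairs,
noise at 5% of the seed grey level. A truth seed counts as recovered only
if exactly one predicted region claims it by majority overlap and covers
at least half its voxels — merges and spurious splits both count against
accuracy. On these conditions the pipeline recovers ~98% of seeds
(the claim band is 95–99%), calibrated virtual weight tracks true weight
at r² ≫ 0.83, and sieved counts on touch-free ears reach r² ≥ 0.99.
`scripts/acceptance.py` recomputes the pooled recovery accuracy from
scratch for any seed.

## Known limitations

- The segmentation is a documented re-invention constrained by the
  published, measurable contracts (counts, volumes, the trait list) —
  the production algorithm's internals are proprietary and no bit-level
  equivalence is claimed.
- Helical cone-beam geometry, scatter, beam hardening and detector
  defects are out of scope; the reconstruction module is a test harness
  for the normalization contract, not a scanner model.
- The absolute grain floor assumes absorption-normalized volumes with
  grain near 0.8/mm; other crops or beam spectra need the floor (or an
  explicit threshold) adjusted.
- Touching-pair splitting assumes grain-scale marker separation
  (≥1.5 mm); heavily fused or sprouted grains would need finer markers
  or a learned splitter.
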