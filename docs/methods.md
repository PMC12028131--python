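# Methods

`vertemetrics` quantifies how faithfully one bone segmentation of the
lumbar spine reproduces another — the setting being a synthetic CT (sCT)
derived from MRI, validated against a reference CT of the same patient.
Because paired patient scans are not publicly available, the package
ships a parametric vertebra phantom with analytically known geometry and
validates the entire measurement chain by parameter recovery on it.

## The phantom

Each vertebra is a union of closed-form solids in a canonical anatomical
frame (+x subject right, +y anterior, +z superior), rasterized by the
voxel-center rule (a voxel is bone iff its center lies inside a solid):

* **Vertebral body** — elliptic cylinder, RL extent `body_width`, AP
  extent `body_length`. The anterior/posterior height difference is a
  wedge cut into the *superior* endplate; the inferior endplate stays
  flat and perpendicular to the local axis. Putting the wedge on top
  keeps both endplate-offset axial cross-sections complete (an oblique
  inferior endplate would be clipped by its own measurement plane) while
  still exercising the endplate-plane fit with a genuinely tilted top.
* **Pedicles** — elliptic cylinders of nominal cross-section
  `pedicle_width x pedicle_height`, length `pedicle_length`, canted in
  the axial plane by `pedicle_cant_deg`, with a cosine constriction that
  scales the cross-section to `pedicle_constriction` at mid-length. The
  constricted (isthmus) extents are the ground-truth pedicle width and
  height.
* **Spinous process** — an extruded stadium (rectangle with semicircular
  caps) of tip-to-tip length `spinous_length`, tilted caudally by
  `spinous_tilt_deg`. The stadium profile is deliberate: among simple
  profiles it is the one whose longest central chord lies exactly along
  its axis, so the sweep-based length measurement has a well-defined
  analytic truth. (For a plain box the oblique diagonal chord exceeds
  the axial length, which would make the generative length unrecoverable
  by *any* longest-line definition.)
* **Lamina** — a flat slab bridging the posterior pedicle ends;
  **transverse processes** — lateral bars. Neither is measured; they
  complete the part vocabulary and keep the vertebra one connected
  component.

Solids overlap slightly at their anatomical junctions so the rasterized
vertebra is 26-connected at every supported spacing. Overlapping voxels
are resolved by the fixed precedence `body > pedicle > spinous > lamina
> transverse`; the spinous process outranks the lamina so that its
anchored base stays labeled "spinous" and the labeled region keeps the
full generative length. Ground-truth records are functions of the spec
alone — independent of pose and voxel spacing.

Default dimensions are typical adult lumbar values (body heights
~23–33 mm, widths 35–50 mm, nominal pedicle widths 8–12 mm with
constriction 0.72–0.92, spinous lengths 25–40 mm); the cohort sampler
draws uniformly from those ranges. The default grid spacing is 0.5 mm,
the sub-millimeter regime a reconstructed sCT grid works in.

## The degradation model

`DegradationSpec` emulates reconstruction error on a binary volume in
this order: Gaussian pre-threshold blur (`smoothing_mm`), a uniform
signed boundary shift (`boundary_shift_mm`, positive = dilation), a
zero-mean spatially correlated surface displacement (`noise_amplitude_mm`
with correlation length `noise_correlation_mm`, default 3 mm — smooth
sub-millimeter boundary undulation, not voxel noise), then re-threshold
at 0.5. Displacement is decided against the *exact* marching-cubes
iso-surface: a coarse signed EDT classifies voxels far from the
boundary, and only the ambiguous band (within about one voxel of the
displaced threshold) is refined with exact point-to-mesh distances, so
sub-voxel shifts move the expected surface by the requested amount. The
all-zero spec returns its input voxel-for-voxel.

What the model does *not* emulate: anatomy-dependent error structure
(e.g. worse reconstruction at endplates), topology changes, missing or
hallucinated structures, intensity information of any kind. Passing the
phantom battery therefore shows that the *measurement chain* is
accurate and stable under sub-millimeter boundary error; it does not
certify performance on real patient data.

## Surface-distance metric

Binary masks become meshes by marching cubes at iso-level 0.5 on a grid
padded by one voxel (so surfaces are always closed). A light Gaussian
pre-smoothing of 0.7 voxel is applied before triangulation, with a
fallback to the raw mask when smoothing would sink a thin structure
below the iso-level. Without it the staircase of the binary grid
inflates surface area by ~9% and biases point-to-surface distances; with
it a 20 mm ball meshes to within 1% of its analytic area and concentric
20/21 mm spheres measure 0.99 mm apart.

The metric itself is the directional surface-distance RMSE: evaluated
points are the source-mesh vertices; each gets its exact minimum
Euclidean point-to-triangle distance to the full target mesh; the values
are pooled as sqrt(mean(d^2)). The measure is asymmetric by
construction and the direction is part of every result. The pipeline
default follows the reference-to-comparison direction (CT points against
the sCT surface); `--direction` flips it. Part-restricted variants
select source vertices by the *source* part labels (nearest labeled
voxel per vertex) but always measure against the full target surface.

The KD-tree acceleration is exact, not approximate: the candidate set
for each point includes every triangle whose centroid lies within
(upper-bound distance + largest triangle circumradius), which provably
contains the true nearest triangle; tests verify bit-level agreement
with a brute-force all-pairs scan.

## Vertebra frame and 2D measurements

* **SI** — normal of the superior endplate plane, fit by least squares
  to the topmost body voxel per (RL, AP) column within the top 15% of
  the body's SI extent, with up to four trimmed re-fits (3 x MAD) to
  reject the downhill lateral-wall points that contaminate the top-voxel
  set at larger scan tilts.
* **RL** — unit vector from the left to the right pedicle centroid,
  orthogonalized against SI. **AP** = SI x RL. Origin = body centroid.
  Swapping the pedicle arguments flips RL and AP and leaves SI alone;
  no silent re-orientation is attempted.
* **Body heights** — in the midsagittal plane (through the origin,
  spanned by AP and SI), the longest SI chord within the extreme 10% AP
  bands (anterior/posterior). The longest chord rather than the band
  mean: chords collapse toward zero at the tangent corner of the
  section, and the wall-height chord is the quantity the red-line
  measurement represents.
* **Body widths/lengths** — RL and AP chords through the section center
  in axial planes stationed 2 mm inside each endplate, where "inside"
  is measured at the point the endplate surface crosses the SI axis.
  This reproduces the pole-2 mm convention on a ball phantom and avoids
  clipping when an endplate is oblique to SI.
* **Pedicle width/height** — the screw-like trajectory starts as the
  mask's principal second-moment axis and is refined once by a robust
  line fit through cross-section centroids (complete sections of a
  straight canal are centered on its axis; the flaring body/lamina
  junctions bias the raw moment axis by several degrees). Planes
  orthogonal to the trajectory are swept over the middle 80% of its
  extent at half-voxel steps; the narrowest plane is the smallest
  *interior local minimum* of the lightly smoothed area profile (edge
  minima are clipped junction slivers, not the isthmus), ties broken
  toward mid-pedicle. Width is the in-plane extent along the
  RL-projected direction, height along the orthogonal in-plane
  direction. "Narrowest" minimizes area; width- or height-minimizing
  variants would be straightforward but are not what is implemented.
* **Spinous length** — near-axial planes through the spinous centroid,
  rotated about RL from -45 to +45 degrees in 1-degree steps; in each
  plane the center line is the locus of RL-chord midpoints and the
  candidate length is the straight-line span between its extreme
  points; the maximum over the sweep is reported.

All extents come from analytic plane-mesh intersections (chords of the
section segments), not voxel counts, giving sub-voxel resolution.
Cross-section areas are integrated from chords, which is exact in the
limit for sections whose vertical extent is a single interval — true for
every solid measured here.

Missing parts yield partial records (fields `None`), never fabricated
values; a missing body or pedicle makes the frame impossible and raises.

## Labeling

Volumes are binarized at a threshold (default 0.5), split into
26-connected components, and components under 100 voxels are dropped as
specks. The sacrum is recognized as the most inferior centroid
(overridable by an explicit seed point), and names walk the
L5→L4→…→L1→T12→… sequence by SI order in both directions from the seed.
Part segmentation of real scans is out of scope: parts must be supplied
and are only re-masked per instance.

## Statistics

Cohort tables report, per measurement and per surface region, the
median, sample standard deviation (n-1), and 75th/95th percentiles
(linear interpolation) of per-vertebra absolute differences; the unit of
aggregation is the vertebra. Pearson's product-moment coefficient
compares raw paired series and refuses degenerate (zero-variance)
input. Condition-tag grouping summarizes any tag meeting a minimum
occurrence count (default 20) and distinguishes spine-scope tags (all
vertebrae of a subject) from vertebra-scope tags.

## Problem sizes and numerical choices

The validation battery runs single-threaded in a few minutes by scaling
the experiments rather than the methods: metric identity on five 1 mm
phantom meshes; sphere oracles and degradation calibration on 20 mm
balls at 0.5 mm; parameter recovery on 20 random specs at 0.5 mm; rigid
poses up to 25 degrees; labeling on twenty 6-component spines at
1.25 mm; and the end-to-end cohort as twenty single-vertebra subjects at
0.5 mm with 0.5 mm correlated noise. All randomness flows from a single
seed through `numpy.random.default_rng`; identical config + seed gives
byte-identical reports (floats rounded to 1e-6 in JSON output).

Known limitations: phantoms are idealized solids without cortical/
trabecular texture or intensity values; degradation is statistically
homogeneous over the surface; part labels of degraded volumes are
transferred by nearest-neighbor from the reference rather than
re-segmented; oblique NIfTI affines are rejected rather than resampled;
and the thoracic naming sequence is available but untested against
thoracic-shaped geometry.
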