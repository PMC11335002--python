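# Methods

## The joint model

A joint couples an *anterior* and a *posterior* vertebra; the posterior is
the moving element. Inputs are assumed pre-oriented in a right-handed
anatomical frame: +X craniocaudal (pointing caudally), +Y dorsal, +Z
anatomical left. The joint frame assigns X to axial rotation, Y to lateral
bending and Z to sagittal bending; anatomical direction names are the
primary interface (dorsoflexion is a positive rotation about +Z, left
lateroflexion about −Y, left axial rotation about +X).

The centre of rotation (COR) is placed at the midpoint between the facing
endplate centroids for amphicoelous/acoelous centra, where the centroid of
an endplate is the mean of its four extreme landmarks (dorsal, ventral,
left, right). For procoelous centra the COR is the centre of an algebraic
least-squares sphere fitted to condyle sample points; the fit reports its
RMS radial residual and refuses coplanar input.

Joint spacing (the craniocaudal gap between facing endplate centroids) is
an input — the "optimal" spacing declared per joint in the column manifest,
scaled by the spacing multiplier of the uncertainty grid. The interactive
alignment step used on real scan data is out of scope here: meshes arrive
pre-oriented, and the synthetic generator emits its own spacing.

Soft-tissue locator pairs connect, across the joint:

* the four endplate extremes (intervertebral disc), and
* the cranial and caudal extremes of each articulating
  post-/pre-zygapophysis pair, per side (capsular ligaments).

The strain of a pair at a pose is (current length − neutral length) /
neutral length. Both tension and compression are limited at the same
allowance for capsule pairs and, by default, also for disc pairs
(`disc_tension_only` switches discs to tension-only). All pairs are
evaluated in every bending direction; a per-direction mask is available in
the configuration but off by default.

## The bending sweep

For each of the six directions the posterior vertebra is rotated about the
COR in 0.5° increments up to 90°. A pose violates when

* the bony overlap fraction strictly exceeds the intersection threshold, or
* any disc or capsule pair exceeds the strain allowance.

ROM is the last non-violating angle (a multiple of the step); the limiting
constraint is the family violated at the next step, with ties resolved in
the order bone, disc, capsule; reaching 90° is reported as "cap" in every
direction. Joint translations are not modelled. Disarticulation — loss of
all projected zygapophyseal facet overlap along the neutral facet normal —
is recorded (first angle at which it occurs) but does not stop the sweep.

The factorial uncertainty grid crosses spacing multipliers (0.9, 1.0, 1.1),
intersection thresholds (0.25%, 0.5%, 0.75%) and strain allowances (45%,
50%, 55% — the 50% base scaled ±10%), 27 variants per joint and direction.
Internally one sweep per (spacing, direction) records the constraint curves
and stops only when the most permissive variant has violated; each
variant's ROM is then read off the recorded curves, which makes the 27
variants cheap and guarantees the monotonicity of ROM in the threshold and
allowance by construction.

## Overlap measurement

No exact mesh-boolean backend is assumed. Overlap uses a deterministic
parity-voxelization kernel written for this package:

* Each closed part of a solid is rasterized onto a regular grid by exact
  ray-parity along X-columns of cell centres; the grid is snapped to an
  absolute lattice of the pitch, so solids differing only far from a
  contact zone share cell centres in the shared region (paired
  structure-removal arms see identical discretization), and the lattice is
  mirror-symmetric about the sagittal plane (bilaterally symmetric joints
  give exactly equal left/right ROM). Columns are nudged off exact cell
  centres along +Y by a sub-permille fraction of the pitch so rays never
  graze shared triangle edges of axis-aligned geometry.
* Intersection volume is estimated symmetrically: interior cell centres of
  each solid are tested against the other, counting a full cell volume per
  interior point. Points landing within one cell of a surface get an exact
  point-in-mesh parity test, so thin contact slivers are never lost to grid
  phase; points in "core" cells (surrounded by occupied cells) are accepted
  without it.
* Contact onset is additionally detected exactly from mesh vertices
  (either solid's vertices tested against the other solid). A pose with
  vertex contact but sub-resolution overlap volume is treated as an
  infinitesimally positive overlap, so a zero intersection threshold
  reproduces analytic first-contact angles exactly — this is what makes the
  cylinder-joint oracle `ROM = floor(2 atan(g/2r) / step) * step` hold.

The bending engine normalizes intersection volume by the mean enclosed
volume of the two *centra* (the largest closed part of each vertebra,
computed exactly by the divergence theorem). The centrum is the standard
size proxy, is untouched by spine truncation or intercentrum merging (so
paired experiments share their thresholds), and is independent of grid
pitch. The general-purpose `overlap_fraction` normalizes by the grid-
estimated union volume (or, optionally, total surface area) instead, which
makes identical solids return exactly 1. The default grid pitch is a
quarter of the mean edge length, clamped against degenerate extremes.

Meshes are multi-part unions: a vertebra assembled from closed primitives
(or merged with an intercentrum) keeps its parts, and containment, volume
and overlap treat it as the union. This keeps parity tests exact even when
parts interpenetrate, at the cost of never producing a single boolean
surface — planar cuts re-cap each part with an ear-clipped polygon instead.

## Stiffness

Relative stiffness per joint and plane is (lever x centrum area) /
(mean centrum length)^3 / ROM: the bending-moment proxy uses the COR to
arch-apex distance for sagittal bending (mean over the two adjacent
vertebrae's apexes) and the COR to lateral endplate-edge distance for
lateral bending, scaled by the mean endplate area. Dividing by centrum
length cubed makes the quantity dimensionless and invariant under isotropic
scaling — only comparisons between joints are meaningful. The size exponent
is exposed for sensitivity analyses. Zero ROM yields an infinite-stiffness
sentinel excluded from ratio and total.

## Post-processing

Raw tables are collapsed per joint by (i) dropping the 0.75% threshold
variants a posteriori (joints commonly disarticulate in axial rotation
before such overlaps are reached), (ii) averaging lateroflexion and axial
rotation across sides and multiplying by two — or doubling the intact side
when a joint is asymmetrically damaged — (iii) summing dorso- and
ventroflexion into sagittal ROM, and (iv) averaging across the surviving
variants (the mean is the aggregation statistic). Ternary proportions are
computed from these processed (doubled) values; a joint is classed
sagittal-dominant when sagittal/(sagittal+lateral) strictly exceeds 0.5,
with the exact tie assigned to the lateral class, and the `dominant` field
records the largest of the three shares. Regions split anterior/posterior
at the diaphragmatic joint for mammals (inclusive on the anterior side) and
at floor(n/2) otherwise. Craniocaudal profiles are least-squares
polynomials (default degree 3, reduced with a warning when
under-determined) reported alongside the raw points.

## Permutation MANOVA

Model terms enter sequentially (type-I) in formula order; nesting is
written `Group/Species` (= `Group + Group:Species`), crossing `*`. Each
term's statistic is the trace of its incremental SSCP (equivalently the
squared Frobenius norm of the response projected onto the term's
incremental orthonormal basis), R² is that trace over the total centred
SSCP trace, and the pseudo-F uses the full-model residual mean square. For
each term, the residuals of the reduced model (all earlier terms) are
permuted as whole rows, added back to the reduced-model fit, and F
recomputed; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) with 10 000
permutations by default and a mandatory recorded seed. Exact equivalence to
any particular published implementation of the statistic is not claimed;
the estimator is validated distributionally (type-I error within
[0.03, 0.07] at α = 0.05 and uniform null p-values over 500 replicates,
power ≥ 95% against a 2-SD shift) and, with a single response, reduces
exactly to sequential univariate ANOVA.

## The synthetic generator

Vertebrae are unions of closed primitives so every landmark and contact
angle has a closed form: a revolved centrum (spherically dished endplates,
dimple depth 10% of the radius; optionally a procoelous condyle cap with
emitted sphere-fit sample points), a box neural arch whose roof clears the
zygapophyseal plates (so truncating a spine "just above the arch" never
touches the facets), a box neural spine, and one rectangular facet plate
pair per side whose orientation interpolates from horizontal (0°, normal
dorsal — the "open" pre-diaphragmatic articulation) to parasagittal (90°).
Facing facets at a joint are congruent: a vertebra's postzygapophyses take
the *next* vertebra's facet angle. The pre/post plates of a pair are
staggered craniocaudally (default 1.5 mm) so capsule locator pairs have a
finite neutral length, and separated by an articular clearance
(default 1.1 mm) along the facet normal.

Default dimensions (mm): centrum radius 6, length 14, joint gap 2, facet
plates 8 x 5 x 2.5 centred 9 above and 5.5 lateral of the centrum axis.
These proportions were chosen so that the three constraint families
interact the way they do in real columns at this scale: discs limit bending
at roughly `gap / (2 x rim distance)` radians per direction, capsules
engage slightly later, and facet contact is the discriminating constraint
whose onset angle depends strongly on facet orientation (twist presses
near-vertical facets together almost immediately, slides horizontal ones
freely). Endplate ellipticity (`endplate_aspect`, mediolateral half-width
over dorsoventral half-height) shifts the disc-limited lateral/sagittal
balance: wide-flat centra favour sagittal bending, tall-narrow centra
lateroflexion.

Presets encode comparative morphologies: `mammal_like` (steep sigmoid
facet-angle switch at the diaphragmatic position, wide-flat centra),
`reptile_like` (uniform 70° oblique facets, tall-narrow centra),
`cynodont_like` (horizontal anterior facets, reduced posterior spacing),
`sailback` (mid-column spines elongated 15-fold), and `tuatara_like`
(45° facets, roomier joints, and a ventral intercentrum at every joint).
The intercentrum is a ventral block spanning nearly the whole
intervertebral gap (0.25 mm clearance to the posterior endplate at optimal
spacing) and most of the ventral endplate breadth; merged with the anterior
vertebra it arrests ventroflexion by bony contact well before the disc
limit while staying clear of lateral bending. At the reduced spacing
variant the clearance shrinks to 0.05 mm — still admissible at neutral, but
users modelling tighter columns should scale the clearance with the gap.

Generation is deterministic; optional landmark noise is the only stochastic
element and sits behind a single seed.

### What the generator does and does not emulate

It reproduces the *mechanistic ingredients* of real columns — articulating
facets with controllable orientation, compressible/stretchable soft-tissue
spans, near-contact bony structures — with exact, analytically known
geometry. It does not attempt realistic vertebral shapes: no transverse
processes or ribs, no curved facet surfaces, no metapophyses, no
craniocaudal size gradients. Passing tests therefore demonstrate that the
pipeline measures what the geometry dictates (and that the documented
morphology-function links emerge from contact mechanics alone); they do not
calibrate absolute ROM magnitudes for any real taxon, and the engine's
outputs are intended to be read comparatively in exactly the same way.

## Numerical choices and limitations

* Violation is strict (`>` threshold), making step-quantized oracles exact.
* Overlap volumes are midpoint-rule estimates: accuracy is one cell layer
  at the contact interface, with the exact narrow phase guaranteeing
  detection; two geometrically identical joints at different absolute
  positions can disagree by about one step when a constraint crossing is
  marginal (the lattice phase differs). Bilateral symmetry and paired-arm
  identity are exact by construction.
* Edge-edge penetrations that carry no vertex of either mesh inside the
  other and accumulate less than one cell of volume can escape the
  zero-threshold contact test; all fixtures and typical articulations
  present vertex-first contacts.
* The 90° cap applies to every direction; capped sweeps report "cap" as
  their limiting constraint.
* Problem sizes in the test-suite and acceptance script (columns of 2-6
  vertebrae, 500 MANOVA calibration replicates at 999 permutations) were
  chosen as the smallest sizes at which every qualitative contrast is
  expressed with comfortable margins.
* Stiffness is relative; no material properties, muscles or ligament
  pre-tension are modelled, and epaxial musculature / interspinous
  ligaments are explicitly out of scope.
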