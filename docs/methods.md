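# Methods

## Model and assumptions

The collision-free space of a C-arm linac is modelled as a cylinder about
the gantry rotation axis through the plan isocenter: radius
`clearance_radius_mm` (*r*, isocenter to collimator front cover), length
`head_length_mm` (*L*, superior–inferior head extent). The model assumes:

- the head front is flat: protrusions (accessory mounts, trays) are absorbed
  by choosing *r* as the smallest clearance circle, which is conservative
  for the cylinder but ignores per-component detail;
- the couch is rigidly couch-mounted, so body and couch contours rotate
  together with the couch angle;
- static geometry only — no gantry/couch trajectory timing, gantry sag,
  imager arms or respiratory motion.

Coordinates: right-handed patient frame for a head-first supine patient
(lateral = patient left +, vertical = anterior +, longitudinal = superior +),
origin at the plan isocenter. The room frame shares the vertical axis;
the couch rotation by θ maps (lateral, longitudinal) through
`[[cos θ, sin θ], [−sin θ, cos θ]]`, i.e. positive θ swings the patient's
superior end toward the patient's left. All interface angles are degrees.
The gantry/polar angle of a room point is `atan2(lateral, vertical)` in
(−180°, 180°], so 0° is beam-from-above and −90° displays as IEC 270°.

### Slice ellipses and the offset sign

A transverse slice at signed distance Δz from the isocenter slice cuts the
cylinder in an ellipse with a = r/cos θ, b = r, center offset
d = −Δz·tan θ. The sign of d is forced by the rotation convention above
(it is the unique choice for which every safe-space contour vertex sits at
radial distance r from the gantry axis in the room frame); the magnitude
|Δz|·tan θ is the familiar textbook form and can be restored with the
`abs_offset` switch (`--abs-offset` on the CLI), which is intended only for
comparing against magnitude-only contour exports.

### Longitudinal coverage window

Collisions are only possible where the head overlaps the patient
longitudinally. A point is inside the window when its room-frame
longitudinal coordinate u satisfies |u − offset| ≤ L/2; for slice planes
this reduces to |z − z_iso| ≤ (L/2)·cos θ. The window is symmetric about
the isocenter plane by default (the head is not, in general; the
`window_offset_mm` parameter shifts it for asymmetric heads). The safety
margin reduces only the radius, never the window.

## Detection

Contour vertices are tested after subdividing polygon edges to ≤ 5 mm
(`max_edge_mm`). In-plane the subdivision is redundant — the cylinder
section is convex and the radial projection of a segment is maximised at an
endpoint — but it matters at the window boundary under couch rotation,
where an edge can cross into the window between two excluded vertices
(covered by a dedicated test). Interior points of polygons never need
testing for the same convexity reason.

A point with ρ > r_eff = r − margin (strictly; the closed boundary is safe,
its collision arc being empty) collides for gantry angles within
φ = arccos(r_eff/ρ) of its polar angle. Two interval rules:

- `union` (default): merge every point's arc. This is exact under the
  cylinder model and is verified against brute-force enumeration
  (`oracle_collision_set`: grid angle g collides iff
  ρ·cos Δ(polar, g) > r_eff for some point) on 0.1° grids.
- `max_point`: cluster points into regions (single linkage, joined within
  5° polar and 10 mm longitudinal — the gaps are a design choice, as
  "region" has no canonical definition) and take one arc per region
  centered on its deepest point. This classical rule can under-cover a
  region whose moderately deep points are widely separated; a test
  demonstrates the under-coverage and that the rule is always a subset of
  the union rule.

Planned arcs are stored directed (start → stop in increasing-angle
direction; loaders swap endpoints for decreasing sweeps) but overlap
testing is direction-independent, since a collision anywhere on the swept
arc is a collision. Exit codes gate automation: 0 safe, 2 collision
predicted, 1 error.

## Synthetic phantoms and study conditions

Phantoms are analytic (ellipse torso, twin-circle legs, torso with arm
lobes, rectangular couch slabs with optional prone plate), so every
expected violation has closed-form ground truth. They emulate gross
clearance geometry only — no anatomy detail, no immobilization devices, no
partial CT coverage — so passing tests show the *detector* is correct, not
that any specific clinic's setups are safe.

The scenario suite fixes r = 400 mm, L = 600 mm (typical C-arm values;
real deployments must measure their own — there are no package defaults)
and builds five situations: a safe centered pelvic setup (deepest point
302 mm), a prone-plate couch with high isocenter (couch corner 455 mm), an
abducted-leg setup (body point 540 mm), a laterally offset isocenter
(couch corner 439 mm), and a couch-30° noncoplanar setup whose superior
couch end swings to 427 mm inside the head window. Verdicts therefore
carry ≥ 20 mm slack relative to r and are stable under margins up to
10 mm and vertex jitter ≤ 1 mm; the safe scenario intentionally flips red
at large margins, exercising the false-positive mechanism.

Desk-scale validation cases (`validation_cases`) randomize couch half-width
(230–300 mm), couch top height (−330 to −140 mm), lateral offset (±90 mm)
and torso semi-axes, placing the deepest point across the clearance
boundary. "Measured" ground truth — standing in for a physical clearance
run on the machine, which is not reproducible at a desk — is the
zero-margin verdict on the same geometry under a rigid setup-error shift
(normal, σ = 5 mm per axis, clipped to ±15 mm). Because the shift is
bounded by 15 mm, margins ≥ 15 mm provably eliminate false negatives, and
per-case calculated verdicts are monotone in margin, which yields the
FN-nonincreasing / FP-nondecreasing / NPV-nondecreasing sweep behaviour
the tests assert. The default sweep uses 200 cases at 20 mm slice spacing
over margins {0, 10, 30, 50} mm; the slice spacing and case count were
chosen to keep the geometry representative while each case stays cheap.

## Numerical choices

- ROISS ellipses are sampled uniformly in parametric angle with 180
  vertices (2° steps, matching typical TPS contour density); the polygon
  area deficit versus πab is < 0.1%.
- Circular arcs are normalized to (−180°, 180°] endpoints; unions are
  computed by unrolling to the line, linear merging, and iterative
  wrap-around merging; a covering union collapses to the explicit
  full-circle interval (width 360°, kept representable distinctly from the
  empty case).
- Confusion statistics round half-up to one decimal (`decimal` module),
  matching the conventional reporting precision; accuracy requires ≥ 1
  case and NPV ≥ 1 negative prediction, otherwise an
  `UndefinedStatisticError` is raised.
- Collision-angle agreement pairs intervals by sorted start angle and
  compares endpoints circularly; the enumeration reference quantizes
  endpoints to its grid step, so agreement is bounded by that step
  (0.1° in tests).
- Degenerate inputs fail loudly: non-finite coordinates, |couch| ≥ 90°,
  margin ≥ r, empty bodies after thresholding, zero-area polygons and
  unsorted slice stacks all raise typed errors.

## File formats

DICOM RTSTRUCT is the contour interchange format (explicitly closed planar
contours, DICOM patient axes x = lateral, y = −vertical, z = longitudinal
for head-first supine); round trips preserve names, order and coordinates
to 10⁻³ mm. Plans are plain YAML/JSON (isocenter plus per-field couch
angle and gantry arc); a thin adapter reads the equivalent subset from
DICOM RTPLAN. CT-like density grids (g/cm³) are accepted as NPZ containers;
the body is auto-contoured at the conventional 0.6 g/cm³ air/tissue
threshold via marching squares, keeping the largest component per slice
plus components above a configurable area floor.

## Known limitations

- A single cylinder cannot represent per-component head protrusions;
  modelling them as separate clearance cylinders is deliberately out of
  scope.
- Collisions with anatomy outside the scanned CT range are invisible to
  any CT-based check; the couch model can be extended longitudinally via
  its `z_range_mm`, but the body cannot.
- The max-point rule is retained for comparison with the classical
  formulation; the union rule should be preferred in use.
- Multi-isocenter plans, dynamic trajectories and HU-to-density
  calibration are out of scope.
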