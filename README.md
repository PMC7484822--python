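# linacclear

Patient-specific gantry-collision prediction for C-arm linear-accelerator
radiotherapy plans, at treatment-planning time.

Collisions between the rotating gantry and the patient or couch are a real
hazard for modern plans — especially noncoplanar plans that rotate the
treatment couch — and are usually caught only in the treatment room, after
planning effort has been spent. `linacclear` predicts them from the planning
geometry alone, so an unsafe isocenter or couch angle can be fixed before a
plan ever reaches the machine.

## The model

As the gantry rotates about the isocenter, the collimator front cover sweeps
a circle of radius *r* (the isocenter-to-cover clearance distance). Sweeping
that circle along the gantry rotation axis over the treatment head's
superior–inferior extent *L* gives a **collision-free cylinder**: anything
inside it clears the head at every gantry angle; anything outside collides
for some arc of gantry angles.

Cutting the cylinder with a transverse CT slice at couch angle *θ* gives an
ellipse with semi-axes

- *a* = *r* / cos *θ* (lateral), *b* = *r* (vertical),

whose center is offset laterally by *d* = −(*z* − *z*₀) · tan *θ* on a slice
at distance *z* − *z*₀ from the isocenter slice. These per-slice contours are
exported as a planning-system ROI — the **safe-space ROI (ROISS)** — so the
clearance boundary can be inspected fused with the anatomy, and are colored
green (clear) or red (collision) after checking.

A contour point at radial distance ρ > *r* from the gantry axis is struck by
the head for gantry angles within the half-angle

- *φ* = arccos(*r* / ρ)

of the point's polar angle. A user-supplied **safety margin** shrinks *r*
before detection to absorb setup error and modelling simplifications. The
collision arcs of all violating body/couch points are merged (or, with the
classical `max-point` rule, one arc per violating region centered on its
deepest point) and intersected with each field's planned gantry arc; any
overlap flags the plan as unsafe.

Validation against ground truth uses confusion counts — accuracy
(TP + TN)/total and negative predictive value NPV = TN/(TN + FN) — swept over
safety margins: larger margins turn false negatives (undetected collisions,
the dangerous kind) into true positives at the cost of false positives.

## Worked example

The package ships analytic phantom scenarios. This one places the isocenter
140 mm toward the patient's right in an abdominal setup, which swings the
far couch edge outside the clearance cylinder:

```sh
linacclear phantom --scenario lateral_iso_offset --out-dir fx
linacclear check --machine fx/machine.yaml --plan fx/plan.yaml \
    --structures fx/structures.dcm --margin-mm 30
```

prints

```json
{
  "calculated_collision": true,
  "fields": [
    {
      "collision_intervals_deg": [[77.036065, 145.378196]],
      "couch_angle_deg": 0.0,
      "name": "arc1",
      "overlap": true,
      "planned_arc_deg": [-180.0, 180.0],
      "state": "red",
      "violating_structures": ["COUCH"]
    }
  ],
  "margin_mm": 30.0,
  "method": "union"
}
```

and exits with status 2 (collision predicted; 0 = safe, 1 = error). Reading:
with a 30 mm safety margin, couch points leave the effective cylinder and
the gantry would strike the couch anywhere between gantry angles 77° and
145° (0° = beam from above, positive toward patient left, −90° ≡ IEC 270°);
since the plan sweeps a full arc, the field is red.

Other subcommands: `roiss` writes the color-coded safe-space ROI as DICOM
RTSTRUCT, `map` writes the couch-angle × gantry-angle collision chart as a
0/1 CSV grid, and `sweep` writes a margin-sweep confusion table (margin,
TP|TN|FP|FN, accuracy %, NPV %) as CSV. The same functionality is available
as a library (`linacclear.check_plan`, `linacclear.build_roiss`, ...).

Machine geometry (`clearance_radius_mm`, `head_length_mm`) is deliberately a
required input with no defaults — these are machine-specific measured
quantities. The bundled scenarios use r = 400 mm, L = 600 mm.

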