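# stapplan

Pre-operative planning of a **retrofacial drilling corridor to the stapedius
muscle (SM)** from 3D surface reconstructions of the middle ear.

During cochlear implantation, direct visualization or EMG recording of the
stapedius reflex requires safe access to the SM — the smallest muscle of the
human body (belly length 2–4 mm) — which lies medial ("behind") the mastoid
segment of the facial nerve (FN). `stapplan` takes the segmented surfaces of
the SM, FN, sigmoid sinus (SS), vestibulocochlear system (VC) and temporal
bone (TB) as STL files (RAS coordinates, millimetres), evaluates every
candidate linear drilling trajectory over a grid of head orientations, and
returns the optimal trajectory, a clearance-certified truncated-cone
surgical corridor, and a quantitative guidelines report. It is written for
otosurgeons' planning workflows and for researchers studying minimally
invasive temporal-bone access.

## Method

For each orientation (roll ∈ [−30°, +30°] about the anterior–posterior
axis, yaw ∈ [−40°, +20°] about the inferior–superior axis, 2° steps —
a 31 × 31 = 961 grid), the scene is rotated about the SM centroid and
projected orthographically into the surgeon's view. Seven polygons are
built: the projected SM, and the proximal/distal parts of FN, SS and VC
(split at the depth of the most lateral SM point). From these, the exposed
SM, the exposure ratio ASM, and the *drillable* region — the exposed SM
minus every proximal obstacle dilated by the **minimum safety distance**

    MSD = r_drill + ε        (default 0.6 mm + 0.2 mm = 0.8 mm)

are computed. The drilling target is the centroid of the drillable region.
Each feasible orientation *i* receives the safety measure

    S(i) = α·ASM(i)/max ASM + β·DFN(i)/max DFN + γ·DSS(i)/max DSS
         + δ·DVC(i)/max DVC − θ·|Roll(i)|/max |Roll|

with weights (α, β, γ, δ, θ) = (0.6, 0.6, 0.6, 0.3, 1.2), where DFN/DSS/DVC
are the distances from the exposed SM to each proximal structure. Along the
best trajectory a truncated cone (small base = drill tip on the target) is
grown to the largest half-angle whose lateral surface keeps the MSD from
FN, SS and VC in full 3D. An access is classified **easy** when the exposed
SM is > 40 % (difficult when > 25 %), the SM–FN distance > 0.8 mm and the
corridor diameter at the skull > 3 mm; otherwise it is unfeasible.

A first-class synthetic-anatomy generator (`stapplan.phantom`) builds
parametric middle-ear phantoms with closed-form ground truth, so the whole
pipeline is testable without patient data.

## Worked example

Generate a feasible phantom and plan it from the reference view:

```sh
stapplan phantom unobstructed --out-dir ph
cat > cfg.yaml <<EOF
roll_range_deg: [0, 0]
yaw_range_deg: [0, 0]
EOF
stapplan plan ph/manifest.yaml --config cfg.yaml --out-dir plan
stapplan report plan/report.json
```

prints

```
Predicted feasibility              Y
Difficulty                         easy
Side                               right
Exposed SM area [%]                100.00
SM thickness at target [mm]        0.90
Distance SM-FN [mm]                2.00
Distance SM-SS [mm]                4.50
Distance SM-VC [mm]                3.50
Depth of SM behind FN [mm]         1.70
Feasible roll range [deg]          (0.0, 0.0)
Feasible yaw range [deg]           (0.0, 0.0)
Optimal (roll; yaw) [deg]          (0.0, 0.0)
Corridor diameter at mastoid [mm]  8.50
TB-to-target depth [mm]            11.55
```

The SM is fully exposed in this phantom; its belly (0.9 mm thick at the
target) lies 1.7 mm behind the facial nerve, 2.0 mm from it in the view
plane, and the maximal safe corridor opens to 8.5 mm at the mastoid surface
over an 11.55 mm drilling depth — an easy access. `plan/` also contains the
corridor STL (overlayable in any 3D viewer), the per-orientation grid CSV,
the color-coded skull map (PNG + PLY) and a run manifest. Dropping the
`--config` restriction evaluates the full 961-orientation grid.

`stapplan plan` exits 0 for a feasible case, 2 for an evaluated-but-
unfeasible case and 3 for input errors.

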