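# Methods

## Problem and measurement model

`faceswell` quantifies facial swelling in rodents from ordinary
photographs.  Swelling is read out as the facial area **S**: the area of
a polygon traced by an annotator around the outer edge of the face, with
the line through the two outer canthi serving as the upper segmentation
boundary.  Because photographs are taken free-hand, S is confounded by
three nuisance factors, each of which has a landmark proxy:

| nuisance | proxy | rationale |
|---|---|---|
| camera distance | **Le**, the inter-canthus distance | interocular width is fixed by the skull, so projected Le ∝ 1/Z |
| head rotation (yaw) | **H2 : H1** | frontal face ⇒ H1 = H2; a turned head shifts the nose tip laterally ⇒ H2 > H1 |
| head lift/lower (pitch) | **H1**, perpendicular nose-tip height | pitch compresses the face vertically while Le is unchanged |

H1 is the perpendicular distance from the nose tip to the canthus line
(not the image-vertical distance); the two coincide when the eye line is
level, and the perpendicular definition keeps H1 meaningful when the
whole image is rotated.  H2 ≥ H1 holds for every annotation because the
canthus midpoint lies on the canthus line.

S is computed by the exact shoelace formula on the annotated polygon —
the continuous limit of counting pixels inside the traced region —
orientation- and start-vertex-independent, and checked for simplicity.

## Calibration pipeline

Three multiplicative stages in a fixed order (distance → rotation →
tilt), each the identity at its reference condition:

1. `S_le = S · (Le_ref / Le)²` — area is quadratic in any linear
   magnification.  For a planar outline under an ideal pinhole this is
   projection-exact at any distance.
2. `S_rot = S_le · (H2 / H1)^γ` — a one-parameter power-law correction
   of the yaw signal; γ = 0 disables it (rotation then acts only as the
   frontal-face check H1 ≈ H2).
3. `S_final = S_rot · (H1_ref / H1_scaled)` with
   `H1_scaled = H1 · (Le_ref / Le)` — linear, because pitch compresses
   only the vertical image dimension; H1 is first rescaled to the
   reference distance so camera distance cannot leak back in.

Distance and tilt are multiplicative scalings and commute; the pipeline
still always applies the fixed order above.  `Le_ref` and `H1_ref`
default to cohort-wide medians (robust to outliers); mean and explicit
policies are available.

### The rotation exponent γ

γ is the one genuinely free parameter, and its calibrated value is less
obvious than the qualitative picture suggests.  The intuitive reading —
a turned head shows a smaller face at constant Le, so the correction
should *enlarge* the area (γ > 0) — implicitly assumes Le is unaffected
by yaw.  Under a rigid head that assumption fails: the projection of
*any* rigid outline and the projection of Le both contract by cos θ to
first order in yaw, so stage 1 already removes the yaw foreshortening —
and over-removes it, because it divides by cos²θ while the area lost
only cos θ.  Consequently:

* measured against the frontal area right after stage 2, the optimal
  exponent is ≈ −(d/p)² (nose drop d over nose protrusion p) — large
  and negative;
* measured end-to-end, the tilt stage re-applies a cos θ factor through
  the Le-rescaled H1, and the optimal exponent shrinks to
  ≈ −(d/p)²·p/(Z−p) — small and negative (≈ −0.09 for the default
  geometry).

`fit_rotation_exponent` estimates γ in closed form (log-linear least
squares) against synthetic ground truth, targeting either the
post-rotation or, via `tilt_factor`, the end-to-end area.  The
simulator's default `gamma_policy="fit"` uses the end-to-end fit,
computed deterministically from a ±12° noise-free yaw sweep of the
configured head geometry at the reference distance.  A fixed default of
γ = 1.0 (the intuitive reading) remains available and is the
`CalibrationConfig` default for user-supplied data.  The practical
effect of the rotation stage is small either way — the H2/H1 signal
carries little correctable information beyond what Le already captured,
which matches the observation that the distance calibration dominates.

## Synthetic ground truth

The generator is a landmark model, not a renderer: eyes at (±w/2, 0, 0),
nose tip at (0, d, −p), and an n-vertex ellipse (semi-axes a, b) in the
eye plane centred on the eye midpoint.  A swelling factor s multiplies
the outline *area* (semi-axes scale by √s) and leaves w, d, p unchanged
— swelling affects soft tissue, not the skull.  The head is posed by a
yaw rotation about the vertical axis through the eye midpoint, then a
pitch rotation about the eye line (so the eyes are fixed points of
pitch, making Le exactly pitch-invariant), then projected by an ideal
pinhole.  Landmark-placement error is i.i.d. Gaussian jitter per
coordinate.

Defaults, chosen once as plausible for an adult rat and a hand-held
telephoto capture (all documented, none fitted to data):

| parameter | default | unit | note |
|---|---|---|---|
| interocular width w | 30 | mm | fixed by skull |
| nose drop d | 35 | mm | eye line → nose tip, in-plane |
| nose protrusion p | 10 | mm | toward camera; 0 = planar head |
| outline semi-axes a, b | 30, 40 | mm | frontal face ellipse |
| outline vertices n | 36 | – | realistic manual annotation density |
| image | 3000 × 4000 | px | phone still |
| focal length f | 15000 | px | telephoto; 10 px/mm at Z_ref |
| reference distance Z_ref | 1500 | mm | weak-perspective regime (below) |
| distance noise σ_Z | 0.10 | log units | ±10% capture distance |
| pose noise σ | 5 | deg | yaw and pitch |
| landmark jitter | 3 | px | manual placement error |
| swelling s_max | 1.3 | – | model-arm plateau at day 7 |
| relief level / τ | 1.1 / 6 | – / days | treated-arm exponential decay |
| per-rat frailty SD | 0.05 | log units | multiplicative size variation |

**Why weak perspective.**  The linear-H1 tilt correction is exact under
orthographic projection; under perspective it carries a first-order bias
≈ d·sin φ / Z (the nose tip changes depth as the head pitches).  At
arm's-length range (Z ≈ 300 mm) this is ≈ 4% at 20° pitch; at the
default telephoto configuration (Z = 1500 mm at the same 10 px/mm image
scale) it is below 1%.  The defaults therefore emulate a telephoto
capture, the regime in which the method's linear corrections are
well-posed; close-range captures are a documented limitation, not a
supported regime.

**What the generator does not emulate:** the face outline is rigid and
planar, so yaw-dependent *shape* change of the visible face (cheek
occlusion, outline wrapping around the head), non-rigid tissue
deformation, lens distortion, lighting/blur-dependent annotation bias,
and correlated (rather than i.i.d.) landmark errors are all absent.
Passing tests therefore demonstrate that the pipeline recovers ground
truth under ideal projective geometry with unbiased annotation noise —
not that these residual effects are negligible in real photographs.

## Cohort simulation and statistics

Each rat × day draws its swelling factor from the arm trajectory times a
per-rat lognormal frailty, draws capture nuisance, generates landmarks,
measures and calibrates.  Randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (PCG64), so tables are
bit-reproducible given the seed and the generator algorithm; an
optional larger pre-dosing model arm mirrors pooled-then-regrouped
designs.

Statistics mirror standard small-cohort practice: per-group per-day
mean ± sample SD (n−1), one-way fixed-effects ANOVA across arms, and
two-sided two-sample t tests — pooled-variance Student by default, Welch
behind a flag — flagged at P < 0.05, with no multiplicity correction by
default (Holm available).  F and t are computed from the explicit
sums-of-squares / pooled-variance formulas; the unit tests cross-check
them against scipy.  Degenerate-input conventions: identical groups
give F = 0 (p = 1); zero within-group variance with distinct means gives
p = 0 with a degeneracy flag; the same conventions apply to the t test.
Repeat-capture variability is summarized as the per-rat coefficient of
variation at each calibration stage; the deviation report flags whether
the mean CV decreases monotonically along the pipeline.

## Numerical choices

* H2 is clamped to ≥ H1 (the inequality is a theorem; violations can
  only be float noise) and the rotation stage tolerates H2/H1 down to
  1 − 1e-9 before declaring a measurement invalid.
* H1 = 0 (nose annotated on the eye line) is a hard error — the pitch
  proxy is undefined — never a silent pass-through.
* Polygon simplicity and nose-tip containment are checked with shapely;
  containment allows the boundary with a 1e-9·√area tolerance.
* The γ fit falls back to its `default` argument when the bundle carries
  no rotation signal (Σ x² < 1e-24 in log space).
* CSV floats are written with shortest-round-trip `repr` and read back
  with round-trip precision, so write→read is exact and seeded runs are
  byte-identical.

## Problem sizes used in validation

The validation experiments run at sizes chosen to make their Monte-Carlo
margins comfortable: 9-point distance sweeps, 21-point pitch sweeps,
20 seeds × 200 repeat-captures for the progressive-CV experiment,
20 seeds for effect recovery, and 2000 single-day replicates for the
null-calibration check (each replicate a control-6 vs model-5 cohort at
day 7 only).

## Known limitations

* Close-range (strong-perspective) captures bias the tilt stage by
  ≈ d·sinφ/Z; correcting it would need a depth-aware model.
* The rotation correction assumes the yaw signal enters through a rigid
  nose offset; real faces change outline shape under yaw.
* References derived per-cohort (median policy) make calibrated areas
  comparable within, not across, cohorts unless explicit references are
  supplied.
* No attrition, dropout, or missing-photograph mechanism is modelled.
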