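# Methods

This note records the models implemented in `sinquad`, the parameter choices,
the scope of the synthetic generator, numerical decisions, and known
limitations.

## 1. Contour model

A contour is a closed polyline of `(x, y)` points in image coordinates with a
mathematical (y-up) orientation. On ingest:

- Orientation is normalized to counter-clockwise using the signed (shoelace)
  area; clockwise input is reversed in place, keeping the first point.
- The contour is resampled to uniform arc length with step
  `DEFAULT_STEP = 5.0` px. The number of samples is
  `n = round(perimeter / step)` and the first input point is kept as the
  first sample, so a feature placed at the start of the generated path is
  sampled exactly.

Each sample `u` gets a characteristic vector
`c(u) = [c_t, c_c, c_x, c_y]` over the sign alphabet `{+, −, 0, V}`:

- `c_x`, `c_y`: signs of the forward increments `Δx`, `Δy`, with a dead band
  `DEFAULT_TOL = 0.5` px treated as `0` (and `V` for a vertical step, i.e.
  `Δx = 0` with `Δy ≠ 0`).
- `c_t`: sign of the tangent-direction trend.
- `c_c`: convexity/curvature behaviour from the cross product of consecutive
  chords, with dead band `DEFAULT_CURV_TOL = 0.5` px².

## 2. Shape language

**Quadrants.** The increment-sign pair maps to a quadrant:
`(+,+) → 1`, `(−,+) → 2`, `(−,−) → 3`, `(+,−) → 4`. Axis-aligned increments
(one sign `0` or `V`) inherit the quadrant of the nearest preceding resolved
sample (look-behind), which makes the labelling causal and deterministic.

**Primitives.** Sixteen classes `p_ij`, `i ∈ {1..4}` the quadrant,
`j ∈ {1..4}` the curvature behaviour (straight, convex arc, concave arc,
variable curvature). `classify_primitive` is total over valid characteristic
vectors. Maximal same-class runs form primitives; runs shorter than one step
cannot occur after merging, and `merge_short_runs` prefers absorbing a short
run into a same-quadrant neighbour.

**Sinquads and switches.** Consecutive primitives in the same quadrant merge
into a sinquad (cyclic wrap-around included). The transition between
consecutive sinquads is a *switch* with token `f t b`: from-quadrant,
to-quadrant, and a convexity bit `b` (1 if the turn at the switch point is a
left turn by cross product, else 0). The cyclic sequence of switch tokens,
dot-joined, is the **key**, e.g. `341.411.121.231` for a circle.

**Anchoring and canonical form.** Switches are rotated to start after the
topmost-then-leftmost contour point, then the key is canonicalized by
rotating to the first token starting with `34` (or the lexicographically
minimal rotation if none). Keys are invariant under translation, uniform
scaling, and full rotation of the contour; a 90° rotation permutes the
quadrant digits.

**Chain property.** In a valid cyclic key each token's to-quadrant equals the
next token's from-quadrant, and the primitive lengths of a segmentation sum
to the number of samples (partition conservation). Both are tested.

## 3. Clinical key and routing

The full cyclic key describes the whole outline, but the clinically relevant
region is the anterior-inferior corner. The **clinical key** is the anchored
switch run starting at the first `3→4` switch and ending before the first
switch whose to-quadrant is 2 — i.e. the lower/anterior boundary up to where
the outline turns back over the top. This definition is purely syntactic and
therefore invariant to tilt and noise that do not change the switch sequence,
unlike a bounding-box midline rule (which misassigns switches when a deep
anterior hook stretches the box).

Routing: clinical keys in `{341.411, 341.430.341.411}` are **typical** and
proceed to the fuzzy stage; any other key (e.g. keys containing `140.411`
from an anterior notch, or extra repeated `430` groups) is **atypical** and
yields the final decision `serious` without a fuzzy stage.

## 4. Fuzzy stage

**Angle α** is the interior angle at the first `4→1` switch of the clinical
run, measured between the incoming and outgoing 5-px chords
(180° for straight continuation, small for a sharp osteophyte tip). The
angle β at the first `3→4` switch is reported for context.

**Membership functions.** Two trapezoids over α ∈ [0°, 180°]:

- syndesmophyte: `(0, 0, 90, 115.6)` — support width 115.6°;
- non-syndesmophyte: `(90, 115.6, 180, 180)` — support width 90°.

They are complementary: `μ_s(α) + μ_ns(α) = 1` exactly for all α, verified
to 1e−12 on a dense grid. The closed-form trapezoid area
(plateau + half shoulders) matches a 360 001-point Riemann sum to 1e−6
relative.

**Modifier areas and thresholds.** For support width `w = b − a` and hedge
exponent `n`, the modifier area is `w·n/4` for `n ≤ 2` and `w·(n−1)/n` for
`n ≥ 2` (continuous at `n = 2`). The linguistic thresholds are
`round_half_up(area(n)/100, 2)`:

- `not_member` from `n = 1`, `almost` from `n = 2`,
  `clearly = round_half_up(sqrt(almost))` (dilation hedge).
- width 115.6 → areas 28.9 / 57.8 → thresholds 0.29 / 0.58 / 0.76;
- width 90 → areas 22.5 / 45.0 → thresholds 0.23 / 0.45 / 0.67.

The printed areas are exact in IEEE double arithmetic (`115.6/4 == 28.9`
etc.), so they are compared with `==` in tests. Rounding is decimal
round-half-up (0.225 → 0.23), not banker's rounding.

**Decision.** Max membership wins (`syndesmophyte` vs `healthy`); an exact
tie (the crossover at α = 102.8°, where both memberships equal 0.5 in floats)
falls back to `healthy` with a `tie` flag. Class-specific membership
functions for classes `K0..K5` can be overridden from YAML; thresholds are
re-derived automatically from the configured support widths.

## 5. Synthetic generator

`generate_vertebra` builds a tilted (−20°), rounded, tapered quadrilateral by
turtle-style path construction at 0.5-px resolution:

- The **lesion corner** (anterior-inferior) is an explicit vertex between two
  straight 8-px flanks whose directions are `20° ± γ` before tilt, with
  `γ = (180° − α)/2`. The designed interior angle is
  `α(sev) = 156° − (156° − 65°)·sev/0.8` for severity `sev ∈ [0, 1]`.
  The path *starts* at the vertex, so resampling anchors a sample there and
  the measured α equals the designed α to ~1e−13.
- Edge directions before tilt: bottom 0°, right 96.5°, top 180°, left 266.7°
  (a slight taper); corners are circular arcs (`corner_radius`, default 12).
  Closure is solved linearly (2×2 system) for the bottom and right edge
  lengths; geometrically impossible parameter combinations raise
  `ValueError("invalid geometry")`.
- Severity > 0.35 adds an anterior **hook**: a concave dip (arc down to 270°,
  a straight cliff of `10 + 8·(sev − 0.35)/0.45` px, arcs back up) which
  inserts `430.341` into the clinical key → `341.430.341.411`.
- Severity > 0.8 adds an anterior **notch** on the right edge which inserts
  `140.411` → atypical → `serious`.
- **Noise**: smooth radial perturbation from Fourier modes k ∈ {1, 2, 3}
  with per-mode amplitude `noise_sd·sqrt(2/3)` and random phases
  (`numpy.random.default_rng(seed)`), applied from the centroid. All
  generated segment directions keep ≥ 12° margin from quadrant boundaries,
  which absorbs the 0.5-px sign-quantization band (±5.7° at 5-px chords) and
  typical noise jitter; at `noise_sd = 1.0` the full key is reproduced in
  ≥ 95/100 seeds (100/100 observed).

`generate_cohort(n_healthy, n_path)` draws pathological severities uniformly
from `severity_range` (default `(0.62, 0.8)`, keeping α ≤ 85.5°, i.e. ≥ 3°
inside the syndesmophyte plateau edge at 90° against noise) and healthy items
at severity 0 (α = 156°, deep in the non-syndesmophyte plateau). This makes
label/decision concordance a design property, which the acceptance suite
verifies on a 133/33 cohort.

`generate_primitive_fixture` produces an ideal open path for each of the 16
primitive classes; `generate_rosette` produces
`r(θ) = 80(1 − eps·cos 4θ)` (default `eps = 0.25`), whose four concave dips
exercise every switch family and encode to the twelve-token key quoted in the
README.

## 6. Numerical choices

- Step 5 px, sign tolerance 0.5 px, curvature tolerance 0.5 px²:
  the tolerances are half the generator's path resolution, so ideal fixtures
  are classified without ambiguity while small noise is absorbed.
- `round(perimeter/step)` sampling keeps spacing within 1% of the nominal
  step on smooth contours.
- Shoelace area for orientation; `numpy.lexsort` for the deterministic
  topmost-then-leftmost anchor.
- Threshold rounding via `decimal` with `ROUND_HALF_UP` on the shortest
  float repr, avoiding binary-float surprises in the published constants.
- Contour files are written with full `repr` precision so CSV/JSON round
  trips are bit-exact.

## 7. Limitations

- The classifier consumes extracted contours; segmentation of radiographs
  into vertebral outlines is out of scope (a basic binary-mask tracer via
  `skimage.measure.find_contours` is provided for convenience).
- The typical-key equivalence classes and the angle thresholds target the
  anterior-inferior corner of cervical vertebral bodies; other corners and
  other lesion types are not modelled (`lesion_corner` accepts only
  `"lower-anterior"`).
- The synthetic generator is a geometric idealization for validation, not a
  statistical shape model of real anatomy; concordance results on synthetic
  cohorts do not estimate clinical accuracy.
- Very coarse contours (perimeter ≲ 15 samples at the default step) give
  unstable keys; inputs with fewer than 3 points are rejected.
- Membership-function parameters for classes `K1..K5` default to the `K0`
  values; tuning per vertebral level requires user-supplied YAML.
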