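# Methods

## The scoring model

A Ruff Figural Fluency Test (RFFT) protocol is five sheets, each a 7 × 5
grid of 35 identical five-dot patterns.  Because a cell offers exactly
`C(5,2) = 10` straight dot-to-dot connections, the set of drawable
designs is the set of non-empty connection subsets: `2^10 − 1 = 1023`.
Each design is encoded as a 10-bit mask (the *design ID*), with bit *k*
for the connection of canonical index *k* (lexicographic order over dot
pairs).  Design equality is strict mask equality: rotations or
reflections of a connection set are different designs.  Scoring scans a
part's cells in drawing order: the first occurrence of a design ID is a
unique design, a repetition within the same part a perseverative error.
Repetition scope is within-part (the standard convention; a cross-part
mode exists behind a flag for sensitivity analyses).  Cells with red ink
that yields neither true connections nor violations are *unscorable* and
enter neither tally; they are reported separately.

## Recognition pipeline

Per scanned page:

1. **Red segmentation.**  Respondent ink is isolated in HSV space: hue
   within ±20° of pure red, saturation ≥ 0.35, value ≥ 0.25.  Black
   print fails the value floor, paper fails the saturation floor.  A
   conservative integer prefilter (max channel must be red, with the
   same floors) restricts the exact HSV test to candidate pixels, which
   keeps full-page segmentation fast without changing its result.
2. **Registration.**  Printed dots are detected as dark blobs of
   dot-like area (0.35–2.5 × the nominal dot area) and low eccentricity
   (≤ 0.92); this excludes the part-2 diamond distractors (smaller than
   dots) and the part-3 line distractors (elongated).  A similarity
   transform (translation, uniform scale, small rotation — flatbed scans
   of flat sheets need no shear) is fit by iterated
   nearest-neighbour matching and least squares.  Registration fails if
   fewer than 80% of the 175 expected dots match or the mean residual
   exceeds 2 px.
3. **Cell cropping.**  Red pixels are mapped through the inverse
   transform into the layout frame and partitioned by cell box; pixels
   outside every box are counted and dropped (the partition is exact:
   per-page red pixels = assigned + dropped).

Per cell, the five-task recognizer (thresholds in pixels at 300 dpi; all
scale linearly with dpi):

1. **Active dots** — ≥ 3 red pixels within the activation radius
   (dot radius + 4 px) of a dot center.
2. **Candidates** — all pairs of active dots.
3. **Pixel assignment** — each red pixel goes to the candidate segment
   nearest to it, if within the corridor half-width (dot radius + 3 px);
   distance ties (1e-6 px) go to the shorter segment, then the lower
   canonical index, so results are deterministic.
4. **Line compatibility** — pixel projections onto the segment are
   binned at 1 px; accept iff occupied bins ≥ 75% of the length and the
   longest empty run (ends included) ≤ 20%.  The 75/20 pair tolerates
   curved, hasty and slightly short strokes while rejecting partial
   marks; both are configurable.
5. **False-positive rejection** — an accepted candidate *i–k* passing
   within the activation radius of an interior active dot *j*, with
   *i–j* and *j–k* both accepted, is removed unless ≥ 10 of its pixels
   lie outside both short candidates' corridors.  Because pixel
   assignment is exclusive, such long candidates are usually starved at
   task 4 already; task 5 closes the remaining gap.

**Violations.**  A stroke whose ink extends more than 10 px (≈ 0.85 mm)
beyond a dot center along the stroke direction, within the corridor of
the infinite supporting line, breached the "connect the dots"
instruction.  Only pixels owned by the stroke or unassigned are
considered, so other strokes meeting at the same dot cannot fake an
overshoot.  Violating strokes are excluded from true connections by
default; `count_violations_as_designs` emulates raters who score them
liberally.  The default board geometry guarantees two properties that
make this sound: no dot lies near a non-incident connection segment
(interior clearance ≫ activation radius), and no stroke's continuation
beyond a dot is nearly collinear with another connection (minimum
continuation angle ≈ 64°).

## Board geometry

The commercial RFFT stimulus artwork is licensed and is not reproduced.
The packaged layout (`layouts/default_rfft.yaml`) is an 8.5 × 11 inch
page at 300 dpi with 450 × 400 px cells: parts 1–3 use a regular
pentagon (matching the published description), parts 4–5 use irregular
five-dot stand-ins chosen for healthy clearance.  All geometry — page,
grid, dot positions, dot radius, distractor shapes — loads from YAML, so
a licensed layout can be swapped in without code changes.  Distractor
geometry is likewise this package's choice: part-2 diamonds are small
filled rhombi between the dots, part-3 lines short black segments
joining no dots.

## Synthetic data generator

The renderer emulates the scans the pipeline is built for: black printed
geometry and red respondent strokes (RGB ≈ (205, 30, 40)) drawn as
soft-edged thick polylines/quadratic arcs.  The noise model covers the
hand-drawing artifacts reported for real protocols, with defaults chosen
as plausible magnitudes at 300 dpi (≈ 85 µm/px):

| parameter | default (moderate preset) | emulates |
|---|---|---|
| `jitter_sd_px` | 1 px | endpoint placement error |
| `curvature_amplitude_px` | 2 px | bowed, non-straight lines |
| `endpoint_shortfall_px` | 1 px | lines not fully reaching the dots |
| `stroke_width_px` | 3 px | a fine felt-tip pen |
| `overshoot_px` | 24 px (≈ 2 mm) | violation mode: crossing through dots |
| `color_noise_sd` | 6 (8-bit) | scanner channel noise |

Scripts fill cells in row-major order; fresh designs are drawn without
replacement within a part (respondents strive for novelty), repeats are
injected at a configurable perseveration rate, and whole cells can be
scripted as violations.  Renders are bit-deterministic given the seed.

What the generator does **not** emulate: paper texture, large rotations
or skew, pencil or non-red ink, strokes anchored away from dots,
cross-outs, and the unknown noise distribution of any real cohort — the
defaults are plausible, not fitted.  Passing round-trip tests therefore
demonstrates correctness of the algorithmic chain under controlled
conditions, not field performance on clinical scans.

## Agreement statistics

The paper-validation statistics are implemented directly:

* **ICC(A,1)** — two-way mixed model, absolute agreement, single
  measures (McGraw & Wong 1996), from the two-way ANOVA mean squares,
  with the standard F-based confidence interval and p-value.  Tests
  cross-check the estimate, CI and p against pingouin's independent
  implementation and against an element-wise sums-of-squares oracle.
* **Lin's CCC** (Lin 1989) with biased (1/n) moments and a Fisher-z
  confidence interval.
* **Bland–Altman** limits: mean difference ± 1.96 × sample SD (n−1);
  the sign convention (first minus second assessment) is recorded in the
  output rather than assumed by the reader.
* **Reconciliation** — a third rating is required when the first two
  raters differ by more than two points in any part or more than four in
  total; the final score averages the two most concordant raters
  (smallest absolute total difference; ties resolved in the order
  (1,2), (1,3), (2,3)).

Parameter-recovery tests for the ICC with k = 2 raters judge the mean of
replicate simulations against its standard error, because a single
simulated table is dominated by the one rater-pair draw regardless of
the number of subjects.

## Problem sizes and numerical choices

The validation suite uses: the exhaustive noise-free round trip over all
1023 designs (part 1; a 40-design sample in each other part), 1,000
random single cells for the moderate-noise robustness property
(≥ 99% exact recovery required), and 100 full synthetic protocols
(16 filled cells per part, 12% perseveration rate, 5% violation cells)
for the end-to-end study; the acceptance script runs the same study at
30 protocols.  These sizes give stable percentages while keeping the
suite comfortably runnable on a laptop.  Degenerate inputs are handled
explicitly: empty cells yield design 0 with no diagnostics; zero-variance
agreement inputs raise `UndefinedStatisticError` rather than returning
NaN; registration of a blank page raises `RegistrationError`.

## Known limitations

* Recognition assumes designs are drawn dot-to-dot; strokes anchored at
  arbitrary points, multi-color ink and stroke-order inference are out
  of scope.
* Parts 4–5 dot arrangements are stand-ins; scores on real sheets
  require a layout file matching the licensed artwork.
* The false-positive (task 5) thresholds are this package's definitions;
  the concrete criteria of the original software are not public.
* Whether violating cells should be wholly excluded from the unique
  count is a policy choice; the default excludes violating strokes, the
  liberal flag restores them.
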