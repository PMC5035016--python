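# ruffscore

Automated scoring of the **Ruff Figural Fluency Test (RFFT)** from color
scans of the paper protocol sheets.

The RFFT measures nonverbal fluency: in each of five one-minute parts the
respondent sees a sheet of 35 identical five-dot patterns (with printed
distractors — diamonds in part 2, lines in part 3) and draws as many
*unique designs* as possible by connecting dots with straight strokes.
Performance is the total number of unique designs across the five parts;
repeating a design within a part is a *perseverative error*.  Manual
scoring is slow and rater-dependent, which is a real burden in
population-scale cohort studies — the setting this package targets.

## How it works

Only 10 distinct connections exist between any two dots of a five-dot
pattern, so every non-empty design is one of the `2^10 − 1 = 1023`
subsets of those connections and can be encoded as a 10-bit **design
ID**.  For each cell the recognizer runs five tasks on the red
(respondent-ink) pixel mask:

1. **active dots** — dots touched by red ink;
2. **candidate connections** — all pairs of active dots;
3. **pixel assignment** — each red pixel is attributed to the nearest
   candidate segment within a corridor;
4. **line compatibility** — a candidate survives only if its pixels
   cover enough of the segment without large gaps;
5. **false-positive rejection** — a long candidate shadowing two
   accepted, nearly collinear short candidates is removed unless it has
   independent ink.

The surviving *true connections* form the cell's design ID.  Strokes that
overshoot straight through their endpoint dots ("crossed the dots") are
counted as procedure violations and excluded from the design.  Scores
follow the RFFT convention: first occurrence of a design ID in a part is
unique, repetitions are perseverative errors.

Around this core the package provides scan ingestion (HSV red-ink
segmentation, similarity-transform registration of the printed dot grid,
per-cell cropping), a synthetic protocol renderer with a hand-drawing
noise model that supplies pixel-perfect ground truth, and the agreement
statistics used to validate automated against human scoring: ICC(A,1)
(two-way, absolute agreement, single measures), Lin's concordance
correlation coefficient, Bland–Altman 95% limits of agreement
(mean difference ± 1.96 SD), and the two-rater/third-rater
reconciliation rule.

## Worked example

```python
import ruffscore as rs

layout = rs.load_layout()                      # packaged board geometry
script = rs.random_script(n_filled_cells_per_part=12,
                          perseveration_rate=0.2, seed=7)
rendered = rs.render_protocol(script, layout, rs.moderate_noise(seed=7))
result = rs.score_rendered(rendered, layout)   # full scan pipeline
truth = rs.score_design_lists(script.effective_designs(),
                              script.violation_counts())
print("recognized:", result.score.total_unique,
      result.score.total_perseverative, result.score.total_violations)
print("ground truth:", truth.total_unique,
      truth.total_perseverative, truth.total_violations)
```

prints

```
recognized: 50 10 0
ground truth: 50 10 0
```

i.e. across the five simulated pages (12 drawn cells per part, 20%
perseveration rate, moderate hand-drawing noise) the pipeline recovered
all 50 unique designs and all 10 perseverative errors scripted into the
render.

The same pipeline is available from the shell:

```bash
ruffscore simulate 10 --out scans/ --noise moderate --seed 1
ruffscore score scans/ --out scores.csv
ruffscore agree scores.csv scans/ground_truth_scores.csv --measure total_unique
```

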