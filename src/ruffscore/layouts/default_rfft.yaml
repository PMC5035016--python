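# Default RFFT board layout: 8.5 x 11 inch page at 300 dpi, 7 x 5 grid of
# 35 cells.  Dot positions are normalized to the unit cell square (origin
# top-left, x right, y down).  The commercial RFFT stimulus artwork is
# licensed and not reproduced; parts 1-3 use a regular pentagon per the
# published description, parts 4-5 use stand-in irregular five-dot
# variants.  Swap in a licensed layout by pointing --layout at a file of
# this same shape.
dpi: 300
page_width_px: 2550
page_height_px: 3300
grid:
  x0: 150
  y0: 300
  cell_width: 450
  cell_height: 400
dot_radius_px: 6
diamond_half_diag_px: 3.5
line_width_px: 2.0
parts:
  1:
    dots:
      - [0.5000, 0.1800]
      - [0.8043, 0.4011]
      - [0.6881, 0.7589]
      - [0.3119, 0.7589]
      - [0.1957, 0.4011]
  2:
    dots:
      - [0.5000, 0.1800]
      - [0.8043, 0.4011]
      - [0.6881, 0.7589]
      - [0.3119, 0.7589]
      - [0.1957, 0.4011]
    distractor_kind: diamonds
    distractors:     # (x, y) diamond centers between the dots
      - [0.5000, 0.5000]
      - [0.3500, 0.3200]
      - [0.6500, 0.3200]
  3:
    dots:
      - [0.5000, 0.1800]
      - [0.8043, 0.4011]
      - [0.6881, 0.7589]
      - [0.3119, 0.7589]
      - [0.1957, 0.4011]
    distractor_kind: lines
    distractors:     # (x1, y1, x2, y2) short segments joining no dots
      - [0.0600, 0.0800, 0.1800, 0.0500]
      - [0.8200, 0.9200, 0.9400, 0.8600]
      - [0.0500, 0.8800, 0.1600, 0.9400]
  4:
    dots:
      - [0.5000, 0.1400]
      - [0.8600, 0.4000]
      - [0.7200, 0.8400]
      - [0.2600, 0.8000]
      - [0.1800, 0.3600]
  5:
    dots:
      - [0.3000, 0.1600]
      - [0.8200, 0.2200]
      - [0.8800, 0.6600]
      - [0.5000, 0.8800]
      - [0.1400, 0.5800]
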