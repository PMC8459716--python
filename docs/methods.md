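# Methods

`segmaps` analyzes digitally drawn bodily findings in acute visceral
disease. Visceral disease refers signs — hyperalgesia, skin and muscle
resistance, vasomotor changes, sympathetic signs such as unilateral
mydriasis — into somatic territories sharing the diseased organ's segmental
innervation (Head/Mackenzie zones), and these signs tend to appear
**ipsilateral** to the organ (the Hansen–Schliack side rule: heart and
stomach left, liver/gallbladder right; lungs and kidneys are paired, so no
single side applies). Spontaneous visceral pain, by contrast, is a poorly
localized midline sensation. The package turns symptom drawings into
per-segment coverage statistics so these two claims become measurable.

## Segmental atlas

All statistics are computed against a schematic front/back body template in
which every body pixel carries exactly one of 33 segment labels (trigeminal
V1–V3, cervical C2–C8, thoracic T1–T12, lumbar L1–L5, sacral S1–S5,
coccygeal Cog1) and one subject-side label. The original drawing app's
template artwork is not published; since every downstream quantity depends
only on the label maps, the atlas is a parametric arrangement of
axis-aligned bands (head column with V1–C3; trunk column with C4–S5 in
cranio-caudal order, Cog1 dorsal only; arm rectangles carrying the C5–T1
dermatomes; leg rectangles carrying L2–S2). Pixels are labeled by their
center point in normalized coordinates, making the construction
deterministic and resolution consistent. Design choices worth noting:

* **Side convention.** "Left/right" always mean the subject's anatomical
  side. On the front view the subject's left is the image's right half; on
  the back view the sides coincide. Side labels are stored per pixel, so no
  later mirroring convention can corrupt lateralization statistics.
* **Minimum grid.** 66 rows × 20 columns guarantee ≥1 pixel row per band
  (39 vertical band units) and non-empty left/right halves; undersized
  requests fail naming the first unresolvable segment band.
* **Odd column counts** leave the exact midline column unlabeled so the
  side partition stays mirror-symmetric.
* **Sacral bands on the front view** are configurable
  (`sacral_on_front`); perineal representation on a flat template is
  ambiguous, and the default keeps S3–S5 on both views.
* Limb dermatome assignment (arms C5–T1, legs L2–S2) follows standard
  dermatome order; the default analysis resolution is 132 × 40 (≈3.4 pixel
  rows per band, 5756 body pixels over both views).

## Rasterization and superimposition

Drawings are closed polygons in normalized [0,1]² template coordinates.
Interiors are filled with the even-odd rule sampled at pixel centers
(`skimage.draw.polygon`) and clipped to the body mask; degenerate zero-area
polygons contribute nothing and raise a warning. Per patient, all
distributed signs are superimposed and binarized (pixel-wise OR): the
number of coinciding signs at a pixel is deliberately discarded, keeping
only bodily location. Spontaneous pain is processed identically but always
separately from the other signs. The interchange format carries closed
polygons only; an examiner's outline stroke is represented by its closure.

## Coverage statistics

For a binarized map, each segment's coverage is `100 · set pixels / total
pixels` of the segment, with front and back pooled into one denominator.
Segments under **5% coverage are excluded** — the study's guard against
marginal coverage from drawing imperfections. Surviving segments are split
at the midline and per-half coverages reported; the threshold is applied to
the full segment first (the inclusion rule precedes the left/right division;
the alternative order is exposed via the `threshold` argument applied to
`segment_coverage` of half maps if ever needed, but is not the default).
Comparisons use the exact fraction (`n_set/n_total >= threshold`) so the
boundary case (e.g. 10 of 200 pixels) is decided by integer arithmetic, not
floating-point noise.

Mean body maps divide the per-patient binary maps by the organ group size,
so `n ·  mean` is integer-valued. The mean number of signs per half segment
counts, per patient, each distributed sign whose own coverage passes the
segment threshold and touches that half. Lateralized findings (mydriasis,
glossy eye, eyelid separation, tense facial muscles, asymmetric posture,
reduced respiration) are counted by side with percent-ipsilateral rounded
to the nearest integer; paired organs and zero denominators give NA, never
0. Table percentages are printed to one decimal with ties rounded half away
from zero.

## Synthetic cohort generator

No patient-level data were deposited, so validation uses synthetic cohorts
whose generative parameters mirror the study's reported structure:

* **Cohort flow** (default n=208, exact apportionment): heart 62, lungs 18,
  stomach 10, liver/gallbladder 12, kidneys/ureters 8 (the 110 single-organ
  patients), plus 50 undiagnosed, 39 multi-organ, 9 other. The heart and
  liver group sizes are recoverable from the printed ipsilateral-mydriasis
  counts and percentages; the remaining splits are this package's choice
  summing to 110. Patients outside the five analyzable groups draw their
  findings from a hidden profile sampled uniformly among the five organs,
  so cohort-wide prevalences are unaffected by the selection strata.
* **Organ spans**: heart T3–T5 (left), stomach T2–T12 with maximum T6–T9
  (left), liver/gallbladder C3–C5 + T5–T10 with maximum T7–T8 (right),
  kidneys/ureters T6–L2, lungs V2–L2 (both paired, bilateral with
  probability 0.3, otherwise a uniformly drawn affected side).
* **Sign/symptom prevalences** reuse the cohort-wide marginals (e.g.
  superficial hyperalgesia 46/110, mydriasis 37/110, nausea 45/110) for
  every organ — a documented modeling convenience, as per-organ rates were
  not reported. The merged "glossy eye/wide eyelid" count is assigned to
  `glossy_eye`; `eyelid_separation`, `zoster`, `passive_movement_resistance`
  and `urinary_retention` default to prevalence 0.
* **Side rule**: each present sign lands on the ipsilateral half with
  probability 0.85 (between the observed 83% for heart mydriasis and 100%
  for liver), configurable per organ; mydriasis uses per-organ values
  (heart 0.83, liver 1.0, stomach 0.85).
* **Geometry**: a present sign draws, per view, one axis-aligned rectangle
  per contiguous stretch of its sampled segment run, anchored at the
  midline and covering a fraction of the half segment drawn from
  N(0.6, 0.15) clipped to [0.3, 0.95]. Runs always contain the span
  maximum and extend toward the span ends uniformly. Signs are drawn on
  **both** views, matching the pooled front+back coverage denominator.
  Spontaneous pain is a midline-straddling rectangle over the organ's pain
  segments (epigastric T5–T9 for lungs/stomach/liver, T3–T5 heart, T10–L2
  kidneys). Vertex jitter defaults to 0.5 px of the 132 × 40 reference
  grid.
* **Randomness**: one seed; per-patient substreams derived via
  `SeedSequence([seed, 1, i])`, so output is bit-identical across runs and
  insensitive to patient order.

What the generator does **not** emulate: correlated co-occurrence of
findings within patients (signs are independent Bernoulli draws, so the
synthetic "at least one sign/symptom" aggregates run higher than the
study's 76.4%/47.3%), free-hand drawing shapes, view-specific asymmetries,
multi-organ physiology, and demographic confounding. Passing recovery tests
therefore show that the *pipeline* measures what the generator encodes —
not that real drawings are rectangles.

## Validation strategy and problem sizes

* Worked examples recompute every printed percentage from the printed
  counts (frequency table and ipsilateral-mydriasis arithmetic).
* Coverage and superimposition are checked for exact equality against
  pure-Python counting oracles on random masks (100 masks / triples), with
  the 5% rule exercised exactly at the 10-of-200-pixel boundary on a
  195 × 40 grid where T5 has exactly 200 pixels.
* Parameter recovery: a 5000-patient default cohort recovers every
  configured prevalence and the heart side-rule probability within 3
  binomial standard errors; with zero jitter, 200-patient single-organ
  cohorts recover each organ's configured span exactly through the full
  rasterize→mean-map→5%-rule pipeline; pain maps stay side-symmetric
  (left/right mass ratio within [0.8, 1.25]) while pooled signs lateralize
  (ipsi:contra mass ratio > 2) for unpaired organs. These sizes keep the
  whole suite around ten seconds while leaving comfortable statistical
  margins.

## Known limitations

* The schematic atlas has no anatomical contours; absolute pixel masses are
  template-specific and only ratios/coverages are meaningful.
* Rasterization quantization at the default 132-row grid is ~±15% of a
  band for adversarial cut positions; coverage-sensitive conclusions should
  use finer grids (resolution consistency is verified at 1170→2340 rows).
* The study's per-patient means (1.80 signs, 0.77 symptoms per patient)
  depend on within-patient correlation that the independence model does not
  reproduce; they are not used as validation quantities.
* The abstract reports 81/110 (73.6%) with at least one segmental sign
  while the frequency table prints 84 (76.4%); both arithmetic identities
  are carried as separate worked examples without adjudication.
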