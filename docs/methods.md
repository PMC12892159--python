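# Methods

## The patterning statistic

The organ of Corti packs its outer hair cells (OHCs) into three ordered,
offset rows — locally a near-hexagonal mosaic. `cortiquant` quantifies how
crystalline that packing is with a nearest-neighbor angular statistic: for
every focal cell in a chosen row (row 2 for OHCs; the fourth /
second-most-lateral row for PROX1⁺ supporting-cell analyses), arms are
drawn to the centers of its k = 6 closest same-type cells. The direction
of each arm, measured counter-clockwise from a longitudinal reference
axis, is assigned to one of 16 radial sectors of 22.5°, numbered 1–16,
sector 1 starting at the axis. Accumulated over all focal cells of one
sample this gives a sector-occupancy profile (counts summing to
6 · n_focal; frequencies summing to 1).

A perfect offset-row lattice with row spacing d_r = d_c·√3/2 puts every
arm at 0°, 60°, 120°, 180°, 240° or 300°, i.e. all mass in sectors
{1, 3, 6, 9, 11, 14} at frequency 1/6 each. Disorder spreads mass into the
other sectors; the Shannon entropy of the frequency vector (base 2, with
0·log 0 := 0) summarizes this in one number, ranging from log₂6 ≈ 2.585
bits for the perfect lattice (6 occupied sectors) to 4 bits for a uniform
profile.

Conventions the field's figures leave implicit, fixed here:

* **Sectors are half-open**, [(s−1)·22.5°, s·22.5°), so every angle maps
  to exactly one sector; numbering runs counter-clockwise from the axis.
* **Reference axis.** `estimate_axis` returns the principal axis of the
  target-row coordinates (direction of maximal variance), reported mod
  180° in [0, 180). An estimated axis is inherently direction-ambiguous:
  flipping it by 180° permutes sectors by 8. For synthetic mosaics, whose
  longitudinal frame is known to be 0°, the pipelines therefore pass a
  *given* axis of 0° (`StarConfig(axis_mode="given")`); for digitized
  images the estimated axis makes profiles comparable across mounting
  orientations, at the cost of that mod-180 ambiguity near the boundary.
* **Neighbor candidates** default to the focal row's cell type plus
  ectopic cells. Ectopic cells are hair cells sitting out of place, and
  their intrusion into the row-1/row-2 neighborhoods is precisely the
  mutant phenotype the statistic should see; set
  `include_ectopic=False` or `candidate_types` to restrict.
* **Ties** in the neighbor search are broken by (distance, cell_id)
  ascending — deterministic and checkable against a brute-force scan.
  Generic real data has no exact ties.
* **Edges.** By default every focal cell with at least k candidates is
  included (matching how "a minimum of 10 focal cells per region per
  sample" is counted); `edge_policy="exclude_margin"` drops focal cells
  within `margin` µm of the bounding box, which is how the analytic
  lattice tests isolate interior cells.
* **Degenerate geometry** (coincident centroids) raises an error rather
  than being dropped silently: it indicates corrupted input.

## Group comparison

The unit of replication is the cochlea: one profile per sample. Per
sector, per-sample frequencies are compared between genotypes with a
two-sided two-sample t-test (Student by default; Welch by flag).
Significance stars follow the plotting convention * p < 0.05,
** p < 0.01 applied to the raw p (the per-sector asterisk convention of
the radar plots); Benjamini–Hochberg adjusted p across the 16 sectors is
always emitted alongside, as basic multiple-testing hygiene. Sectors where
both groups have zero variance leave t undefined; they are reported as
not significant with an explicit `degenerate` flag rather than dropped.

With n = 3 samples per group the t-test operates far from asymptopia; the
calibration suite therefore measures its actual behavior under the
generator: across 2000 null experiments the per-sector rejection rate at
α = 0.05 stays within 0.05 ± 0.02, and control-vs-knockout experiments
flag at least one sector in ≥ 80% of runs (in practice ~100%).

## Density

Density is defined exactly as digitized from an image: cells of a chosen
type divided by the length of the sensory epithelium in the field, × 100
(cells per 100 µm). The length is an input recorded per field (a helper
computes the longitudinal cell extent as a default when it was not
digitized). Hair-cell counts include ectopic cells by default
(`"OHC+ectopic"`), since mutant fields contain hair cells outside the
normal rows; the counting label is explicit in every output row.

Densities across a genotype × region design are compared with a
fixed-effects two-way ANOVA with interaction (type-II sums of squares;
identical to type I/III on balanced designs, which is what the simulated
cohorts produce) via statsmodels, plus Tukey's HSD computed over all
genotype × region cells — so the studentized-range family spans the whole
design — reported for genotype contrasts within each region. The tests
verify the F statistics against an explicit sums-of-squares oracle on all
balanced designs up to 3 × 3 × 5. Note that Tukey's adjusted p uses the
pooled MSE across all cells; it dominates the *pooled-error* unadjusted p
for the same contrast, not a two-sample t-test computed from the two
cells alone (which has fewer error df). No mixed-effects or
repeated-measures structure is modeled.

## The synthetic epithelium generator

The generator exists so every downstream stage is testable without
imaging data. It emulates, not simulates: an offset-row lattice stands in
for the OHC (or supporting-cell) mosaic, with three independent
perturbations emulating the knockout phenotypes — Gaussian positional
jitter (disordered patterning), per-site missing cells, and ectopic hair
cells placed midway between row 1 and the pillar/IHC position (a partial
extra row on the medial side; an optional IHC row can be generated there
too). All randomness comes from numpy's PCG64 seeded explicitly per
operation, so identical configs are bit-identical.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_rows` × `cells_per_row` | 3 × 20 | OHC rows and cells per row |
| `col_spacing` d_c | 8 µm | within-row center spacing — a placeholder on the scale of an embryonic OHC apical surface; no measured inter-OHC spacing is imposed, set it from data when known |
| `row_spacing` d_r | d_c·√3/2 | chosen so the noiseless lattice has six equidistant neighbors |
| `row_offset_fraction` | 0.5 | alternate-row shift (near-hexagonal packing) |
| `jitter_sd` | 0 | isotropic positional noise, µm |
| `missing_rate`, `ectopic_rate` | 0 | per-site probabilities |

Presets: **control** (σ = 0.05·d_c, 1% missing, no ectopic) and
**etv_tko** (σ = 0.25·d_c, 5% missing, 10% ectopic). The knockout values
were calibrated once so that three samples per group produce a visibly
disrupted radar profile relative to control — a qualitative match to the
published contrast, not fitted numbers. Mean profile entropy rises from
≈ 3.2 bits (control preset) to ≈ 3.9 bits (knockout preset).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: cochlear curvature (fields are locally straight;
no curvature correction is applied), cell-size gradients along the spiral,
segmentation error structure, correlated (non-isotropic) displacement
from convergent-extension defects, and any biological mechanism of
patterning. Tests against the generator validate the *statistics*, not
the biology.

## Numerical choices

* Angles are computed with `atan2` and reduced mod 360; a guard maps the
  float artifact `x % 360 == 360.0` to 0. Binning uses
  `floor(angle / 22.5)`, so only arms lying exactly on a sector boundary
  are sensitive to rounding; the rigid-motion tests budget < 1% of arms
  for this and observe essentially none at generic rotations.
* Profile entropy uses base-2 logs on strictly positive frequencies.
* The k-NN search computes full distance matrices (fields hold at most a
  few hundred cells) and orders by `lexsort((cell_id, distance))`.
* Sub-seeds for cohorts and repeated experiments are drawn as integers
  below 2³¹ from a master PCG64 stream, so one `--seed` reproduces an
  entire run.

## Problem sizes

Simulated cohorts follow the study design: n = 3 cochleae per genotype
per region for patterning (the hair-cell density assay used n = 6; the
simulations here keep n = 3 throughout, which is the harder setting for
the t-test). Calibration runs use 2000 null experiments in the test
suite and 400 in the acceptance script, with 100 experiments for power;
fields of 3 × 20 cells keep each experiment a few milliseconds.

## Known limitations

* The sector numbering convention (where sector 1 starts, CCW direction)
  is this package's own; published radar plots do not anchor theirs, so
  sector-by-sector comparisons with published figures are up to rotation
  and reflection of the labels.
* The estimated axis is mod-180 ambiguous (see above); prefer a given
  axis whenever the image frame is known.
* Student's t on n = 3 frequency vectors is used because that is the
  stated analysis; the calibration suite shows it holds its size under
  the generator, but heavy-tailed real-data deviations are untested.
* No circular statistics (Rayleigh/Watson), Ripley's K, or Voronoi
  alternatives are provided; the sector statistic is the method under
  study.
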