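# ecmscreen

High-content quantification of extracellular matrix (ECM) stained *in situ*
with a fluorescent total-protein dye.

Cell-based fibrosis models deposit a mature ECM that can be decellularised,
fixed and stained in multi-well imaging plates. Two complementary endpoints
read that matrix out:

* **how much matrix accumulated** — total stain intensity above a fixed
  threshold, normalised to a viability signal (or, for the radiolabelled
  reference assay, ECM counts per minute normalised to cellular cpm), then
  summarised as dose-response curves and percent inhibition; and
* **how the matrix is organised** — a fibril *branch count*: a densely
  interconnected mesh of fine fibrils yields many branches, while a sparse
  matrix of thick, poorly connected fibrils yields few, even when the total
  amount of stain is unchanged.

`ecmscreen` implements both endpoints for screening laboratories working on
fibrosis and related matrix biology, together with the dose-response and
statistical machinery around them and a synthetic fibril-network generator
with exact ground-truth topology, so that every stage is testable without
microscope data.

## The branch-analysis pipeline

Four acquired fields per well (1104 × 1104 px each at 2 × 2 binning) are
tiled into one 2208 × 2208 well image, then:

1. **Adaptive segmentation** — pixel *p* is foreground iff
   `I(p) > localmean(p) + offset`, where the local mean is Gaussian-weighted
   over a 51 px window and the offset defaults to twice the robust
   (MAD-based) background sigma.
2. **Skeletonization** — the exact Euclidean distance-to-background field is
   computed and the foreground is reduced to a one-pixel-wide,
   topology-preserving centreline (one skeleton component per mask
   component; no 2 × 2 block).
3. **Marker regions** — skeleton pixels with ≥ 3 skeleton neighbours are
   junctions; the maximal skeleton paths between junctions/endpoints become
   markers.
4. **Flood fill from markers** — markers grow into the surrounding
   foreground on the original image, brightest pixels claimed first
   (deterministic tie-breaks), partitioning the foreground into candidate
   branches.
5. **Inclusion band** — a branch is retained iff its mean intensity lies in
   `[marker mean − 50, marker mean + 150]` native counts (bounds inclusive).
6. **Summary** — the per-well branch count and mean branch area.

## Quantitative endpoints

* `total_intensity_above_threshold`, `normalize_to_viability`,
  `normalize_radioactive`, `fold_change`
* `percent_inhibition` = `100 · (stim − value) / (stim − unstim)`, anchored
  at 0% on stimulated and 100% on unstimulated plate controls
* four-parameter logistic fits
  `y = bottom + (top − bottom) / (1 + (EC50/x)^hill)` with multi-start
  trust-region least squares; EC50/IC50 summarised across independent
  experiments as geometric mean with min, max and n
* ΔΔCt relative expression against the geometric mean of the housekeepers
  B2M, HMBS and TBP
* unpaired Student's t-test, one-way ANOVA, and Dunnett's many-to-one post
  hoc (seeded Monte-Carlo multivariate-t adjustment)

## Worked example

`examples/branch_analysis.py` draws a clean synthetic network whose true
topology is known exactly, then recovers it from the rendered image:

```text
ground-truth branches : 20
recovered branches    : 20
mean branch area      : 524.5 px^2
retained / total      : 20 / 20
```

The 20 ground-truth branches are the stretches of fibre between network
junctions and endpoints; the pipeline recovers every one from pixels alone,
and the inclusion band retains all of them because genuine branches share
their marker's intensity. `examples/phenotype_comparison.py` shows the
organisational readout at work — an altered matrix with a quarter of the
mesh fibrils at twice the width drops from a mean of 88.0 branches to 49.8
(t = 8.31, p = 8.7e-07) even though the amount of drawn signal is similar —
and `examples/dose_response_fit.py` fits three simulated titrations
(true EC50 = 15) and prints the cross-experiment summary:

```text
 Geometric mean  Min  Max  n
           15.9 15.5 16.7  3
```

A thin CLI wraps the same library for shell use:

```bash
ecmscreen simulate --outdir sim --seed 3 --n-wells 4
ecmscreen branches --images sim --plate-map sim/plate_map.csv --outdir out
ecmscreen fit --responses tidy.csv --outdir fits
```

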