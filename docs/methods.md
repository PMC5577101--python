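# Methods

This note documents the models, algorithms and design choices behind
`ecmscreen`, the parameters that matter, and what the synthetic validation
does and does not demonstrate about real microscope data.

## Image model and conventions

Images are single-plane unsigned-integer grayscale TIFFs at native camera
scale; nothing is rescaled on load because the branch inclusion band (below)
is defined in native counts. Arrays are indexed `(row, col)`, 0-based,
origin top-left. Four fields per well are tiled row-major by field index
(0 top-left … 3 bottom-right); the order is configurable because branch
counts are invariant to it but visual QC is not. 8-connectivity is used for
foreground and skeleton throughout; background connectivity for topology
checks is 4, the standard complementary pair.

## Branch analysis

**Adaptive segmentation.** Foreground iff
`I(p) > localmean(p) + offset`. The local mean is a separable Gaussian
weighting over a `window_px` window (default 51 px, sigma = window/6,
truncated at the window edge), with reflected borders. The offset defaults
to `max(2 × robust background sigma, 1)` counts, where the robust sigma is
1.4826 × MAD of the whole image — valid because fibril images are
background-dominated. The inequality is strict, so a perfectly flat image
segments to nothing. The rule is deliberately per-pixel and unsmoothed; it
is checked bit-for-bit against a brute-force per-pixel oracle in the tests.

**Skeletonization.** The distance field is the exact Euclidean distance to
background. The centreline comes from topology-preserving thinning followed
by a cleanup pass that removes residual 2 × 2 blocks by simple-point
deletion, retracting a simple endpoint arm pixel next to the block when no
block pixel is itself simple, with a final fallback that deletes a block
pixel only if the global component and hole counts are provably unchanged.
The contract is topological: one thin skeleton component per 8-connected
mask component, holes preserved. For unstructured noise masks a thin
topology-equivalent subset can fail to exist at all (an X-core whose four
arms each hang off one corner of a 2 × 2 block); such configurations do not
arise from the ribbon-like masks fibril segmentation produces, and the
contract is verified exhaustively over every connected 4 × 4 mask and over
smoothed-noise and fibril masks in the tests.

**Marker regions.** Skeleton pixels with ≥ 3 skeleton neighbours are
junction pixels. Thinning renders a fibre crossing as two nearby Y-junctions
connected by a micro-segment rather than a single X; to make one junction
region per crossing, every skeleton pixel within
`junction_merge_scale × distance(j) + 1` px of a raw junction pixel `j`
(default scale 1.5) is absorbed into the junction region — the inscribed
ball of the crossing, scaled. The remaining skeleton decomposes into
8-connected paths; paths shorter than `min_marker_px` (default 3) are
discarded as noise. Junction pixels belong to no marker; their eventual
branch assignment follows the flood-fill priority rule.

**Flood fill from markers.** Seeded region growing over foreground pixels
with priority by descending original-image intensity, implemented with an
explicit heap: equal-intensity claims go to the lowest marker label, then
first-queued, making the partition fully deterministic. Every foreground
pixel 8-connected to a marker is assigned to exactly one branch. Branches
smaller than `min_branch_px2` (default 5 px²) are discarded before
filtering.

**Inclusion band.** A branch is retained iff
`marker_mean − 50 ≤ branch_mean ≤ marker_mean + 150` (native counts, bounds
inclusive). We read the band as one asymmetric closed interval around the
marker mean; the offsets are configurable because the native scale of any
given camera export is assay-specific. Excluded branches are kept in the
audit table with `retained = False`.

**Summary.** `n_branches` counts retained branches; `mean_branch_area` is
the arithmetic mean of retained areas in px² (µm² when a pixel size is
set and undefined when no branch is retained).

## Synthetic fibril networks

The generator draws major fibres as quadratic Bézier curves spanning the
image and mesh fibrils connecting random points on pairs of majors, rendered
with Gaussian cross-sections (sigma = width, per fibre class) on a flat
background with additive Gaussian noise, combined by maximum so crossings
stay at the nominal ridge intensity. Ground truth is computed geometrically:
fibres are cut at every pairwise intersection (endpoint attachments snapped
within half a pixel), and a *branch* is an edge between consecutive nodes
along a fibre — the same operational definition the image analysis uses, so
recovery is well-posed.

Key defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| image_size | 512 px | desk-scale mosaic; the native 2208 px geometry is supported and exercised in the tiling tests |
| n_major / n_mesh | 4 / 40 | a dense control mesh; the altered phenotype uses ×0.25 mesh count and ×2 widths |
| fibre_intensity | 110 counts over background | the −50/+150-count inclusion band presumes low-contrast staining: with a Gaussian cross-section the grown branch mean sits ≈ 30–40% of the ridge amplitude below the marker mean, so amplitudes ≲ 130 counts are the regime in which genuine branches satisfy the band |
| background / noise | 100 / 6 counts | faint-stain background with SNR ≈ 18 |
| min_node_separation_px | 0 (off) | set to 40 px for "clean" validation networks, with crossings ≥ 25°, so each crossing is resolvable |

With `min_node_separation_px > 0` fibres are placed incrementally with
rejection until all network nodes are separated and crossings steep; all
draws come from one seeded generator, so identical spec + seed gives
bit-identical images and graphs.

**What the generator does not emulate:** optical point-spread, photon
(Poisson) noise, uneven illumination, fibre width variation along a fibre,
out-of-focus debris, and genuinely overlapping parallel fibres. Passing the
recovery tests therefore shows the pipeline implements its stated
definitions correctly and discriminates organisation phenotypes under
realistic contrast — not that counts on real plates are error-free. On
noisy synthetic wells the count inflates by roughly 10–25% (ragged masks
split extra path segments) while paired phenotype discrimination is
unaffected; absolute counts are most trustworthy on clean, well-separated
networks, and comparisons between conditions are the robust readout.

## Scalar endpoints

Total intensity sums pixels strictly above a fixed threshold; the
per-plate threshold default is background mode + 3 robust sigmas estimated
from unstimulated-control wells (the analysis that inspired it used an
instrument-configured fixed threshold whose value is not recoverable).
Viability and radioactivity normalisations are plain ratios with explicit
errors for non-positive denominators (dead or empty wells). Percent
inhibition is anchored at the plate's stimulated (0%) and unstimulated
(100%) control means and is affine-invariant by construction. ΔΔCt uses the
arithmetic mean of the housekeeper Cts as the reference — exactly equivalent
to normalising against the geometric mean of housekeeper expression on the
linear scale, since expression is `2^−Ct`. Both total and mean
above-threshold intensity are emitted; dose-response fitting uses the total
by default.

## Dose-response fitting

The four-parameter logistic
`y = bottom + (top − bottom)/(1 + (EC50/x)^hill)` is fitted by trust-region
least squares from a multi-start grid: 7 log-spaced EC50 starts spanning the
concentration range ×3 on either side, crossed with hill starts ±1 and
±2.5; EC50 is parameterised on the log scale. After fitting, orientation is
normalised to `top ≥ bottom` (declining curves carry hill < 0 — the two
parameterisations are exactly equivalent). Zero/vehicle concentrations are
excluded from the fit and serve only as the unstimulated anchor. Flat
responses return a degenerate `bottom == top` fit with `converged = False`
rather than raising, so plate-scale batch fitting never aborts. Optional
1/y² weighting is available; no weighting is the default. Cross-experiment
potency is summarised as geometric mean, min, max and n; EC50 units are
carried through from the input and never converted.

## Statistics

Student's t (pooled variance) and one-way ANOVA are computed from the
standard closed forms, with explicit degenerate handling for zero variance
(equal means → p = 1; unequal → p = 0, flagged). Dunnett's many-to-one
adjusted p-values are computed by Monte-Carlo integration of the null
multivariate-t of the comparison statistics: per-group normal draws are
generated group-by-group and the pooled-sd draws by inverse-CDF from a
separate stream, so adding a comparison group reuses identical draws for
existing ones and the family maximum — hence the adjusted p — can only
grow. Defaults: 100 000 draws (accuracy ≈ ±0.002 in p), seed in the call;
the adjusted p is clipped to be at least the raw p, and a family of one
returns the raw p exactly. The draw set is cached per design shape, so
simulation studies that call Dunnett repeatedly pay for it once. Against
`scipy.stats.dunnett` (deterministic integration) the Monte-Carlo values
agree to ≈ 0.005.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: every connected 4 × 4 mask
(37 196) for skeleton topology; 50 random 16 × 16 images against the
segmentation oracle; 20 clean 384 px networks plus the two-crossing-fibre
fixture for recovery; 12 phenotype pairs at 384 px; 100 seeded titrations
(8 concentrations × 4 replicates, cv 0.1) for EC50 recovery; 10 datasets ×
100 000 permutations for the t-test oracle; 2 000 null replicates for the
Dunnett family-wise error rate; and two full CLI runs hashed byte-for-byte.
These sizes keep the whole validation at desk scale while leaving every
stage exercised end-to-end.

## Known limitations

* The branch count is resolution- and parameter-dependent; only counts
  produced with identical parameters are comparable.
* Junction consolidation can merge genuinely distinct junctions closer than
  about the fibre width; dense real meshes will read lower than their true
  topological branch count.
* The inclusion band presumes the native count scale of the original
  acquisition; on bright high-contrast data the default offsets would
  exclude genuine branches and must be rescaled.
* Dunnett assumes homoscedastic normal groups (pooled variance); Welch's
  unequal-variance form is available only for the two-group t-test (the
  `welch` flag of `students_t`), not for the post hoc.
* No confidence intervals on EC50 (profile likelihood or bootstrap would be
  the natural extension).
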