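# Methods

This note documents the models, procedures and numerical choices behind
`astroquant`, and what the synthetic benchmarks do and do not establish.

## Scope

The toolkit reimplements the bespoke quantification steps of a typical
iPSC-astrocyte senescence study as testable, scriptable code: confocal
mitochondrial-network morphometry with a perinuclear-distribution ratio,
autophagosome–mitochondria area colocalization, halo-based senescent-cell
counting in tissue sections, generic immunofluorescence marker
quantification, Mito Stress Test parameterization of extracellular-flux
traces, the gene set score, 2^−ΔΔCt relative quantification, and a
normality-gated group-comparison ladder. Upstream acquisition
(microscopes, flux analyzers, qPCR machines) and downstream enrichment
analysis are out of scope; the package consumes calibrated TIFFs, tidy CSV
traces and Ct tables, and produces per-cell/per-well/per-sample tables.

## Image model and calibration

Images are channel × z × y × x grids with a physical pixel size
(µm/px). Coordinates are (y, x), 0-based; every micron quantity is
derived through the pixel size (areas scale with its square). Z-stacks
are always reduced by maximum-intensity projection before 2D analysis,
matching the standard confocal workflow. Cell perimeters use the
weighted boundary (crack-length) estimator of
`skimage.measure.regionprops`; no estimator is canonical for hand-drawn
outlines, so the choice is fixed and documented rather than configurable.

Nucleus segmentation is a pluggable one-function contract (2D image →
integer label grid) so a learned segmenter can be dropped in. The default
backend is classical: Gaussian smoothing (σ = 1 µm), global Otsu
threshold, hole filling, small-object removal, and a distance-transform
watershed with minimum peak separation of 3 µm to split touching nuclei.
Cell masks may be supplied externally (the original workflow drew them by
hand); labels must be disjoint.

## Mitochondrial morphometry

The MitoTracker channel is enhanced by rolling-ball background
subtraction (default radius 5 µm) followed by CLAHE (clip limit 0.01,
kernel ≈ image/8). Fibrillar structures are detected with a single-scale
Hessian tubeness (Sato) ridge filter; the default scale is half the
expected tubule width (0.5 µm width → 0.25 µm scale), the response is
binarized with Otsu's threshold, and connected components below 4 px are
discarded as speckle. The binary network is thinned to a 1-px skeleton.

Per cell (always restricted to the cell mask) the toolkit reports:

* `n_mitochondria` — connected skeleton components. The branch count
  (`n_branches`, skeleton segments between junction pixels) is reported
  alongside because "number of mitochondria" is ambiguous between
  components and branches in skeleton-analysis workflows; components are
  the default reading. Segment lengths are minimum-spanning-tree path
  lengths over 8-adjacent skeleton pixels (1 / √2 steps), exact for
  simple paths.
* `mito_area_um2` — area of the detected (pre-skeleton) binary mask.
* `density_count` and `density_area` — count per µm² of cell, and mask
  area as a fraction of cell area. Two distinct densities are reported
  explicitly because normalizing either count or area by cell size is
  common and they are not interchangeable.
* `mito_intensity` — integrated (summed) raw MitoTracker intensity over
  the cell, an integrated-density readout; it is the only metric that
  scales with global intensity rescaling.

### Perinuclear ratio

The perinuclear zone is the nucleus grown isotropically until its area
reaches 1.2× the nucleus area (the nucleus plus 20 % of its area),
implemented with the Euclidean distance transform so the realized area is
within one dilation step of the target; the zone is clipped to the cell.
The ratio is

    (skeleton pixels in zone∩cell / skeleton pixels in cell)
    ÷ (zone∩cell area / cell area)

A uniformly distributed network gives 1; perinuclear clustering gives
values above 1. Skeleton pixels are the default signal (the raw detection
mask is available via `ratio_source="mask"`); the ratio is reported
missing for cells without skeleton pixels.

## Colocalization

Autophagosome–mitochondria colocalization is the intersection area of
the two Otsu-binarized channels, per cell or per field normalized by cell
count — an area-overlap measure, matching the macro-style readout, not a
correlation. Pearson and Manders coefficients can be requested as extras
but are off by default. Line profiles sample channels bilinearly at a
fixed step (default 1 px) along a polyline, with distances in µm.

## Senescence counting

Nuclei are counted in the DAPI channel; a nucleus is marker-positive
(H2A.X) when its mean intensity exceeds Otsu's threshold computed over
the distribution of per-nucleus means (a fixed threshold can be given; a
contrast-free distribution yields no positives). For these small 1-D
samples the Otsu split is computed exactly over the sorted values, with
the threshold at the midpoint of the gap at the optimal split — a
histogram-binned Otsu can misplace the cut by a bin width when the
positive class is small and far from the background cluster, which
clips the tail of the background into the positive class. Each positive nucleus is
dilated by round(1.89 µm / pixel size) px (minimum 1 px, else an error
advising finer sampling); the halo is the dilation ring minus the
nucleus. A positive nucleus counts as an astrocyte when at least
`min_halo_frac` (default 0.05) of its halo pixels exceed the GFAP
channel's Otsu threshold — the original workflow gives no explicit
criterion for "positive labeling in the halo", so this fraction rule is
exposed in the API. Reported are `n_cells`, `pct_pos`, and
`pct_pos_astro` (= 100·n_pos_astro/n_pos, missing when there are no
positives).

## Extracellular flux

Mito Stress parameters follow the standard Agilent-style min/max/last
rules over the oligomycin → FCCP → rotenone/antimycin protocol: a
measurement belongs to the phase of the most recent injection strictly
before it; non-mitochondrial OCR is the post-rotenone/antimycin minimum;
basal is the last pre-oligomycin point minus non-mito; maximal the
post-FCCP maximum minus non-mito; ATP-linked the basal-point minus the
post-oligomycin minimum; proton leak the post-oligomycin minimum minus
non-mito. Spare, spare %, and coupling efficiency % follow by identity.
ECAR reports the pre-oligomycin level and its rise after oligomycin.
Whether a study uses last-point or phase-mean basal values is rarely
stated; both rules are implemented (`basal_rule="last"` default).
Negative spare capacity (no FCCP response) and non-positive basal are
reported with warnings rather than errors. Rates are normalized per cell
when a well's cell count is known; blank-well subtraction for uptake
assays floors negative consumption at zero with a warning.

## Expression statistics

* Gene set score: c_ij = e_ij − mean_j e_ij, S_j = mean_i c_ij. Scores
  sum to zero across samples by construction; this is verified to 1e−9
  and against an independent two-loop summation oracle.
* 2^−ΔΔCt: ΔCt = Ct_target − Ct_housekeeping per sample; ΔΔCt subtracts
  the arithmetic mean ΔCt of the reference group (per-sample pairing is a
  possible alternative nowhere specified; the arithmetic mean is the
  default and only rule). The reference group's folds then have geometric
  mean 1.
* Fold and percent changes are ratios/differences of group means with
  half-up decimal rounding, the rule consistent with conventionally
  reported values.
* `compare_groups`: Shapiro-Wilk per group at α = 0.05; all groups must
  pass for the parametric branch (per-group testing rather than pooled is
  a deliberate choice). Parametric: Student's t (2 groups) or one-way
  ANOVA with Tukey's HSD. Nonparametric: Mann-Whitney U or
  Kruskal-Wallis with Dunn's pairwise z-tests, Bonferroni-adjusted
  (the adjustment is our choice; unadjusted Dunn is not offered). Paired
  designs gate on the differences and use the paired t-test or Wilcoxon
  signed-rank. Groups below n = 3 force the nonparametric branch with a
  warning. Stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.

## Synthetic data

The generators provide ground-truthed stand-ins for data that cannot be
shipped:

* Fields are disk-shaped, non-overlapping cells with concentric disk
  nuclei. Mitochondrial filaments are random-walk curves (heading noise
  0.3 rad/step) stamped as binary masks of the configured width — no
  anti-aliasing, so truth areas are exact pixel counts. Perinuclear
  placement allocates round(p·n) filaments to the zone (p from
  `perinuclear_fraction`, or the zone's area share for uniform
  placement); walks are confined to their region eroded by the stamp
  radius and reflect at its boundary, keeping the realized pixel fraction
  within ±0.05 of the request. A positive `min_separation_um` (default
  1 µm) enforces non-touching filaments for exact count oracles; dense
  perinuclear studies set it to 0. Marker-positive nuclei, GFAP-filled
  cytoplasm and punctate channels (overlapping puncta are concentric, so
  the overlap fraction directly controls intersection area) cover the
  counting and colocalization stages. Noise is a single additive
  Gaussian model clipped at 0 — instruments' noise statistics are not
  published, so `noise_sd` is an explicit parameter, never hard-coded;
  z-stacks are replicated planes with independent noise, as the analysis
  only ever sees maximum projections.
* Flux traces are plateaus at the phase levels implied by the true
  parameters, three or more measurements per phase, 6.5 min apart, plus
  optional Gaussian noise. At zero noise the extractor round-trips the
  true parameters exactly.
* Expression matrices are baseline + additive group effect + noise.

What passing these benchmarks shows: the geometry, bookkeeping and
arithmetic of every stage are correct, thresholds behave sensibly on
bimodal intensity distributions, and recovery is unbiased under additive
noise. What they do not show: robustness to real-world confounds — uneven
illumination beyond a smooth background, out-of-focus light, densely
overlapping cells, irregular cell shapes, autofluorescence, drifting flux
baselines. The segmentation and threshold defaults will need tuning on
real material.

## Benchmark problem sizes

The shipped recovery studies use: 5 cells × 10 filaments (count/area
oracle, noiseless), 12 cells × 30 filaments per field for the
perinuclear-ratio calibration (uniform placement and four graded
fractions), ten 200-nucleus fields at 10 % signal noise for senescence
counting, 50 noisy traces for flux identities, and 2000 replicates of
n = 10 equal Normal groups for the type-I calibration of the statistics
ladder. These sizes keep each study's Monte-Carlo error well inside the
tolerances being checked.

## Known limitations

* Filaments are uniform-width curves; real mitochondria branch, vary in
  width and overlap in projection, so absolute counts on real data depend
  on the skeleton-component convention chosen here.
* The tubeness scale is single-scale; networks with strongly mixed tubule
  widths would need a multi-scale extension.
* Dunn's test uses the large-sample normal approximation; very small
  groups with heavy ties are better served by exact permutation tests.
* The halo rule treats any supra-threshold halo fraction ≥ 5 % as
  astrocytic; crowded tissue with interleaved processes can inflate this,
  and the parameter should be validated against manual calls per dataset.
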