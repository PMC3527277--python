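# Methods

This note documents the models, parameter choices and numerical
conventions behind `mitoret`, and what the synthetic-data validation
does and does not establish about real data.

## Coordinate and interval conventions

All coordinates are 0-based, half-open (BED convention), internally and
on disk; 1-based dialects must be converted at the reader boundary.
Interval sets are normalized on construction — sorted by (chromosome
lexicographic, start, end) and, when a genome map is supplied, clipped
to chromosome bounds (clipping is logged, never an error; an unknown
chromosome is an error). Overlap between two intervals requires at
least one shared base pair by default; every overlap routine exposes a
`min_bp` parameter because published overlap tables rarely state a
minimum-overlap rule. Peaks on unassembled scaffolds (chrU/chrUextra
naming) are dropped by the pipeline after calling.

## Peak caller

The caller is a deliberately minimal fixed-fragment Poisson scanner in
the spirit of early MACS releases. It does not estimate a fragment
shift model: the fragment size is a parameter (default 36 bp, i.e. the
read length of a short-read experiment where the sonicated fragment was
treated as the read footprint), because the analyses this package
reproduces pinned it rather than estimating it. Consequences and
choices:

- **Background model.** λ_bg = N·(w + L − 1)/G expected fragments per
  w-bp window (N mapped reads, L fragment size, G effective genome
  size). Windows of width `bandwidth` (default 200 bp) slide at half-
  window steps; windows with Poisson upper-tail probability < `p_cutoff`
  (default 1e-5) are merged when closer than `bandwidth`, then trimmed
  to their covered extent.
- **Effective genome size** defaults to the total of the supplied
  genome map. For real fly data the established mappable-genome value
  (1.2e8) should be passed explicitly; a fixed large default applied to
  a small test genome would underestimate λ_bg by orders of magnitude
  and flood the caller with false windows.
- **Local λ.** With a sequencing-input track, the rate is the maximum
  of the genome-wide rate and the input-derived rate in 1-kb and 10-kb
  windows around the summit (depth-rescaled). Without input, genome-wide
  only.
- **Summit.** The summit is the coverage centroid of the peak rather
  than the raw argmax: sites with roughly uniform occupancy produce a
  flat, noisy coverage plateau on which the argmax is an unstable
  estimator (ties resolve arbitrarily and jitter across the plateau
  width), while the centroid is unbiased for symmetric peaks and has
  a few-bp standard error at 50 reads per site. Peak height remains the
  maximum pileup.
- **p-value.** Each merged peak's p-value is the Poisson upper tail of
  its fragment count against the local rate scaled to the peak's
  footprint (length + L − 1). Ties in downstream rankings break by read
  count, then coordinate, so output is deterministic.
- **Empirical FDR** follows the sample-swap convention: peaks are
  called with treatment and input exchanged, and a treatment peak at
  p-value p gets FDR = #(swap peaks ≤ p) / #(treatment peaks ≤ p),
  clipped to [0, 1]. A running maximum over the p-value ranking makes
  the reported FDR monotone non-decreasing (the raw ratio need not be),
  which is conservative. Without an input track the FDR is undefined
  and filtering falls back to the p-value cutoff, with a loud log
  message.

## Retention analysis

- A control peak is persistent iff it overlaps ≥ 1 mitotic peak by
  ≥ `min_bp` (default 1). A mitotic peak overlapping several control
  peaks is assigned to the one with the largest intersection, ties to
  the smaller p-value, then coordinate. Mitotic-only peaks are always
  reported, never auto-discarded: there is no automatable rule for
  dismissing them, so that judgement stays with the analyst.
- Decile tables rank control peaks best-first (ascending p-value;
  descending reads/height/fold), split them into 10 equal bins with the
  remainder spread one-per-bin over the leading bins (deterministic),
  and report the percentage of partnered mitotic peaks per bin. The
  entries sum to 100 exactly when every mitotic peak has a partner.
- The cross-sample correlation is Pearson's r over per-peak fragment
  counts on the merged union of peaks called in either sample, using
  the same fragment-overlap counting as the caller.

## Average profiles and the contamination null

Profiles accumulate fragment coverage in `bin_size` (default 50 bp)
bins across ±`flank` around each anchor midpoint (summit anchoring is
available), average over anchors, and scale by 1e6/total_mapped (RPM).
Windows running off a chromosome end are clipped; the anchor still
counts.

The contamination null asks whether the mitotic profile could be
produced by a fraction (default 5%) of interphase cells surviving the
mitotic sort. The null profile keeps each in-region control read with
probability 5% (one-pass binomial thinning; at thousands of reads the
difference from exact-count sampling is negligible) and — deliberately —
keeps the **original** total_mapped as its RPM denominator: the null
models contaminating cells inside a library sequenced to the original
depth, and renormalizing by the subsampled count would cancel the very
effect under test.

The headline statistic is the ratio of **central-bin enrichment**:
mean RPM over bins within ±200 bp of the anchor, minus the profile's
own baseline (mean over the outer half of the window), mitotic over
null. The baseline subtraction matters because the mitotic library is
sequenced to full depth and so carries a uniform background pedestal
that the in-peak-only null profile lacks; raw central means would
compare signal-plus-pedestal against signal alone and inflate the ratio
~3-fold even under pure contamination. Measured on the generator: pure
5% contamination gives a ratio of ≈ 1.0; 10% retention at 30% occupancy
gives ≈ 6 at retained anchors.

## Annotation

- Gene assignment uses a symmetric ±2 kb window around the TSS
  (strand ignored; no directional asymmetry is claimed), distance 0
  when a peak covers the TSS. The window is a parameter; a promoter
  definition of 250 bp upstream is a common alternative for
  region-composition annotation, not for gene lists.
- Border overlap is reported in both directions (fraction of peaks at
  borders, fraction of borders carrying a peak) with explicit
  numerators and denominators, since published percentage tables often
  leave the direction ambiguous. The preferential-retention ratio is
  the mitotic peak-at-border fraction over the control fraction.
- Chromosome-scale distributions report per-chromosome percentages per
  condition (each summing to 100) and their difference; the windowed
  variant tiles the genome in 5-Mb windows (parameter) and assigns each
  peak once, by midpoint, to avoid double counting at boundaries.

## Fractionation

Band intensities are normalized to percentages over the four fractions
S2 (cytosolic), P2, S3 (soluble nuclear), P3 (chromatin pellet). For a
G2/M culture with mitotic index m, the mitotic chromatin percentage is
recovered by the mixture inversion (P3_obs − (1 − m)·P3_ctrl)/m,
applied to P3 as published; a generalization to any fraction under the
same mixture model is provided as an explicit extension. Negative
corrected values (noise exceeding the mixture model) are flagged and
preserved in the raw field; clipping to [0, 100] applies only to the
exported summary value. Replicate SDs use the n−1 denominator. The
inversion is exact by construction: the generator applies the forward
mixture and the correction inverts it to machine precision on a full
grid of true values and mitotic indices.

## Image colocalization

Thresholds come from the Li minimum cross-entropy method (iterative
fixed point of the cross-entropy update; the implementation is
scikit-image's `threshold_li`, validated in the test suite against
exhaustive minimization of the cross-entropy objective over all
candidate thresholds). Masks replace the manual outline selection of a
bench workflow with an automatable proxy: the thresholded connected
component containing the global intensity maximum, holes filled. The
DNA mask is not constrained to lie inside the cell mask; the cytoplasm
is the literal set difference cell − DNA, so the identity
cyto = cell AND NOT dna holds by construction. An empty cytoplasm mask
yields an undefined (NaN) ratio rather than an error; an empty DNA mask
is an error. Group summaries report mean, SD (n−1) and n only — the
per-group comparisons are routine t-tests left to the user.

## Synthetic-data generator

The generator emulates the statistical structure of a two-condition
bookmarking experiment on a toy genome (default four 1-Mb chromosomes,
one kept site-free to exercise the all-sites-lost-on-one-chromosome
case):

- **Sites**: `n_sites` (default 5,000) non-overlapping 200-bp sites,
  ≥ 300 bp apart, allocated to chromosomes by length. Occupancy shares
  are log-normal (σ = 0.8) so that rank deciles are non-degenerate;
  expected control reads per site are depth·share (default depth
  250,000 ≈ 50 reads/site).
- **Retention**: a fraction ρ (default 0.1) of sites is retained at
  `occupancy_scale_mitotic` (default 0.3) of control occupancy.
  Retained sites are drawn with probability ∝ occupancy^2.5, so
  retention favors — but is not confined to — the strongest sites. The
  exponent and σ were fixed together by the design requirement that the
  end-to-end pipeline recover retained/non-retained status with
  sensitivity and specificity ≥ 0.9 at 50 reads/site over a 0.001
  reads/bp background, while keeping retention visibly non-exclusive
  across deciles.
- **Contamination**: a fraction c ≤ 0.05 of a control-like signal draw
  is added to the mitotic sample, modeling interphase cells passing the
  mitotic sort.
- **Matched depth**: by default the mitotic sample is topped up with
  uniform background reads so both conditions have the same expected
  library size, as two libraries sequenced to matched depth would.
  Setting `matched_depth=False` exposes the raw composition (useful for
  checking background expectations directly).
- **Borders**: a fraction of sites (default 0.1) is flagged
  border-proximal; border intervals are the flagged sites padded by
  300 bp, and an optional retention-enrichment factor multiplies those
  sites' retention weight. Because retention saturates, an enrichment
  factor e yields an observed peak-level ratio of e/(1 + (e−1)f) for
  border fraction f (≈ 1.8 for e = 2, f = 0.1), which the border-overlap
  tests account for.
- Reads are 5′ positions with random strand; signal fragments lie
  wholly within their site; background is uniform. All generators are
  pure functions of (config, seed).

**What passing on synthetic data does not show.** The generator has no
sequence content, mappability structure, PCR duplicates, copy-number
variation or chromatin-accessibility bias; occupancy is log-normal by
convenience, not by measurement; contamination is proportional to
control occupancy sites-wide, whereas real sort impurity may be
cell-state dependent. Recovery statistics on this generator validate
the pipeline's logic and calibration, not the biology of any particular
dataset.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at
1,000 sites / ~54,000 reads per condition (and smaller), which resolves
all the calibration bars above in seconds; the pipeline itself is
linear in reads and windows and runs unchanged at real-data scale. All
randomness flows from explicit seeds; the retention pipeline is a pure
function of (config, inputs, seed) and two identical runs produce
byte-identical output trees (manifests contain no timestamps).
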