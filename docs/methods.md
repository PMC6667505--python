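# Methods

`capcall` implements the computational side of a multiplexed 5'-capped-RNA
profiling experiment (MAPCap-style, applicable to CAGE/RAMPAGE-type data):
inline demultiplexing and UMI-based PCR de-duplication, replicate-aware TSS
detection by local negative-binomial enrichment, differential TSS usage with
spike-in or internal normalization, hierarchical TSS annotation, and a
precision-recall evaluation harness. This note records the model, the
defaults and why they are what they are, the design choices that were
genuinely open, and what the simulation-based tests do and do not establish.

## Read preprocessing

The library adapter ("s-oligo") contributes a fixed-length inline prefix on
one mate, described by a pattern over `{N, T}`: `T` positions carry the
sample index, `N` positions carry random nucleotides that act as a unique
molecular identifier (UMI). The default pattern `NNNNNTTTTTTNN` encodes a
6 nt index flanked by 7 random nucleotides. Because protocol write-ups of this adapter family differ on the ordering of
index and UMI bases, the pattern is fully configurable and neither ordering
is hard-coded; likewise the mate
carrying the prefix (`barcode_mate`, default R1) is configurable because the
strand that physically retains the adapter after circularization is not
fixed by the protocol description.

Demultiplexing assigns a read to the *unique nearest* barcode within
`max_mismatch` (default 1) of its index bases; exact matches therefore beat
one-off matches, and equidistant candidates are counted as ambiguous. A
warning is emitted when the sample sheet's minimum pairwise Hamming distance
does not exceed `2 * max_mismatch`. The adapter bases are trimmed from the
barcode mate and the UMI travels in the read name (`name_UMI`) on both
mates.

A 5'-end *tag* is the transcript-start base of a primary, mapped R1: the
leftmost aligned base on the plus strand, the rightmost on the minus strand.
Secondary, supplementary and unmapped records are skipped; the default MAPQ
floor is 0 (no filter). PCR duplicates are reads sharing (chromosome,
strand, 5' position, UMI); within each such group exactly the first read in
coordinate-then-name order is kept, which makes de-duplication deterministic
and idempotent. UMIs are matched exactly — no error-correction network —
mirroring the grouping the protocol defines. A RAMPAGE compatibility mode
takes the first 15 read bases as the UMI instead of a name token.

Single-base 5' coverage is exported as one bedGraph per strand, raw or CPM
(counts per million total tags, both strands pooled). All coordinates are
0-based half-open throughout the package; GTF input is converted on read.

## TSS detection

Tags are counted in strand-specific sliding windows (width 10 bp, step 5 bp
by default) and in a 2 kb background region centred on each window, clipped
at chromosome ends with the realised width recorded. Windows that would
overhang a chromosome end are dropped rather than clipped so the density
model stays exact. For single-base tags, strict-intersection counting and
any-overlap counting coincide.

Counts across replicates are modelled per region as

    y_i ~ NB(mu_i, phi),   mu_i = M_i * p,

with `M_i` the library size, `p` the common relative abundance of the group
and `phi` the NB dispersion (variance `mu + phi mu^2`). The log-likelihood
is strictly concave in `log p`, so a safeguarded Newton iteration converges
globally; `phi = 0` is the Poisson limit with the exact closed form
`p = sum(y)/sum(M)`. The fit default `phi = 0.1` is configurable; because
the one-group MLE at equal library sizes reduces to the replicate mean, the
choice of `phi` barely moves the point estimate and mainly matters through
downstream uncertainty, so no per-window dispersion estimation is performed
in the detection path.

The enrichment score of a window is a linear fold-change over its local
background computed from the two fitted log2-CPM abundances:

    delta = 2 ** (logCPM_window - (logCPM_background + log2(w / b_eff))),

where `w` is the window width and `b_eff` the realised background width.
The `log2(w/b_eff)` term converts the background abundance to the same
per-bp density scale as the window, so uniform coverage yields `delta = 1`;
without it the ratio of a 10 bp window to a 2 kb background would sit near
0.005 everywhere and a 2-fold cutoff would be meaningless. Presentations of
this statistic sometimes write delta as a ratio of mean logCPM values; it is
implemented as a fold-change on the linear scale, since only that reading
makes a 2-fold threshold interpretable.

Two prior-count details matter numerically:

- The background fit receives the prior scaled by `b_eff / w`, i.e. the same
  *per-bp* prior density as the window fit. An equal absolute prior on both
  fits would bias delta upward by roughly `1 + prior/count` (about +8% at a
  pooled window count of 25) and break the uniform-coverage calibration;
  with the width-matched prior, `E[delta] = 1` under uniform coverage at any
  depth, and windows with an empty background floor near 1 instead of
  diverging.
- The enrichment path uses a deliberately light prior (0.01 per window per
  sample, scaled by relative library size) so its damping effect on delta is
  below 1e-3 once a window holds 10 or more tags. The general-purpose
  abundance fit keeps the conventional prior of 0.5 for stabilising reported
  log-CPMs. Priors scale with each sample's library size relative to the
  mean library size, which makes delta exactly invariant under a uniform
  rescaling of all library sizes.

Windows with `delta >=` a primary threshold (default 2) seed clusters.
Seeds that overlap or lie within `merge_gap` bp of each other (default: the
grid step, so seeds separated by one sub-threshold window still fuse) are
merged into a cluster spanning their union. The cluster score is the mean
delta of *all* grid windows inside the span, bridging sub-threshold windows
included, and clusters scoring below a secondary threshold (default 1.5)
are discarded. "Nearby" has no canonical quantification;
`merge_gap = step` is this package's choice and is configurable, as is a
stricter 4-fold primary threshold used for sparse tissue data. The summit is
the base with the highest pooled deduplicated tag count, ties broken toward
the strand-aware 5'-most base. Clusters at most 20 bp wide (inclusive) are
classified "sharp", wider ones "broad".

The background region includes the window itself ("centred at the window",
by definition of a centred background); a flag excludes it. Self-inclusion turns out to
be stabilising: the tags of a strong TSS inflate their own local background,
which suppresses satellite windows at the cluster edges and keeps called
spans close to the true promoter width.

## Differential TSS usage

Per-sample TSS sets are unioned (overlapping same-strand clusters merged)
and tags are re-counted on the union regions. Size factors come from five
schemes: RLE (median of ratios over zero-free rows), TMM (30% log-ratio /
5% abundance double-trimmed, precision-weighted mean of M-values against the
column whose upper quartile is nearest the mean), upper-quartile (75th
percentile of nonzero counts), windowTMM (TMM on 10 kb genomic bins — bin
size is a free parameter; 10 kb chosen here), and
"external" (RLE on a spike-in count table). All factors are reported on the
count scale — divide counts by the factor — rescaled to geometric mean 1;
for TMM-family methods the compositional factor is multiplied by library
size first. A single count-scale convention means every method directly
recovers a global depth change and the GLM needs only `log(s_j)` offsets.

The two-group test fits, per region, NB group means with offsets `log(s_j)`
(group-mean coding, so the two one-group fits solve the GLM exactly) and
reports the Wald statistic `z = (beta_B - beta_A) / SE` with a two-sided
normal p-value and Benjamini-Hochberg adjustment (Holm optional). BH is
computed natively with the textbook `p * n / rank` running minimum.
Dispersion is estimated from the Cox-Reid adjusted profile likelihood
(`APL = loglik - 0.5 log det(X'WX)`, diagonal under group-mean coding) on a
30-point log-spaced grid: the common value maximises the row-averaged APL,
and per-row estimates maximise `APL_row + prior_n * mean APL` with
`prior_n = prior_df / residual_df` (prior_df 10), squeezing row estimates
toward the common value exactly in the spirit of weighted-likelihood
empirical Bayes. On 3v3 null simulations at the package's study conditions
this keeps the empirical type-I error at `p < 0.05` within a few tenths of a
percent of the rate obtained with the true dispersion supplied. Designs with
a single replicate in both groups are refused unless a fixed dispersion is
given. Spike-in rows (reference-name prefix, default `ERCC-`) are excluded
from testing and from internal normalization.

## Annotation

Gene models are flattened into a per-strand map in which every base carries
exactly one category, claimed in rank order: sense 5'UTR > sense CDS >
sense 3'UTR > sense intron > the same four antisense > enhancer > repeat >
intergenic. UTRs come from explicit records or exon-minus-CDS arithmetic;
transcripts without CDS contribute their exons at intron rank with a
warning. Enhancers outrank repeats by default (configurable), antisense
categories mirror the sense internal order, and each TSS is annotated at its
summit base (interval-majority available by flag). Distances to arbitrary BED feature sets
(e.g. dosage-compensation high-affinity sites, TAD boundaries) are 0 inside
a feature and otherwise the gap to the nearest covered base.

## Evaluation

Truth anchors are the annotated TSS positions of transcripts with TPM
strictly above 1.0 that fall inside an open-chromatin peak. A detection
matches an anchor within +/-100 bp (distance 0 inside the detection
interval, else gap to the nearest end); matching is one-to-one and greedy by
descending score. Detections inside the genic mask with no anchor within the
radius are false positives; unmatched anchors are false negatives.
Precision, recall and F1 are swept over score thresholds; AUPRC integrates
precision over recall by trapezoid with a left extension at the precision of
the highest threshold. Whether the
peak-overlap requirement applies to positives is configurable; the default
requires it, as written.

## Synthetic data

The generator plants `n_tss` TSSs (default 200, 70% sharp) on a random
genome (default one 2 Mb chromosome) without same-strand overlap, at least
300 bp apart and 1.1 kb from chromosome ends. Sharp TSSs emit tags from a
9-point kernel with exactly 90% of mass within +/-2 bp of the mode and a
decaying satellite tail (3.5% / 1.5% at +/-3 / +/-4) — real CAGE tag piles
taper rather than stopping abruptly, and a hard-edged kernel would let a
grid window isolate a 5% satellite and stretch strong sharp promoters past
the 20 bp shape cutoff. Broad TSSs spread tags uniformly over 30-70 bp.

Expected tags per TSS per replicate are log-normal (median 150, log-sd 1),
floored at `10 * background_rate * width` so that every planted TSS meets
the stated >=10-fold density contrast over background. Replicate molecule
counts are NB with `phi_sim = 0.1` (gamma-Poisson); background molecules are
uniform at 1.2 tags/bp/replicate across both strands. That background is
what makes a bare 2-fold cutoff specific: at ~24 pooled background tags per
10 bp window per strand, a Poisson fluctuation clears 2-fold with
probability ~2e-6 and the 800k-window genome yields only a handful of noise
clusters. Sparser backgrounds make any stray tag pile >2-fold enriched — a
real property of the method, visible in the single-replicate runs the
evaluation module scores.

Each molecule receives a UMI uniform over 4^7 (a collision-free mode draws
distinct UMIs per 5' position for exactness studies) and a Geometric(0.8)
PCR copy number (mean 1.25 copies; the truncation at 50 copies is
cosmetic). Reads are rendered as coordinate-sorted single-block SAM of the
trimmed R1 (the aligner itself is out of scope) and as multiplexed paired
FASTQ with the adapter prefix on R1; R2 is the reverse complement of the R1
genomic portion, as fragment-length modelling is a non-goal. Spike-ins are
10 species in a 2-fold within-sample dilution ladder (top expected count
8192), scaled across samples by a configurable relative-concentration
series, with Poisson counting noise.

All draws derive from `numpy.random.default_rng` seeded from
`SeedSequence([seed, stream])` with fixed stream ids, so a seed fixes every
byte of output across platforms.

What the simulation does *not* model: mappability and alignment error,
sequence-dependent capture bias, splicing, fragment-length variation,
UMI sequencing errors (hence no error-collapsing in the deduplicator), and
promoter shape classes beyond the sharp/broad dichotomy. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real libraries, for which evaluation against deep
sequencing datasets and curated annotation remains necessary.

## Numerical and reproducibility notes

- Newton iterations on the one-group fit stop at step 1e-12 with steps
  clipped to +/-5; all-zero rows with a zero prior floor at the abundance of
  0.1 pooled counts and are flagged.
- Dispersion grids span 1e-4 to 4 in 30 log-spaced points; APL maximisation
  is by grid argmax (the APL is smooth and unimodal in practice; quadratic
  refinement changes type-I rates by less than Monte-Carlo noise).
- The pipeline's provenance file records the package version, the resolved
  configuration and input/output checksums — but no wall-clock timestamp, so
  identical (inputs, config, seed) reruns are byte-identical; timestamps go
  to the log stream only.
- Problem sizes in the test-suite: the end-to-end study uses the full
  default conditions (2 Mb, 200 TSSs, 4 replicates, ~12M read pairs);
  differential calibration uses 2000 regions at 3v3; the NB fit oracle uses
  500 random instances. The de-duplication exactness study runs at 200 kb /
  20 TSSs with collision-free UMIs, since at full depth random 7 nt UMIs
  collide by design and exact molecule recovery is only defined without
  collisions.
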