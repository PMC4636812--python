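# Methods

This note documents the models, conventions and numerical choices behind
chipmeta, and what the synthetic-data validation does and does not show.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) everywhere inside
the package. Conversion to 1-based happens only at serialization of
formats that demand it (fixedStep wiggle, GTF). Reads are BED records
with a mandatory strand; the 5′ position is `start` on `+` and `end − 1`
on `−`. Peaks enter as BED with the tag density *t* in the score column;
an optional seventh column gives an absolute summit, otherwise the
summit defaults to the interval midpoint. Reads on chromosomes absent
from the declared sizes are dropped by default (configurable to a hard
error).

## Coverage model

A read is extended from its 5′ end to the expected fragment length
(default 200 bp, the typical sonication/size-selection scale for
single-end ChIP-seq) and counted once in every bin (default 25 bp) it
overlaps by at least one base. This overlap-count semantics matches how
browser tracks built from extended reads look; an alternative
5′-end-in-bin counting mode is available (`count_mode="five-prime"`).
Consequences of overlap counting: the sum of all bins lies between the
fragment count and fragment count × (⌈L/w⌉ + 1), and a fragment
boundary falling inside a bin still counts fully — there is no
fractional weighting.

Normalizations: `per-million` scales by 10⁶ / total reads (unique
mapped reads are the intended denominator); `input-ratio` is
(CPM + p) / (CPM_input + p) with pseudocount p = 1 CPM unit by default,
which caps the ratio where the input is empty; `scalar` divides by a
constant (used to bring a very deep histone-mark track onto the same
scale as factor tracks, e.g. dividing by five).

## Density matrices, profiles, offset estimate

Matrix columns are bin-spaced signed offsets −flank … +flank inclusive
(2·flank/bin + 1 columns, symmetric about 0 with a column at the anchor
itself). Each cell is a point sample of the track bin containing the
offset position — no interpolation, so the matrix bin width must be a
multiple of the track bin width. For `−` strand anchors the offset axis
is reversed, making "downstream" positive on both strands. Windows
crossing a chromosome boundary are zero-padded and the anchor id is
flagged rather than dropped, keeping row count equal to anchor count.

The binding-offset estimator smooths the metagene profile with a
moving average (default 3 bins, reflecting that a 25-bp grid is noisy at
realistic depths) and takes the argmax. Ties are broken toward offset
0, then downstream; a constant profile raises an error (no peak).

## k-means co-occupancy

Rows of each track's matrix are divided by (row mean + 1) — removing
per-site amplitude while keeping profile shape, in the spirit of
density-normalized clustering — then matrices are concatenated
column-wise and clustered with Lloyd's algorithm, k-means++
initialization, fixed `random_state` (scikit-learn backend; 10
restarts, tol 1e-4, max 300 iterations). Labels are renumbered 1…k by
decreasing cluster size so identical inputs and seed give bitwise-equal
labels. Cluster semantics are always read off the per-cluster mean
profiles of the *unnormalized* matrices, never off label order. k is a
per-analysis choice (2 for positive/negative splits, 3–4 for
promoter-state panels); it is an argument, not a constant.

A cluster is "positive" for a track when its mean density within
±100 bp of the anchor is at least 2× the background, where background is
the across-cluster median of mean flank density (outermost 25 % of
columns). Degenerate cases: a central mean of 0 is never positive; if
the background is exactly 0 any positive central density counts. The
co-bound fraction is the share of reference anchors in query-positive
clusters; the stricter ≥ 1-bp interval-overlap estimate is computed
separately and both are reported by the scenario runners.

## Peak annotation

Categories are evaluated at the peak summit with fixed precedence
promoter-TSS > 5′UTR > 3′UTR > exon > intron > TTS > intergenic. The
promoter window is −1000/+100 bp around the TSS and the TTS window
−100/+1000 bp around the 3′ end, both strand-aware. A single
promoter-TSS class is used; no separate "TSS" category is distinguished.
Gene binding uses an inclusive ±window (default 1 kb) on the summit-to-TSS
distance; one peak may bind several genes (divergent promoters), and the
best peak per gene is the qualifying peak with the highest tag density
(ties by peak id). The nearest-peak density for expression correlation
searches ±2 kb by default; a downstream-only mode exists because
"within 2 kb of the TSS" is directional in some workflows
(`side="downstream"`). Equidistant peaks resolve to the higher tag
density, then peak id.

## Expression integration

Quintiles: stable sort by FPKM descending with gene-id tie-break, split
into five groups whose sizes differ by at most one (remainder to the
top groups). Occupancy per quintile is summarized as median/Q1/Q3 with
notch half-width 1.58 · IQR/√n (the conventional notched-boxplot
formula); zero densities are dropped before quartiles by default since
a gene with no peak carries no occupancy signal. Bound-versus-all uses
log₂(FPKM + 0.1) — the pseudocount keeps silent genes finite roughly one
order of magnitude below typical expressed values — and a two-sided
Wilcoxon rank-sum test. The "all" group includes the bound genes, so
the comparison is bound versus the full catalogue, not bound versus
unbound.

## Enhancers and super-enhancers

Enhancer ranking averages the ranking track (per-bp exact mean over
track bins) in ±1 kb of the midpoint; quartiles I–IV are assigned by
rank with near-equal sizes and deterministic id tie-breaks. Midpoints
are unstranded — no orientation flip. Positive-enhancer calling reuses
the clustering machinery on midpoint matrices.

Super-enhancer profiles: each region's body is split into 80 contiguous
sub-intervals (remainder base pairs to the leftmost bins), flanks are
4 kb of fixed 50-bp bins on each side; per bin the per-bp mean CPM of
factor and input are accumulated across regions and the meta value is
mean(factor) ÷ mean(input) — average-then-ratio, which is robust to
empty per-region input bins; a ratio-then-average mode is provided for
comparison. Where both numerator and denominator are exactly zero the
ratio is defined as 1 (no evidence of enrichment either way); signal
over a zero input reports +inf rather than being silently clipped.
Flank bins beyond a chromosome end are excluded from the average.
Because both tracks are depth-normalized, planted local enrichment is
recovered slightly shrunk: extra reads inside enriched bodies inflate
the factor's library size, scaling the whole track down by
(background reads / total reads) — about 3 % in the validation scenario
(10 regions of 5–10 kb on 5 Mb at 3×). This composition effect is a
property of depth normalization itself, not an implementation artifact.

## The generator: what it emulates, what it does not

Emulated: non-overlapping genes with strand, exon structure and
strand-aware TSSs; enhancers and super-enhancers in intergenic space;
per-site binding strength (log-normal, σ = 0.5); a strand-aware
downstream binding offset (default +200 ± 50 bp — the elongation-coupled
positioning regime); exact-count pairwise co-binding between a reference
factor and each other factor; Poisson read counts per site with Normal
5′ positions; uniform background and a background-only input at matched
depth; uniform fold enrichment inside super-enhancer bodies; FPKM
rank-coupled to binding strength via a Gaussian copula
(weight w = 2 sin(πc/6) so the realized Spearman ≈ the requested c at
noise 1; with noise 0 the map is deterministic and rank agreement is
perfect).

Not emulated: sequence content, mappability and duplicate reads; fragment-
length variability; chromatin-state-dependent background; peak calling
(peak sets derive from the planted truth); co-binding structure among
more than two factors beyond each factor's pairing with the reference;
UTR annotation in generated genes (exons only). Passing the validation
suite therefore demonstrates correctness of the computations under a
clean statistical model, not robustness to alignment artifacts or
caller idiosyncrasies in real libraries.

## Validation scenario sizes

The canonical scenarios (in `chipmeta.scenarios`) fix the study
conditions: 2,000 reference sites on a 20-Mb genome for offset and
co-binding recovery (50 reads per site over a 200k-read background,
roughly an order of magnitude local enrichment); 2,000 enhancers with
25 % planted positives; 10 super-enhancers of 5–10 kb at 3× body
enrichment over a 100k-read background; 5,000 genes at Spearman
coupling 0.5 for the quintile trend; 26,460 simulated FPKMs for the
quintile-size law. These sizes keep each scenario's full pipeline run in
the seconds-to-tens-of-seconds range while leaving the planted effects
comfortably above sampling noise.

## Known limitations

- Overlap counting makes adjacent bins correlated over ~L/w bins;
  profile peak widths reflect fragment extension as much as binding
  geometry.
- The cluster-based co-occupancy estimate depends on the positivity
  threshold (2× flank background); heavily imbalanced designs or very
  low enrichment can shift it by a few percentage points, which is why
  the interval-overlap estimate is always reported next to it.
- The promoter window convention (−1 kb/+100 bp) places summits of
  factors bound a few hundred bp downstream of the TSS into 5′UTR/exon
  categories; interpret category distributions with the window in mind.
- Input-ratio tracks with the default pseudocount compress ratios in
  sparse regions; for very shallow inputs prefer the super-enhancer
  module's average-then-ratio pooling.
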