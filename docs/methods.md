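# Methods

## Per-gene domain statistics

A peak contributes to every gene it overlaps by at least 1 bp; overlap is
strand-blind. The per-gene width is the sum of **full** peak widths by
default (`clip=False`): a domain extending past a short gene still reflects
the true extent of repression around it, and this matches how broad
H3K27me3 is observed to spill beyond short oncogenes. An overlap-clipped
mode (`clip=True`) is exposed for sensitivity analysis; with clipping,
coverage is guaranteed ≤ 1, without it coverage may exceed 1. Coordinates
are 0-based half-open (BED convention) throughout; GTF input is converted
once at the parsing boundary.

## The knee-point width cutoff

Widths are sorted ascending and plotted against rank; both axes are
affinely rescaled to `[0, n−1]` (min–max for the widths, identity for the
ranks) and the turning point is the curve point with minimal Euclidean
distance to the bottom-right corner `(n−1, 0)`. Ties break toward the
larger rank (the broader width), so the cutoff errs conservative. The BGRD
cutoff is `multiplier × width_at_turn` with `multiplier = 2` by default.
The search is invariant to affine transformations of the widths: the knee
index is unchanged and the cutoff follows the data scale. A flat curve
(all widths equal) has no knee and raises an error rather than returning an
arbitrary point.

Classification takes the top `n_top` genes by width (default 500) and keeps
those at or above the cutoff — fewer than `n_top` are returned when the
cutoff bites. FGRDs are the `n_top` genes with the tallest peaks, with BGRD
taking precedence for genes in both lists. All ranking ties break by
lexicographic gene id, and the random control set is drawn from the
remainder with an explicit seed, so every call is reproducible.

## Coverage boundary and gene groups

The low/high-coverage split is the valley of a Gaussian kernel density
estimate (Silverman bandwidth) over positive coverages: the minimum between
the two highest local maxima of the density on a 512-point grid. A unimodal
density raises an error reporting the single mode; a user-supplied boundary
can be passed instead wherever the valley is used. Groups: a1 = BGRD genes;
L\* = the minimal gene length among them; a2 = length ≥ L\* with coverage at
or above the boundary; b = length ≥ L\* below the boundary; c = length <
L\*. The four groups partition the universe by construction.

## Enrichment

One-tailed Fisher's exact test on a 2×2 table with fixed margins equals the
hypergeometric upper tail `P(X ≥ observed)`; it is computed via the
survival function for numerical stability. Fold enrichment is observed over
expected with `expected = group × category / universe`. Sliding windows of
1500 genes advance by 1000 ranks (500 genes shared between neighbors); a
trailing partial window is dropped rather than padded so all windows have
equal size, and ranked genes missing from the universe are dropped with a
warning. No multiple-testing correction is applied across windows — the
curves are descriptive, reported as raw one-tailed p values.

## Profiles, pausing index, PTB ratio

Profile windows are strand-oriented: the TSS is `start` on `+` and `end` on
`−`, with minus-strand rows reversed so positive offsets always point into
the gene body; positions beyond chromosome bounds contribute zero.
Gene-body profiles resample each body into equal fractions (mean within
each fraction) so genes of different lengths align. The Pol II pausing
index is the ratio of **summed** per-bp signal in `[TSS−30, TSS+300)` to
`[TSS+300, TTS)`; the H3K27me3 promoter-to-body ratio uses `[TSS−3 kb,
TSS+3 kb)` against the remaining body. Sums (not means) follow the
read-density definition of the quantities; the eligibility filter instead
uses **mean** densities with a strict `> 0.01` floor in both windows, and a
zero body sum flags the ratio undefined (NaN) for downstream exclusion.
Both ratios are invariant to multiplying the track by a positive constant.
Motif tracks are binary per-bp indicators (no double counting of
overlapping occurrences), and motif fold enrichment is the ratio of mean
scaled-body densities between a gene group and its control group.

## Multi-sample matrices and panel selection

Genes absent from a sample's peak calls get width 0, not missing — absence
of enrichment is informative and keeps matrices dense. Per-sample BGRD
membership uses either the top-N rule (N = 500 by default, for parity with
single-sample classification) or an absolute width cutoff; conservation is
the row mean of the membership mask. Quantile normalization maps each
sample's value at rank r to the reference's order statistic at rank r, with
ties receiving the mean of the order statistics they span; it is idempotent
and preserves within-sample ranking, and a degenerate all-zero reference is
rejected. Forward panel selection ranks samples by the enrichment p of
their own BGRD set (ties by sample id), scores the cumulative union at
every k, and keeps the argmin of the union p curve (ties toward smaller k).
An alternative stopping rule — stop just before the union p first exceeds
the single-best-sample p — is exposed as `stop_rule="threshold"`; the two
coincide on well-behaved curves but the argmin is the default because it is
unambiguous.

## Differential calls

Pairwise mode computes `Δ = test − ref` per gene and gives each tail its own
knee: the positive part of `−Δ` (shortened side) and of `Δ` (lengthened
side), zeros included so the curve keeps its L shape, each feed the
turning-point search, and a gene is called when its change is positive and
at least `multiplier` (default 2) times the tail's turning-point value.
Calls are optionally capped at the `n_top = 350` most extreme per class.
Swapping the two conditions exactly exchanges the shortened and lengthened
sets. Cohort mode requires the cancer-minus-normal difference in mean width
and in conservation to both strictly exceed their thresholds (5 kb and 0.3)
with a common sign. The thresholds are strict inequalities, matching
"larger than"; the 0.3 conservation threshold is treated as a plain
threshold (its original normal-distribution justification specifies no
parameters to recompute).

The mock comparison permutes sample labels (class sizes preserved), reruns
the cohort call, and reports mean ± SD counts over replicates (default
1000; the analysis drivers and tests use 100, which already pins the mean
to well under one call on the conserved null). Its selectivity comes from
the conservation criterion and depends on cohort size: with only 10+8
samples a random shuffle can concentrate condition-linked samples in one
mock group often enough to re-call planted genes, while from roughly 20+20
samples onward mock counts collapse toward zero — the regime of the
hundred-sample cohorts this analysis is designed for. On a cohort with no
conservation differences the mock mean is exactly zero at any size.

## Candidate cascade

Flags are conjunctive: recurrent (BGRD in ≥ 2 panel samples), non-driver
(mutation Q absent or ≥ 0.5 — genes missing from the mutation table count
as non-drivers, since the cascade targets genes *not* found by mutation
analysis), expressed (strictly above the median of all genes in the
expression table), shortened (sample width ≤ `(1 − shrink_frac)` × panel
mean width, inclusive, with the panel mean averaging over **all** panel
samples, zeros included). lncRNA candidates skip the mutation filter and
additionally require an absolute shrinkage ≥ 20 kb (inclusive). Lengthened
controls mirror the cascade with `≥ (1 + grow_frac) ×` the panel mean, and
are disjoint from shortened candidates for any input. Tightening any
threshold can only remove candidates. The final manual inspection step
(browser review of candidate loci) is out of scope; the output carries all
evidence columns to support it.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
ChIP-Seq reads. One 300 Mb chromosome carries 2,000 non-overlapping genes
with log-normal lengths (median 20 kb, log-sd 1.3, ≥ 2 kb gaps); exon
totals grow sublinearly with length so the intron fraction rises with gene
length. Broad domains are planted on 10% of genes, restricted to genes
≥ 80 kb (falling back to the longest genes if too few qualify): a 3 kb
promoter peak plus body tiling of ~10 kb peaks summing to a coverage drawn
from (0.6, 0.9), heights in (1, 4). Building domains as tilings rather than
single peaks ensures the aggregation logic (width **sums**) is genuinely
exercised. Focal domains go to 5% of genes as a single 2 kb promoter peak
whose height (≥ 3 × the broad-domain ceiling) deterministically exceeds
every broad peak. Background noise peaks (2 per Mb, ≤ 2 kb, heights ≤ 2)
avoid planted genes so the planted margins are controlled by the spec, not
by accident. Signal tracks are the peak superposition plus small
non-negative noise at 100 bp steps.

Panels hold 10 samples sharing a conserved core (half of the planted broad
domains); the rest appear independently with probability 0.5. Cancer
cohorts add 8 samples, each copying a normal sample's planted peaks with
fresh background noise; 20 core genes are re-tiled to 10% of their width
(capped at a 10 kb remnant, mimicking the promoter-proximal residue left
after body erosion — and ensuring the remnant falls below any sensible
membership cutoff regardless of gene length), and 10 long unplanted genes
gain full domains. Copying rather than re-sampling the normals keeps
non-planted genes' conservation differences bounded (≤ 0.25 at 10+8
samples), so the planted calls are recoverable with zero false positives at
the 0.3 threshold. Expression is `exp(baseline − coupling × coverage +
noise)` with baseline 4, coupling 3 and log-noise sd 0.5 — positive,
finite, and negatively coupled to repression so that de-repressed
(shortened) genes tend to clear the median-expression filter.

Identical spec + seed gives bit-identical output; all derived random
streams are seeded from `(seed, tag)` pairs.

### What the generator does not emulate

Read-level noise, fragment-size effects and mappability; peak-caller
artifacts (the thresholding caller here is plumbing, not DANPOS);
inter-sample batch structure beyond what quantile normalization removes;
copy-number variation confounding cancer widths; genes spanning multiple
chromosomes of context (one chromosome only). Passing tests therefore
demonstrate correctness of the pipeline's logic and its behavior under the
assumed statistical structure — not robustness to the full messiness of
real ChIP-Seq.

## Problem sizes and runtimes

The default study (2,000 genes, 300 Mb, 18-sample cohort) runs the full
pipeline in a few seconds; the test suite completes in well under a minute
and the analysis drivers in under a minute total. These sizes were chosen
so that planted effects are estimated with comfortable margins while the
suite stays quick to iterate on; all thresholds and planted effect sizes
are fixed in `SyntheticSpec` and documented above.

## Known limitations

- The knee-point cutoff assumes the marked minority is small relative to
  the universe; when a large fraction of genes carries broad domains with a
  wide width spread, the knee migrates into the signal arm and the twofold
  cutoff turns conservative (this is a property of the corner-distance
  definition, reproduced faithfully here).
- FGRD classification has no height floor: with fewer tall peaks than
  `n_top`, zero-height genes can be labeled FGRD by the tie rule, matching
  the fixed-size top-N convention.
- The compact mock-shuffle caveat above: mock counts on very small cohorts
  are not comparable to the near-zero values attainable on hundred-sample
  cohorts.
- The group-a1 enrichment background is ambiguous in one published figure
  and is not resolved here; the enrichment module always scores against the
  explicit universe it is given.
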