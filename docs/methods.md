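# Methods

## Locus definition and annotation

Fragment loci are the unit of measurement: intervals between consecutive
MspI cut sites.  `msp_digest` cuts one base into every `CCGG` occurrence
(`C^CGG`), scans overlapping motifs (`CCGGCCGG` yields two sites), matches
case-insensitively, excludes the two terminal chromosome stretches (their
outer ends are not CCGG-bounded) and keeps fragments whose length lies in
the configured size selection (default 200–2000 bp, the assay's window).
All coordinates are 0-based half-open internally; BED I/O is native, the
gene TSV dialect is declared 1-based inclusive and converted on read.

Compartments partition the locus set with precedence **PR > GB > IG**:

* PR — overlap (>= 1 bp) with a promoter window, the 2 kb upstream of a
  TSS in strand orientation (`+`: `[tss−2000, tss)`; `−`: `[tss+1,
  tss+2001)`), clipped at chromosome bounds;
* GB — overlap with the gene body, TSS to TES.  A `gb_start_offset` knob
  (default 0) can start the body 2 kb downstream of the TSS instead: the
  originating study's wording is ambiguous about which was used, so both
  are supported and neither is asserted as its intent.  With offset 0 the
  promoter-vs-body ambiguity at the TSS is resolved by the PR precedence;
* IG — everything else.

When several genes qualify at the same precedence level, the locus links to
the gene whose TSS is nearest the locus midpoint (ties broken by gene id,
so outputs are deterministic).  Overlap is >= 1 bp rather than midpoint
containment: fragments are up to 2 kb long and a midpoint rule would
discard genuine promoter contacts of long fragments.

Promoter loci get a subcompartment: CGI if overlapping a CpG island, else
CGS if overlapping an island flank of width 2 kb, else `other`.  Islands
take precedence over shores.  Because CpG islands are unstranded, the
default shore is **both flanks** (standard usage); `upstream-only` mode
restricts to the lower-coordinate flank for strict compatibility with
wording that defines shores as the 2 kb upstream of an island.

## Paired testing

Both platforms use the same engine: per feature, a plain paired t-test of
T vs NT over subjects (`t = mean(d)/(sd(d)/sqrt(n))`, two-sided p, df
n−1), then Benjamini–Hochberg step-up adjustment, significance at
`q < alpha` (default 0.05).  No moderated-variance (empirical-Bayes)
variant is offered: pairing already removes the subject variance component
and the plain test is the one the downstream accounting is defined
against.  Missing values are handled pairwise-complete with n recomputed;
features with fewer than two complete pairs are dropped with a warning.
Degenerate features (zero spread) report `t=0, p=1` when the mean
difference is also zero, and `p=0` with a warning otherwise.

Sign convention: the score is an MspI/HpaII log ratio, so **delta < 0 is
hypermethylated in tumor** (direction `hyper`), delta > 0 `hypo`.
Magnitude classes are |delta| bands `[0, 0.5)` negligible, `[0.5, 1)`
small, `>= 1` moderate/large, boundaries assigned upward, values above 2
retained in the top class.  Ranked outputs order by q ascending, then
|delta| descending, then locus id.

## Enrichment

The compartment over-representation test draws, in each of B = 1000
iterations, as many loci as were called DM uniformly without replacement
from the full array, and counts how many land in the target compartment.
The one-sided empirical p is `(1 + #{null >= observed})/(B + 1)` — the +1
smoothing keeps it off zero, and also floors it at `1/(B+1)`.  Two
companions are reported for effects beyond that floor: a Gaussian tail
probability from the null draws' mean/sd, and an exact mode that evaluates
the hypergeometric upper tail (the analytic limit of the sampling
procedure), which the Monte-Carlo mode is tested to converge to.  Sampling
is plain uniform; no GC- or length-matched strata.

Categorical comparisons (direction x subcompartment, category x
subcompartment) use Pearson chi-square without continuity correction;
expected counts below 5 warn rather than refuse.

## DM x DE integration

A record links a significant DM locus to a significant DE gene whose
promoter window or gene body it overlaps (IG loci never link; both
platforms must be significant before categorization).  Joint directions
map to four categories — HyperDown, HypoUp, HyperUp, HypoDown — with
canonical defined per compartment: PR canonical = {HyperDown, HypoUp}
(methylation represses), GB canonical = {HyperUp, HypoDown} (methylation
tracks expression).  Records always carry the four-way category; the
counts table pools a compartment's two non-canonical categories into
`other`, giving the published tables' shape, with totals, canonical totals
and the canonical fraction as a percentage rounded to one decimal.

Counting unit: by default one record per **locus** (`dedup_locus=True`),
matching "# of loci" accounting — a locus overlapping several DE-gene
regions keeps its promoter link over a body link, then the nearest TSS.
An all-pairs mode keeps every qualifying (locus, gene) pair; accounting
conservation (cells sum to record count) holds under both.

Known discrepancy in the published accounting this package reproduces: the
adenocarcinoma merge table's promoter canonical cells sum to 80 (64 + 16)
while the accompanying text says PR n = 100; the table-consistent figures
(total 37,056, canonical 3,216, 8.7%) are the ones reproduced here.  The
genomic-distribution table's printed percentages are inconsistent with its
printed counts; the generator's default DM rates follow the counts (see
below) and no printed percentage from that table is used as a check.

## Classification and candidate ranking

Subjects — not samples — are split 2/3 train / 1/3 test (a subject's T and
NT never straddle the split, which would leak pairing information).  On
each of 10 iterations the DM test is re-run on the training subjects only,
the top k loci (k = 25 or 100; q ascending, |delta| descending, id) are
selected, and a **nearest-centroid** model (class means over the selected
loci, Euclidean assignment, ties to NT) is scored on the held-out samples:
sensitivity = tumor recall, specificity = non-tumor recall.  The source
study never names its classifier; nearest-centroid is adopted as the
minimal model consistent with building classifiers from a locus panel, and
no claim is made that published accuracies are reproducible (they also
require the undeposited real data).  Reports carry per-iteration and
averaged metrics — both the mean of per-split accuracies and the pooled
over-samples accuracy, since either averaging convention is defensible —
plus per-locus selection frequency; loci selected in every iteration are
flagged as stable discriminators.

Loco-regional consistency ranking scores each significant locus by the
number of other significant loci on the same chromosome, same compartment,
same direction, within a window (default 2000 bp) of edge-to-edge
distance.  Distance is strict (`< window`), so `window=0` disables
scoring; overlapping fragments count at distance 0.

## Synthetic data generator

No generative model accompanies the original study, so the generator
adopts the simplest model consistent with paired t-testing being the
inference engine: Gaussian subject-plus-residual noise on the normalized
score scale, `NT = mu_i + b_is + eps`, `T = mu_i + delta_i + b_is + eps`,
with `b_is` a per-locus, per-subject baseline shared between tissues and
`eps` residual noise.  Planted DM is drawn per locus at
compartment-specific rates; the sign is negative (hyper) with a
compartment-specific probability; |delta| comes from a three-band mixture
matching the magnitude taxonomy (`[0,0.5)`, `[0.5,1)`, `[1,2]`, uniform
within band) so magnitude classification has ground truth.  Expression
reuses the same noise structure on a log2 scale.  A gene whose promoter or
body contains a planted DM locus couples to its nearest such locus (one
gene, at most one locus — keeps truth unambiguous) and is always DE:
canonical direction with probability `canonical_coupling`, anti-canonical
otherwise; unlinked genes are DE at `de_rate` with random sign and fixed
|log2fc|.

Defaults emulate a 16-pair adenocarcinoma-sized cohort on a 5 Mb
two-chromosome genome: DM rates PR 0.21 / GB 0.45 / IG 0.32 (derived from
the published distribution's counts; its printed percentages are
internally inconsistent and would invert the gene-body enrichment),
hyper-given-DM PR 0.31 / GB 0.25 / IG 0.06, band mixture 0.35/0.45/0.20,
`subject_sd=0.2`, `residual_sd=0.3`, `de_rate=0.35`,
`canonical_coupling=0.087`.  The noise scales are this package's own
choice — the source study does not state the variance of its normalized
scores — and are
chosen so that moderate deltas are comfortably but not trivially
detectable at n = 16 (per-locus paired t ≈ 9 at |delta| = 1).  Zero sds
are allowed so noise-free limiting cases can be simulated.  Loci can be
placed directly (lengths uniform in the size window, non-overlapping, at a
configured density) or cut from random A/C/G/T sequence by the real digest
code.  One config seed fans out to fixed per-stage child streams, so any
stage is individually reproducible and identical configs give
byte-identical outputs.

What the generator does **not** emulate: array probe effects, dye bias or
normalization artifacts (the entry contract is a normalized matrix),
spatial autocorrelation of methylation beyond the planted per-locus
deltas, heavy-tailed or heteroskedastic noise, cell-type mixture, and any
dependence between DM status and locus GC content or length.  Passing
recovery tests therefore shows the *inference chain* is correct and
calibrated under the declared model — not that the model captures every
feature of real HELP data.

## Benchmark problem sizes

The standard experiments (in `helpdm.experiments`, shared by the analysis
drivers, test suite and acceptance script) use: 2,000 loci x 16 pairs x
20 seeds for null calibration and sensitivity/FDP (50 seeds for estimator
bias); a sparse-DM 80 Mb / 16,000-gene genome (~20,000 loci, ~1 locus per
gene region, DM rate 0.05) for coupling recovery, so a coupled gene almost
always contains exactly its one planted locus and the recovered canonical
fraction estimates the planted coupling probability with only ~1 pp of
contamination from multi-locus genes; 400 loci x 20 seeds for classifier
sanity.  These sizes give binomial error bands comfortably inside the
asserted tolerances while each experiment completes in seconds.

## Numerical and degenerate-input choices

BH adjustment delegates to the standard step-up implementation and is
tested against exhaustive evaluation of the definition.  Empty DM sets
render percentage columns as NA rather than 0.  Chi-square refuses zero
marginals.  Packing errors (gene mass or locus mass exceeding a
chromosome) raise explicit "infeasible" errors rather than truncating.
The classifier's distance ties resolve to NT; ranked tables use stable
sorts with id tie-breaks throughout, so every output is reproducible
byte-for-byte given the seeds logged in the run report.
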