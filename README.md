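# helpdm

Paired tumor / non-tumor differential-methylation analysis for
restriction-enzyme (HELP-style) methylome profiling, with expression
integration, compartment enrichment, discriminatory-locus classification —
and a synthetic-data generator with planted ground truth to exercise all of
it.

## Who this is for

The HELP assay (HpaII tiny fragment Enrichment by Ligation-mediated PCR)
reads out CpG methylation on genomic fragments bounded by MspI/HpaII
recognition sites (`C^CGG`), retaining fragments of 200–2000 bp.  Studies
built on it compare tumor (T) against adjacent non-tumor (NT) tissue from
the same subjects and ask, genome-wide:

1. which fragment loci are differentially methylated (DM),
2. whether DM concentrates in particular genomic compartments — promoter
   (PR, the 2 kb upstream of the TSS), gene body (GB), intergenic (IG) —
   and, within promoters, in CpG islands (CGI) or CG shores (CGS),
3. whether DM loci sit next to differentially expressed (DE) genes and
   whether the joint direction is *canonical* (promoter hypermethylation
   with downregulation / hypomethylation with upregulation; gene-body
   methylation tracking expression) or non-canonical,
4. whether a small panel of top DM loci discriminates T from NT.

`helpdm` implements that chain as a tested library plus CLI for anyone
analysing fragment-level methylation scores with a paired design.  Because
such studies rarely deposit raw arrays, the package ships a generator that
emulates the statistical structure of a paired cohort with known planted
effects, so every stage can be validated by parameter recovery.

## The model

Scores are normalized MspI/HpaII log ratios.  For locus *i* and subject
*s*:

```
NT_is = mu_i + b_is + eps_is
 T_is = mu_i + delta_i + b_is + eps'_is
```

with subject-level baseline `b_is ~ N(0, sigma_b^2)` (shared between the
two tissues, so it cancels in pairing) and residual noise
`eps ~ N(0, sigma_e^2)`.  Each locus is tested with a paired t-test on
`d_s = T_s − NT_s`:

```
delta_i = mean_s(d_s),   t = delta_i / (sd(d)/sqrt(n)),   p two-sided, df = n − 1
```

followed by Benjamini–Hochberg adjustment; loci with `q < 0.05` are DM.
By the HELP sign convention **delta < 0 means hypermethylated in tumor**.
|delta| is classed negligible `[0, 0.5)`, small `[0.5, 1)`, moderate/large
`>= 1`.  Expression uses the identical engine on log2 values (direction
up/down).  Compartment over-representation is a random-sampling permutation
test (draw |DM| loci from the array, count the target compartment, repeat
B = 1000 times), with the exact hypergeometric tail available as the
analytic reference.  The DM×DE merge links each significant locus to a
significant DE gene whose promoter window or body it overlaps and tallies
canonical/non-canonical categories; classification is repeated 2/3–1/3
subject-level holdout with top-k locus re-selection per split and a
nearest-centroid model.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential.py
python analysis/03_enrichment.py
python analysis/04_integration.py
python analysis/05_classification.py
python analysis/06_recovery_benchmarks.py
```

Output of steps 02–04 on the default 16-pair, 2,500-locus cohort:

```
DM: 693 / 2500 loci at q<0.05 (sensitivity 0.791, FDP 0.027 vs planted truth)
DE: 255 / 300 genes at q<0.05
compartment  n_on_array  n_dm  pct_of_represented  pct_hypo  pct_hyper
         PR         445    91                  20        68         32
         GB         693   246                  35        73         27
         IG        1362   356                  26        92          8

[montecarlo] observed 246/693 DM loci in GB (null mean 192.1); p = 0.000999, gaussian p = 1.13e-08
[exact]      observed 246/693 DM loci in GB (null mean 192.1); p = 7.34e-08

335 DM x DE records, 86 canonical (25.7%)
planted couplings: 228 (10.5% canonical)
```

Reading this: 693 loci are called DM against the 852 planted (sensitivity
0.79 at FDP 0.03 — the missed ones are mostly planted *negligible* deltas);
gene bodies hold more DM loci than random sampling predicts (246 observed
vs 192 expected; the Monte-Carlo p is floored at 1/1001, the Gaussian and
exact tails show how far beyond that floor the excess lies); hypomethylation
dominates everywhere but most extremely in intergenic loci; and of the 335
DM loci lying within 2 kb of a DE gene, 25.7% have the canonically expected
direction pair.  The same synthetic truth lets `06_recovery_benchmarks.py`
verify that the estimator chain is calibrated (delta bias ≈ 0, null
false-positive fraction ≈ 0, planted coupling fraction recovered within
binomial noise).

The `helpdm` CLI exposes each stage (`simulate`, `digest`, `annotate`,
`dm`, `de`, `enrich`, `integrate`, `classify`, `rank-candidates`) and an
end-to-end `run-all` driven by a YAML config; see `helpdm --help`.

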