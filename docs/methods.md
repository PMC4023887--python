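# Methods

## The analysis in brief

`regrescue` models a condition-contrast ChIP-seq experiment: a transcription
factor (the androgen receptor, AR) is profiled in a 2×2 design — background
∈ {empty vector (EV), HES6 overexpression} × treatment ∈ {vehicle,
bicalutamide} — with biological replicates (4/3/4/4; the EV-bicalutamide arm
in triplicate). The question is which binding sites survive androgen
inhibition only when HES6 is present. The expression arm asks whether genes
co-expressed with the same factor across tumours, and differentially
expressed in a model system, form a signature that stratifies patient
outcome.

## Consensus sites and classification

Replicate peak calls are merged by single-linkage overlap (gap 0: overlap or
abutment) across *all* samples, so one consensus site exists wherever any
replicate called a peak. The consensus summit is the rounded arithmetic mean
of contributing replicate summits and the interval is the union span.
Presence in a condition is a reproducibility vote: the site is present when
at least `reproducibility_min_fraction` of that condition's replicates
contributed a peak.

The default fraction is **0.5 (majority rule)**. With four replicates this
requires 2/4 and with three replicates 2/3. A stricter 0.75 (3/4 and 3/3) is
a configuration away, but majority is the default because presence calls
should be robust to realistic single-replicate drop-out: if each replicate
independently misses a true site with probability 0.1, a 3/3 requirement
passes only 73% of truly present sites in a triplicate arm, while 2/3 passes
97%. Classification compounds presence calls across two or three conditions,
so per-condition robustness matters quadratically.

Sites present at baseline (EV-vehicle) receive exactly one label:

| class    | EV-bicalutamide | HES6-bicalutamide | extra condition |
|----------|-----------------|-------------------|-----------------|
| lost     | absent          | absent            | — |
| rescued  | absent          | present           | — |
| enhanced | present         | present           | HES6-bic mean RPM ≥ 1.5 × EV-bic |
| other    | anything else   |                   | includes non-baseline sites |

Signal is the mean, over a condition's replicates, of RPM-normalised read
counts in the summit ± 250 bp window (RPM = counts × 10⁶ / library size).
The enhancement fold of 1.5 operationalises "clearly enhanced"; it is a
judgement call, exposed as `enhancement_fold_min`. HES6-vehicle presence is
recorded but never consulted. Coordinates are 0-based half-open throughout;
strand is carried but ignored by occupancy arithmetic.

## Co-occurrence Z-scores

The co-occurrence of a test interval set with a query set is
`bp_overlap(test, query) / bp_occupancy(query)` — total base-pair overlap of
the merged unions over the query's total occupancy, a strandless score in
[0, 1]. Because test sets differ in size, scores are compared across queries
after standardising each test row to Z-scores. The **sample** standard
deviation (n−1) is used and recorded in the output metadata; a degenerate
row (zero spread) yields all-zero Z with a warning rather than NaNs. The
interval algebra is exact: merge/occupancy/overlap are verified against a
per-base membership-set oracle in the test suite.

## TSS-relative genomic distribution

Each site, located by its summit, maps to exactly one of five bins with
precedence promoter > gene body > intergenic, always relative to the
*nearest* TSS (ties to the lower coordinate), strand-aware:

* distal promoter: 500–2,000 bp upstream (offsets in (500, 2000]);
* proximal promoter: 0–500 bp upstream;
* downstream: 0–500 bp past the TSS;
* gene body; intergenic.

Per-set bin fractions are divided by the whole-genome base composition of
the same bins (computed exactly, base-by-base in chunks) to give fold
enrichments, and any two named sets can be compared bin-wise (e.g.
rescued/lost). Fractions sum to 1 per set by construction.

## Nearest-gene targets and overlap enrichment

A site's candidate targets are all genes with |TSS − summit| ≤ 25 kb
(`--closest-only` restricts to the single nearest; the all-within-range
reading is the default because a summit between two close promoters is
genuinely ambiguous). Enrichment of a target gene set against a DEG list is
the hypergeometric upper tail P(X ≥ k) over an explicitly supplied universe
— the universe is never inferred, to avoid silent inflation. The overlap
percentage is reported relative to the DEG list. The implementation uses
`scipy.stats.hypergeom.sf`; the tests verify it against exhaustive rational
enumeration for every (N ≤ 30, K, n, k) to 10⁻¹² relative error, and the
p-value's symmetry in (targets, DEGs) is asserted numerically at run time.

## Differential expression and the anchor signature

Differential expression is a per-gene Welch (unequal-variance) t-test on log
expression with Benjamini–Hochberg adjustment. A moderated (empirical-Bayes)
statistic would borrow strength across genes; the plain test is used
deliberately — the derivation procedure, not the moderation machinery, is
what this package studies — and the substitution is recorded in the DEG
output metadata.

The signature is the intersection of two independently derived sets:

1. genes whose Pearson correlation with the anchor gene across the tumour
   cohort is ≥ `r_cutoff` (default 0.9; signed by default, `--absolute`
   for |r|; Spearman by flag; the anchor itself is excluded and
   zero-variance genes report missing);
2. the DEG set from the model-system contrast.

An optional `top_fraction` truncation keeps only the top fraction of ranked
genes by r when the correlated set is larger. It is **off by default**: on
platforms where the r-cutoff and a fixed percentage happen to select the
same genes the two descriptions coincide, but when they disagree the
correlation threshold is the scientifically meaningful filter, and
truncating by rank would discard genes that pass it for reasons unrelated to
their DEG status. Both knobs, all intermediate set sizes and the truncation
flag are recorded in the signature provenance YAML.

## Survival stratification

* **Kaplan–Meier / logrank** via lifelines: product-limit curves and the
  Mantel–Haenszel test (χ² with groups−1 df).
* **Single-gene cut-point** ("recursive partitioning" read as a single
  maximally selected split): all inter-sample expression midpoints between
  the 10th and 90th percentiles are scanned and the threshold maximising
  the logrank χ² is returned, ties broken toward the smallest midpoint.
  Because the cut is selected post hoc, the unadjusted p is optimistic; an
  optional permutation p (re-running the scan on permuted expression) is
  provided. Full recursive trees are out of scope.
* **Two-cluster partition**: signature genes are z-scored, samples are
  clustered by Ward linkage on Euclidean distance and the tree cut at two.
  Cluster 2 is defined as the higher-mean-expression cluster, making labels
  deterministic and sample-order invariant.
* **Cox regression** via lifelines with Efron tie handling: age, PSA,
  Gleason (numeric by default — a single hazard ratio per point — with a
  categorical option), surgical-margin status (dummy-coded) and the cluster
  label. Missing covariates are deleted listwise with a reported count;
  constant covariates, < 2 events and non-convergence raise with
  diagnostics rather than returning silent garbage.

## The synthetic study

The generator is a pure function of its config (one `numpy` Generator
seeded once); regeneration is byte-identical, and truth tables are
serialised next to the data so downstream evaluation reads truth from file.

**Genome and annotation.** Two 3 Mb chromosomes, 300 non-overlapping genes
(2–8 kb, ≥ 6 kb apart, strand-balanced; the gap keeps each promoter's bins
attributable to a single nearest TSS). Annotation gene ids are drawn from
the expression universe so genomic and expression arms share a namespace.

**Sites.** 300 per class. Class presence patterns follow the definitions
exactly. Rescued and enhanced sites are enriched in the distal promoter bin
by an exact factor 2 (per-bin counts by largest-remainder rounding, uniform
placement within each bin's base set); the exactness is deliberate — the
planted enrichment is a design parameter, not a sampled quantity — while
the uniform-null check uses genuinely random summits. In-bin promoter
placements are biased (weight 5) toward planted-DEG genes, emulating
regulatory sites upstream of the genes they induce. Sites keep ≥ 1.5 kb
apart so consensus merging cannot fuse neighbours.

**Peak calls.** Per replicate: each truly present site is called with
probability 0.9 (drop-out 0.1), its summit jittered by N(0, 20 bp); 20
spurious calls per replicate land uniformly.

**Coverage.** Gaussian bumps (sd 100 bp, ~200 reads per present site,
lognormal 10% replicate jitter) on a Poisson background of 0.01 reads/bp in
1 kb blocks, built at 10 bp resolution and run-length compressed; enhanced
sites get fold 3 in HES6-bicalutamide. Library size 2 × 10⁶ reads.

**Expression.** Two matrices, because the correlation and DEG evidence come
from different datasets in practice and a single matrix cannot carry both
structures: a planted group shift on correlated genes would add variance
independent of the anchor and destroy the planted correlation. The tumour
cohort (2,000 genes × 140 samples) has anchor ~ N(0,1) plus a 3-sd shift
for true cluster-2 samples (40%), and a 40-gene block = 0.95·anchor +
√(1−0.95²)·noise; the cluster shift propagates through the anchor, so the
planted correlation survives. The 3-sd shift is the d′ separation of the
two patient clusters — the shared anchor variance does not average out
across signature genes, so cluster recovery is bounded by Φ(d′/2) ≈ 93%,
and Ward typically reaches 80–95%. The xenograft matrix (10 vs 10, noise sd
0.5) plants a 2 log-unit shift on 30 of the 40 block genes plus 70 others.

**Survival.** Exponential baseline (0.02 events/month), hazard ×
exp(0.7) for true cluster 2 and × exp(0.2·(Gleason−7)); independent
exponential censoring calibrated so ~30% of records censor. The exponential
baseline keeps closed-form sanity checks available.

**What passing tests show — and do not.** The generator produces clean
unimodal peaks, homoskedastic Gaussian log expression, exchangeable
replicates and proportional hazards by construction. Recovery results
demonstrate that the statistical machinery is implemented correctly at the
study's scale, not that it is robust to copy-number artefacts, mappability
holes, batch effects, probe cross-hybridisation or non-proportional
hazards, none of which are simulated.

## Problem sizes and numerics

Default analysis scales (300 sites/class with 15 replicate tracks on a 6 Mb
genome; 2,000 genes; 140 patients) run the full pipeline in ~10 s and were
chosen so the complete property suite — including a 2,000-iteration logrank
null and 50 Cox recovery fits at n = 500 — stays comfortable on one CPU.
Windows at chromosome edges are clipped and report the signal actually
present; summit windows use half-open bin arithmetic so bins always sum to
the window total. Z rows standardise with n−1; BH q-values are monotone and
capped at 1; hypergeometric tails are computed by `scipy` in a numerically
stable way rather than by naive summation of tiny terms.

## Known limitations

* Peak calling, alignment and IDR-style reproducibility modelling are out
  of scope; the pipeline consumes peak calls and coverage.
* The co-occurrence statistic has no significance model (Z-scores only,
  by design); motif analysis and pathway tools are not included.
* The maximally selected cut-point's unadjusted p does not account for
  selection; use the permutation option when it matters.
* Ward/Euclidean on z-scored genes is one defensible clustering choice
  among several; it is recorded in output metadata rather than claimed to
  be canonical.
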