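# regrescue

Condition-contrast ChIP-seq binding-site analysis and anchor-correlated
prognostic expression signatures.

## The problem

When an androgen-dependent prostate cancer cell is treated with an
anti-androgen, the androgen receptor (AR) loses most of its chromatin
binding. Some resistance factors (here the transcription co-factor HES6)
keep a subset of AR binding sites occupied anyway. `regrescue` is a desk
pipeline for the computational half of such a study, for analysts working
with peak calls, coverage tracks, expression matrices and clinical
follow-up:

1. **Classify binding sites** across a 2×2 design (background EV/HES6 ×
   treatment vehicle/bicalutamide, replicated 4/3/4/4). Replicate peak
   calls are merged into consensus sites (summit = mean of replicate
   summits; presence = reproducibility vote per condition), and every
   baseline site is labelled **lost** (absent under inhibition in both
   backgrounds), **rescued** (absent in EV-bicalutamide, present in
   HES6-bicalutamide), **enhanced** (retained, with HES6-bicalutamide mean
   RPM ≥ 1.5× EV-bicalutamide) or **other**.
2. **Compare interval sets** by base-pair co-occurrence: for test set T and
   query set Q, `score = bp_overlap(T, Q) / bp_occupancy(Q)`, standardised
   to Z-scores within each test set so differently sized sets are
   comparable.
3. **Profile signal** (RPM-normalised) around summits, and measure each
   class's **TSS-relative genomic distribution** — distal promoter
   (500–2,000 bp upstream), proximal promoter, downstream, gene body,
   intergenic — against the whole-genome base composition.
4. **Score target overlap**: genes with a TSS within 25 kb of a site summit,
   tested against a differentially-expressed-gene list by the
   hypergeometric upper tail P(X ≥ k) over an explicit gene universe.
5. **Derive a signature**: genes with Pearson r ≥ 0.9 to an anchor gene
   across a tumour cohort, intersected with DEGs (Welch t +
   Benjamini–Hochberg) from a model system.
6. **Stratify survival**: Ward two-cluster partition on signature
   expression, Kaplan–Meier/logrank, a maximally selected single-gene
   cut-point, and Cox proportional hazards with clinical covariates (age,
   PSA, Gleason, margin status).

A seeded synthetic-data module generates every input with planted truth
(site classes, correlated gene block, DEGs, patient clusters, hazards), so
the whole pipeline is testable end-to-end without any download. See
`docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full pipeline on a default synthetic study (300 sites per class on
a 6 Mb genome, 2,000 genes, 140 patients):

```bash
$ regrescue run --seed 1 --out demo
pipeline complete: 10 stages -> demo
```

`demo/` now holds the consensus site table, per-class BEDs, co-occurrence
matrices, distribution tables, DEG and signature lists, cluster
assignments, KM tables and the Cox summary, plus `run_manifest.yaml` with
the fully-echoed config and checksums. Highlights from this run:

```text
$ head -2 demo/distribution_rescued_vs_lost.tsv
        rescued_vs_lost
upstream_2000_500       1.8041558441558438
```

Rescued sites are ~1.8× as concentrated in the distal promoter bin as lost
sites (the generator plants a 2× shift of rescued binding toward proximal
promoters; 1.80 is the recovered estimate at 300 sites/class).

```text
$ cat demo/cox_summary.tsv
covariate  coef       hr        hr_lower95  hr_upper95  pvalue
age        -0.015129  0.984985  0.949913    1.021351    0.413418
psa        -0.007634  0.992395  0.980025    1.004922    0.23295
gleason    0.205184   1.227751  0.98151     1.53577     0.072406
cluster2   0.599758   1.821678  1.133899    2.926638    0.013158
margin_positive  -0.207952  0.812246  0.507417  1.300199  0.386312
```

The signature (30 genes out of 2,000; 104 DEGs) splits the 140 patients
into two clusters whose membership carries an independent hazard ratio of
1.82 (p = 0.013, logrank χ² = 6.29) after adjusting for the clinical
covariates — the planted cluster effect was exp(0.7) ≈ 2.0, attenuated by
imperfect cluster recovery, while age/PSA/margin were planted null and
report null.

Individual stages are available as subcommands (`regrescue simulate |
classify | profile | cooccur | distribution | deg | enrich | signature |
stratify`); the library functions under `regrescue.*` expose the same
operations programmatically.

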