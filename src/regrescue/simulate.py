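"""Seeded generators for every input the pipeline consumes.

The generator emulates the statistical structure of a condition-contrast
AR ChIP-seq + expression study:

* a 2x2 condition design (EV/HES6 background x vehicle/bicalutamide) with
  replicate counts 4/3/4/4 (EV-bicalutamide in triplicate, the others in
  quadruplicate), per-replicate peak drop-out, summit jitter and spurious
  calls;
* planted site classes with the presence patterns that define them —
  lost (baseline only), rescued (returns with HES6 under bicalutamide),
  enhanced (retained everywhere with a signal fold in HES6-bicalutamide) and
  other (retained, fold ~1) — with rescued/enhanced sites enriched in the
  distal promoter bin (500-2,000 bp upstream of a TSS) by an exact factor;
* Gaussian-shaped coverage bumps (sd 100 bp) on a Poisson background, RPM
  denominators per replicate;
* a tumour-cohort expression matrix with a planted anchor-correlated gene
  block and a two-cluster structure driven through the anchor, and a
  separate two-group xenograft matrix with planted differential expression
  (the correlation and DEG evidence come from different datasets, as they
  would in practice);
* survival times with an exponential baseline whose hazard depends on the
  true cluster, plus clinical covariates (age, PSA, Gleason, margin status).

Everything is a pure function of (config, seed): regeneration is
byte-identical.  Truth tables are serialised alongside the data so that
downstream evaluation reads truth from file, never from memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .classify import (
    CONDITIONS,
    Condition,
    EV_BIC,
    EV_VEHICLE,
    HES6_BIC,
    HES6_VEHICLE,
    Peak,
    PeakSet,
)
from .context import TssBinScheme, UPSTREAM_FAR, assign_bin_codes, genome_background
from .intervals import Genome, Interval, SignalTrack

__all__ = [
    "SimConfig",
    "PRESENCE",
    "make_genome_and_annotation",
    "make_peak_truth",
    "make_replicate_peaks",
    "make_signal_tracks",
    "make_expression_and_survival",
    "uniform_summits",
    "simulate_all",
    "score_recovery",
    "load_peak_sets",
    "load_tracks",
]

#: Presence pattern per planted class — the class definitions themselves.
PRESENCE: dict[str, dict[Condition, bool]] = {
    "lost": {EV_VEHICLE: True, HES6_VEHICLE: True, EV_BIC: False, HES6_BIC: False},
    "rescued": {EV_VEHICLE: True, HES6_VEHICLE: True, EV_BIC: False, HES6_BIC: True},
    "enhanced": {EV_VEHICLE: True, HES6_VEHICLE: True, EV_BIC: True, HES6_BIC: True},
    "other": {EV_VEHICLE: True, HES6_VEHICLE: True, EV_BIC: True, HES6_BIC: True},
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    seed: int = 0

    # genome / annotation
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000}
    )
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    gene_gap_min: int = 6_000

    # planted binding sites
    sites_per_class: dict[str, int] = field(
        default_factory=lambda: {"lost": 300, "rescued": 300, "enhanced": 300, "other": 300}
    )
    replicates: dict[str, int] = field(
        default_factory=lambda: {
            "EV.vehicle": 4,
            "EV.bicalutamide": 3,
            "HES6.vehicle": 4,
            "HES6.bicalutamide": 4,
        }
    )
    dropout: float = 0.1
    summit_jitter_sd: float = 20.0
    spurious_per_replicate: int = 20
    peak_half_width: int = 300
    min_site_spacing: int = 1_500
    promoter_enrichment: float = 2.0  # distal-promoter fold for rescued/enhanced
    deg_target_weight: float = 5.0  # promoter placement bias toward planted-DEG genes

    # coverage tracks
    site_reads: float = 200.0  # reads per present site per replicate
    bump_sd: float = 100.0
    bump_extent: int = 400
    signal_bin: int = 10
    background_rate: float = 0.01  # reads per bp
    background_block: int = 1_000
    amp_jitter_sd: float = 0.1  # lognormal sd of per-site-replicate amplitude
    enhanced_fold: float = 3.0
    library_size: float = 2_000_000.0

    # expression (tumour cohort + xenograft)
    n_expr_genes: int = 2_000
    anchor: str = "HES6"
    block_size: int = 40
    rho: float = 0.95
    n_tumor_samples: int = 140
    cluster2_fraction: float = 0.4
    anchor_cluster_shift: float = 3.0
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    xeno_n_per_group: int = 10
    deg_in_block: int = 30
    n_deg_extra: int = 70
    deg_effect: float = 2.0
    xeno_noise_sd: float = 0.5

    # survival
    baseline_hazard: float = 0.02  # events per month
    log_hr: float = 0.7  # planted cluster-2 log hazard ratio
    gleason_log_hr: float = 0.2  # per Gleason point above 7
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if not 0 < self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in (0, 1)")
        if self.deg_in_block > self.block_size:
            raise ValueError("deg_in_block cannot exceed block_size")
        for key, n in self.replicates.items():
            Condition.parse(key)
            if n < 1:
                raise ValueError(f"replicate count for {key} must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        d = dict(d)
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        return cls(**d)


def _expression_gene_ids(cfg: SimConfig) -> list[str]:
    ids = [f"G{i:04d}" for i in range(1, cfg.n_expr_genes)]
    return [cfg.anchor] + ids


def make_genome_and_annotation(
    cfg: SimConfig, rng: np.random.Generator, gene_ids: list[str] | None = None
) -> tuple[Genome, pd.DataFrame]:
    """Genome plus non-overlapping, strand-balanced gene annotation.

    Genes are spread across chromosomes in proportion to length, separated by
    at least ``gene_gap_min`` bp with the slack distributed at random.
    ``gene_ids`` (e.g. a subset of the expression universe) may be supplied;
    otherwise synthetic ids are used.  Raises when the genes cannot fit.
    """
    genome = Genome(dict(cfg.chrom_lengths))
    if cfg.n_genes == 0:
        ann = pd.DataFrame(columns=rio.ANNOTATION_COLUMNS)
        return genome, ann
    if gene_ids is None:
        gene_ids = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    if len(gene_ids) != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    chroms = list(genome.lengths)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(cfg.n_genes, weights / weights.sum())
    rows = []
    gi = 0
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, n_c)
        slack = genome.lengths[chrom] - int(lengths.sum()) - (n_c + 1) * cfg.gene_gap_min
        if slack < 0:
            raise ValueError(f"genes cannot fit on {chrom} without overlap")
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = cfg.gene_gap_min + extra[0]
        for j in range(n_c):
            start = int(pos)
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            rows.append((gene_ids[gi], chrom, strand, tss, start, end))
            gi += 1
            pos = end + cfg.gene_gap_min + extra[j + 1]
    ann = pd.DataFrame(rows, columns=rio.ANNOTATION_COLUMNS)
    return genome, ann


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` closest to ``fracs * total``."""
    exact = fracs * total
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    return base


class _SpacingGuard:
    """Grid-based exclusion: no two accepted positions within ~spacing bp."""

    def __init__(self, spacing: int):
        self.spacing = max(spacing, 1)
        self.blocks: dict[str, set[int]] = {}

    def accept(self, chrom: str, pos: int) -> bool:
        b = pos // self.spacing
        occ = self.blocks.setdefault(chrom, set())
        if {b - 1, b, b + 1} & occ:
            return False
        occ.add(b)
        return True


def make_peak_truth(
    cfg: SimConfig,
    genome: Genome,
    annotation: pd.DataFrame,
    rng: np.random.Generator,
    scheme: TssBinScheme | None = None,
    favored_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Planted site summits with true classes.

    Rescued and enhanced sites are enriched in the distal promoter bin by the
    exact factor ``promoter_enrichment`` (bin counts by largest-remainder
    rounding, positions uniform within each bin's base set), the remaining
    mass following the genome background; lost/other sites follow the
    background in every bin.  When ``favored_genes`` is given, the promoters
    chosen for in-bin rescued/enhanced placement are biased toward those
    genes with weight ``deg_target_weight`` — emulating regulatory sites that
    sit upstream of the genes they induce.
    """
    scheme = scheme or TssBinScheme()
    labels = scheme.labels
    far_idx = labels.index(UPSTREAM_FAR)
    bg = genome_background(genome, annotation, scheme).to_numpy()
    have_promoters = bg[far_idx] > 0

    # base positions per bin, per chromosome (sampled lazily below)
    chrom_codes = {}
    for chrom, length in genome.lengths.items():
        chrom_codes[chrom] = assign_bin_codes(
            np.arange(length, dtype=np.int64), chrom, annotation, scheme, genome
        )
    chrom_names = list(genome.lengths)
    chrom_w = np.array([genome.lengths[c] for c in chrom_names], float)
    chrom_w /= chrom_w.sum()

    guard = _SpacingGuard(cfg.min_site_spacing)
    ann = annotation
    fav = favored_genes or set()
    if have_promoters:
        gene_weights = np.where(ann["gene_id"].isin(fav), cfg.deg_target_weight, 1.0)
        gene_weights = gene_weights / gene_weights.sum()

    def sample_in_far_bin() -> tuple[str, int]:
        g = ann.iloc[rng.choice(len(ann), p=gene_weights)]
        u = int(rng.integers(scheme.far_lo + 1, scheme.far_hi + 1))
        pos = g["tss"] - u if g["strand"] == "+" else g["tss"] + u
        return str(g["chrom"]), int(pos)

    def sample_in_bin(code: int) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_w)]
            pos = int(rng.integers(0, genome.lengths[chrom]))
            if chrom_codes[chrom][pos] == code:
                return chrom, pos
        raise RuntimeError(f"could not sample a position in bin {labels[code]}")

    rows = []
    for cls in ("lost", "rescued", "enhanced", "other"):
        n = cfg.sites_per_class.get(cls, 0)
        if n == 0:
            continue
        fracs = bg.copy()
        if cls in ("rescued", "enhanced") and have_promoters:
            boosted = min(cfg.promoter_enrichment * bg[far_idx], 0.9)
            rest = 1.0 - boosted
            fracs = bg * rest / (1.0 - bg[far_idx])
            fracs[far_idx] = boosted
        counts = _largest_remainder(fracs, n)
        for code, n_bin in enumerate(counts):
            placed = 0
            attempts = 0
            while placed < n_bin:
                attempts += 1
                if attempts > 200 * n_bin + 1_000:
                    raise RuntimeError(
                        f"cannot place {n_bin} {cls} sites in bin {labels[code]}: "
                        "genome too crowded for min_site_spacing"
                    )
                if code == far_idx and have_promoters:
                    chrom, pos = sample_in_far_bin()
                    if not (0 <= pos < genome.lengths[chrom]):
                        continue
                    if chrom_codes[chrom][pos] != far_idx:
                        continue  # promoter shadowed by a neighbouring gene
                else:
                    chrom, pos = sample_in_bin(code)
                half = cfg.peak_half_width
                if pos - half < 0 or pos + half > genome.lengths[chrom]:
                    continue
                if not guard.accept(chrom, pos):
                    continue
                rows.append((chrom, pos, cls))
                placed += 1
    truth = pd.DataFrame(rows, columns=["chrom", "summit", "true_class"])
    truth = truth.sort_values(["chrom", "summit"], kind="stable").reset_index(drop=True)
    truth.insert(0, "site_id", [f"true{i + 1:05d}" for i in range(len(truth))])
    return truth


def _condition_replicates(cfg: SimConfig) -> list[tuple[Condition, int]]:
    out = []
    for c in CONDITIONS:
        for r in range(1, cfg.replicates[c.label] + 1):
            out.append((c, r))
    return out


def make_replicate_peaks(
    truth: pd.DataFrame, cfg: SimConfig, genome: Genome, rng: np.random.Generator
) -> dict[tuple[Condition, int], list[Peak]]:
    """Noisy replicate-level peak calls from the truth table.

    A truly-present peak appears in a replicate with probability
    ``1 - dropout``, its summit jittered by a rounded Gaussian; each
    replicate also gains ``spurious_per_replicate`` uniformly-placed false
    calls.
    """
    half = cfg.peak_half_width
    chrom_names = list(genome.lengths)
    chrom_w = np.array([genome.lengths[c] for c in chrom_names], float)
    chrom_w /= chrom_w.sum()
    out: dict[tuple[Condition, int], list[Peak]] = {}
    for cond, rep in _condition_replicates(cfg):
        peaks: list[Peak] = []
        for row in truth.itertuples(index=False):
            if not PRESENCE[row.true_class][cond]:
                continue
            if rng.random() < cfg.dropout:
                continue
            jitter = int(round(rng.normal(0.0, cfg.summit_jitter_sd)))
            length = genome.lengths[row.chrom]
            summit = int(np.clip(row.summit + jitter, half, length - half - 1))
            peaks.append(Peak(Interval(row.chrom, summit - half, summit + half), summit))
        for _ in range(cfg.spurious_per_replicate):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_w)]
            summit = int(rng.integers(half, genome.lengths[chrom] - half))
            peaks.append(Peak(Interval(chrom, summit - half, summit + half), summit))
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        out[(cond, rep)] = peaks
    return out


def _site_amplitude(cfg: SimConfig, cls: str, cond: Condition) -> float:
    """Expected reads contributed by one present site (class x condition)."""
    if not PRESENCE[cls][cond]:
        return 0.0
    if cls == "enhanced" and cond == HES6_BIC:
        return cfg.site_reads * cfg.enhanced_fold
    return cfg.site_reads


def make_signal_tracks(
    truth: pd.DataFrame, cfg: SimConfig, genome: Genome, rng: np.random.Generator
) -> dict[tuple[Condition, int], SignalTrack]:
    """Coverage step functions: Gaussian bumps at true summits on Poisson background.

    Bump amplitudes follow the class x condition table (enhanced sites get
    ``enhanced_fold`` in HES6-bicalutamide) with lognormal per-site-replicate
    jitter; the background is Poisson per ``background_block`` bp block.
    Tracks are built at ``signal_bin`` resolution and run-length compressed.
    """
    from scipy.stats import norm

    bin_w = cfg.signal_bin
    out: dict[tuple[Condition, int], SignalTrack] = {}
    by_chrom = {c: g for c, g in truth.groupby("chrom")}
    for cond, rep in _condition_replicates(cfg):
        segments = {}
        for chrom, length in genome.lengths.items():
            n_bins = length // bin_w
            values = np.zeros(n_bins)
            # Poisson background, constant within each block
            n_blocks = -(-length // cfg.background_block)
            bg = rng.poisson(cfg.background_rate * cfg.background_block, n_blocks)
            per_bin = cfg.background_block // bin_w
            values += np.repeat(bg / cfg.background_block, per_bin)[:n_bins]
            g = by_chrom.get(chrom)
            if g is not None:
                for row in g.itertuples(index=False):
                    amp = _site_amplitude(cfg, row.true_class, cond)
                    if amp == 0.0:
                        continue
                    amp *= float(rng.lognormal(0.0, cfg.amp_jitter_sd))
                    lo = max((row.summit - cfg.bump_extent) // bin_w, 0)
                    hi = min((row.summit + cfg.bump_extent) // bin_w + 1, n_bins)
                    edges = np.arange(lo, hi + 1) * bin_w
                    cdf = norm.cdf(edges, loc=row.summit, scale=cfg.bump_sd)
                    values[lo:hi] += amp * np.diff(cdf) / bin_w
            # run-length encode equal-valued neighbouring bins
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change]) * bin_w
            ends = np.concatenate([change, [n_bins]]) * bin_w
            vals = values[np.concatenate([[0], change])]
            keep = vals != 0
            segments[chrom] = (starts[keep], ends[keep], vals[keep])
        out[(cond, rep)] = SignalTrack(segments, cfg.library_size, genome)
    return out


def uniform_summits(
    genome: Genome, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """n summits uniform over the genome — the Monte-Carlo null for distribution folds."""
    chrom_names = list(genome.lengths)
    w = np.array([genome.lengths[c] for c in chrom_names], float)
    idx = rng.choice(len(chrom_names), size=n, p=w / w.sum())
    pos = [int(rng.integers(0, genome.lengths[chrom_names[i]])) for i in idx]
    return pd.DataFrame({"chrom": [chrom_names[i] for i in idx], "summit": pos})


def make_expression_and_survival(
    cfg: SimConfig, rng: np.random.Generator
) -> dict:
    """Tumour-cohort and xenograft expression plus survival metadata and truth.

    Tumour cohort: anchor ~ N(0,1) plus a mean shift for true cluster-2
    samples; block genes = rho * anchor + sqrt(1-rho^2) * noise (the cluster
    shift propagates through the anchor, preserving the planted
    correlation); all values ride on gene-specific baselines.  Xenograft:
    two groups with planted DEG shifts (``deg_in_block`` block genes plus
    ``n_deg_extra`` others).  Survival: exponential baseline, hazard scaled
    by exp(log_hr) for cluster 2 and by Gleason; independent exponential
    censoring calibrated to the requested censoring fraction.
    """
    gene_ids = _expression_gene_ids(cfg)
    n_genes = len(gene_ids)
    anchor_idx = 0
    non_anchor = np.arange(1, n_genes)
    block = np.sort(rng.choice(non_anchor, size=cfg.block_size, replace=False))
    deg_block = np.sort(rng.choice(block, size=cfg.deg_in_block, replace=False))
    rest = np.setdiff1d(non_anchor, block)
    deg_extra = np.sort(rng.choice(rest, size=cfg.n_deg_extra, replace=False))
    deg_planted = np.sort(np.concatenate([deg_block, deg_extra]))

    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, n_genes)

    # ---- tumour cohort
    n_t = cfg.n_tumor_samples
    samples = [f"T{i + 1:03d}" for i in range(n_t)]
    cluster = np.where(rng.random(n_t) < cfg.cluster2_fraction, 2, 1)
    anchor_vals = rng.normal(0.0, 1.0, n_t) + cfg.anchor_cluster_shift * (cluster == 2)
    tumor = rng.normal(0.0, 1.0, (n_genes, n_t))
    tumor[block] = cfg.rho * anchor_vals + np.sqrt(1 - cfg.rho**2) * tumor[block]
    tumor[anchor_idx] = anchor_vals
    tumor += baseline[:, None]
    tumor_expr = pd.DataFrame(tumor, index=gene_ids, columns=samples)

    # ---- xenograft (two-group DE experiment)
    n_x = 2 * cfg.xeno_n_per_group
    xsamples = [f"X{i + 1:02d}" for i in range(n_x)]
    xgroup = np.array(["EV"] * cfg.xeno_n_per_group + ["HES6"] * cfg.xeno_n_per_group)
    xeno = rng.normal(0.0, cfg.xeno_noise_sd, (n_genes, n_x))
    signs = np.ones(n_genes)
    signs[deg_extra] = rng.choice([-1.0, 1.0], size=len(deg_extra))
    shift = np.zeros(n_genes)
    shift[deg_planted] = cfg.deg_effect * signs[deg_planted]
    shift[anchor_idx] = 2 * cfg.deg_effect  # the anchor itself is overexpressed
    xeno += baseline[:, None] + np.outer(shift, (xgroup == "HES6").astype(float))
    xeno_expr = pd.DataFrame(xeno, index=gene_ids, columns=xsamples)

    # ---- survival + clinical covariates for the tumour cohort
    gleason = rng.choice([6, 7, 8, 9], size=n_t, p=[0.25, 0.45, 0.2, 0.1])
    log_rate = (
        np.log(cfg.baseline_hazard)
        + cfg.log_hr * (cluster == 2)
        + cfg.gleason_log_hr * (gleason - 7)
    )
    rate = np.exp(log_rate)
    event_time = rng.exponential(1.0 / rate)
    c = cfg.censoring_fraction
    censor_rate = c / (1 - c) * rate.mean()
    censor_time = rng.exponential(1.0 / censor_rate, n_t)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(np.round(time, 2), 0.01)

    meta = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.round(rng.normal(62, 7, n_t), 1),
            "psa": np.round(rng.lognormal(2.3, 0.8, n_t), 1),
            "gleason": gleason,
            "margin": np.where(rng.random(n_t) < 0.3, "positive", "negative"),
            "true_cluster": cluster,
        },
        index=pd.Index(samples, name="sample"),
    )
    xmeta = pd.DataFrame(
        {"group": xgroup}, index=pd.Index(xsamples, name="sample")
    )
    ids = np.array(gene_ids)
    truth = {
        "anchor": cfg.anchor,
        "block_genes": [str(g) for g in ids[block]],
        "deg_genes_planted": [str(g) for g in ids[deg_planted]],
        "signature_true": [str(g) for g in ids[deg_block]],
        "true_cluster": {s: int(cl) for s, cl in zip(samples, cluster)},
    }
    return {
        "tumor_expr": tumor_expr,
        "tumor_meta": meta,
        "xeno_expr": xeno_expr,
        "xeno_meta": xmeta,
        "truth": truth,
    }


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``.

    Emits chrom.sizes, annotation.tsv, per-replicate narrowPeak and bedGraph
    files, a samples manifest, expression/metadata TSVs, the site truth
    table and truth.yaml.  Deterministic: same config (incl. seed) gives
    byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    expr = make_expression_and_survival(cfg, rng)
    universe = list(expr["tumor_expr"].index)
    if cfg.n_genes > 0:
        ann_ids = sorted(
            str(g) for g in rng.choice(universe, size=min(cfg.n_genes, len(universe)), replace=False)
        )
    else:
        ann_ids = []
    genome, annotation = make_genome_and_annotation(cfg, rng, gene_ids=ann_ids or None)
    favored = set(expr["truth"]["deg_genes_planted"]) & set(ann_ids)
    truth_sites = make_peak_truth(cfg, genome, annotation, rng, favored_genes=favored)
    peaks = make_replicate_peaks(truth_sites, cfg, genome, rng)
    tracks = make_signal_tracks(truth_sites, cfg, genome, rng)

    paths: dict[str, Path] = {}

    def save(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    rio.write_chrom_sizes(genome, save("chrom_sizes", "chrom.sizes"))
    rio.write_annotation(annotation, save("annotation", "annotation.tsv"))
    truth_sites.to_csv(save("sites_truth", "sites_truth.tsv"), sep="\t", index=False)

    manifest_rows = []
    for (cond, rep), plist in sorted(peaks.items(), key=lambda kv: (kv[0][0].label, kv[0][1])):
        stem = f"{cond.label}_rep{rep}"
        ppath = outdir / "peaks" / f"{stem}.narrowPeak"
        tpath = outdir / "tracks" / f"{stem}.bedGraph"
        rio.write_narrowpeak([(p.interval, p.summit, p.score) for p in plist], ppath)
        rio.write_bedgraph(tracks[(cond, rep)], tpath)
        manifest_rows.append(
            {
                "sample": stem,
                "background": cond.background,
                "treatment": cond.treatment,
                "replicate": rep,
                "library_size": cfg.library_size,
                "peaks_path": f"peaks/{stem}.narrowPeak",
                "bedgraph_path": f"tracks/{stem}.bedGraph",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(save("manifest", "manifest.tsv"), sep="\t", index=False)

    rio.write_expression(expr["tumor_expr"], save("tumor_expression", "tumor_expression.tsv"))
    expr["tumor_meta"].to_csv(save("tumor_metadata", "tumor_metadata.tsv"), sep="\t")
    rio.write_expression(expr["xeno_expr"], save("xeno_expression", "xenograft_expression.tsv"))
    expr["xeno_meta"].to_csv(save("xeno_metadata", "xenograft_metadata.tsv"), sep="\t")
    with open(save("truth", "truth.yaml"), "w") as fh:
        yaml.safe_dump(expr["truth"], fh, sort_keys=True)
    return paths


def score_recovery(sites, truth: pd.DataFrame, max_dist: int = 750) -> float:
    """Fraction of planted sites whose matched consensus site carries the true class.

    Each truth summit is matched to the nearest classified consensus summit
    within ``max_dist`` bp (planted sites are spaced far apart, so matches
    are unambiguous); unmatched planted sites count as errors.
    """
    pred: dict[str, list[tuple[int, str]]] = {}
    for s in sites:
        if s.site_class is None:
            raise ValueError("sites must be classified before scoring")
        pred.setdefault(s.interval.chrom, []).append((s.summit, s.site_class.value))
    for v in pred.values():
        v.sort()
    correct = 0
    for row in truth.itertuples(index=False):
        entries = pred.get(row.chrom)
        if not entries:
            continue
        summits = [e[0] for e in entries]
        i = int(np.searchsorted(summits, row.summit))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries) and abs(summits[j] - row.summit) <= max_dist:
                if best is None or abs(summits[j] - row.summit) < abs(summits[best] - row.summit):
                    best = j
        if best is not None and entries[best][1] == row.true_class:
            correct += 1
    return correct / len(truth)


def load_peak_sets(
    manifest: pd.DataFrame, base: str | Path
) -> list[PeakSet]:
    """Materialise :class:`PeakSet` objects from a samples manifest."""
    base = Path(base)
    out = []
    for row in manifest.itertuples(index=False):
        cond = Condition(str(row.background), str(row.treatment))
        triples = rio.read_narrowpeak(base / str(row.peaks_path))
        out.append(
            PeakSet(cond, int(row.replicate), [Peak(iv, s, sc) for iv, s, sc in triples])
        )
    return out


def load_tracks(
    manifest: pd.DataFrame, base: str | Path, genome: Genome | None = None
) -> dict[Condition, list[SignalTrack]]:
    """Per-condition replicate signal tracks from a samples manifest."""
    base = Path(base)
    out: dict[Condition, list[SignalTrack]] = {}
    for row in manifest.itertuples(index=False):
        cond = Condition(str(row.background), str(row.treatment))
        track = rio.read_bedgraph(base / str(row.bedgraph_path), float(row.library_size), genome)
        out.setdefault(cond, []).append(track)
    return out
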