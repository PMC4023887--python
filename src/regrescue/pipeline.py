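"""End-to-end orchestration: simulate -> classify -> profiles/co-occurrence/
distribution -> DE -> enrichment -> signature -> survival stratification.

A single YAML config drives the run; every default is echoed into the run
manifest so a run is reproducible from its manifest alone.  Stages write
plain-text outputs (TSV/BED/YAML) under one output directory; on rerun the
expensive simulate stage is reused when the previous run recorded the same
config hash, and any stage can be skipped by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .classify import (
    CONDITIONS,
    ClassificationConfig,
    SiteClass,
    class_sets,
    classify_sites,
    consolidate_replicates,
    site_signal,
)
from .context import (
    TssBinScheme,
    UPSTREAM_FAR,
    cooccurrence_zscores,
    genomic_distribution,
    mean_profile,
    profile_matrix,
)
from .enrichment import overlap_enrichment, target_geneset
from .signature import derive_signature, differential_expression
from .simulate import SimConfig, load_peak_sets, load_tracks, simulate_all
from .survival import cox_fit, km_estimate, logrank_test, single_gene_cutpoint, two_cluster_partition

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    outdir: str = "regrescue_out"
    seed: int = 0
    data_dir: str | None = None  # existing inputs; None => simulate
    simulate: SimConfig = field(default_factory=SimConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    tss_bins: TssBinScheme = field(default_factory=TssBinScheme)
    enrichment_max_dist: int = 25_000
    enrichment_closest_only: bool = False
    deg_q_cutoff: float = 0.05
    signature_r_cutoff: float = 0.9
    signature_top_fraction: float | None = None
    signature_absolute: bool = False
    anchor: str = "HES6"
    profile_half_width: int = 1_000
    profile_bin_width: int = 10
    cutpoint_permutations: int = 0
    skip_stages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["gene_length_range"] = list(d["simulate"]["gene_length_range"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTION_BUILDERS = {
    "simulate": SimConfig,
    "classification": ClassificationConfig,
    "tss_bins": TssBinScheme,
}

_SCALAR_KEYS = {
    "outdir": str,
    "seed": int,
    "data_dir": (str, type(None)),
    "enrichment_max_dist": int,
    "enrichment_closest_only": bool,
    "deg_q_cutoff": float,
    "signature_r_cutoff": float,
    "signature_top_fraction": (float, type(None)),
    "signature_absolute": bool,
    "anchor": str,
    "profile_half_width": int,
    "profile_bin_width": int,
    "cutpoint_permutations": int,
    "skip_stages": list,
}


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse + range-check a YAML config; errors are collected and reported together.

    An empty document yields the full default config.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    errors: list[str] = []
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_BUILDERS:
            builder = _SECTION_BUILDERS[key]
            try:
                if not isinstance(value, dict):
                    raise ValueError(f"{key} must be a mapping")
                if hasattr(builder, "from_dict"):
                    kwargs[key] = builder.from_dict(value)
                else:
                    known = {f.name for f in dataclasses.fields(builder)}
                    unknown = set(value) - known
                    if unknown:
                        raise ValueError(f"unknown {key} keys: {sorted(unknown)}")
                    kwargs[key] = builder(**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
        elif key in _SCALAR_KEYS:
            expected = _SCALAR_KEYS[key]
            if key == "seed" and isinstance(value, bool):
                errors.append("seed: must be an integer")
            elif isinstance(value, int) and expected is float:
                kwargs[key] = float(value)
            elif not isinstance(value, expected if isinstance(expected, tuple) else (expected,)):
                errors.append(f"{key}: expected {expected}, got {type(value).__name__}")
            else:
                kwargs[key] = value
        else:
            errors.append(f"unknown config key: {key!r}")
    cfg = None
    if not errors:
        try:
            cfg = PipelineConfig(**kwargs)
            if not 0 < cfg.deg_q_cutoff <= 1:
                errors.append("deg_q_cutoff: must be in (0, 1]")
            if not -1 <= cfg.signature_r_cutoff:
                errors.append("signature_r_cutoff: must be >= -1")
            if cfg.enrichment_max_dist <= 0:
                errors.append("enrichment_max_dist: must be positive")
    # keep seeds compatible with 32-bit generators downstream
            if not 0 <= cfg.seed < 2**31:
                errors.append("seed: must be in [0, 2^31)")
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    # the simulate block inherits the top-level seed unless set explicitly
    if isinstance(raw.get("simulate"), dict) and "seed" not in raw["simulate"]:
        cfg.simulate.seed = cfg.seed
    elif "simulate" not in raw:
        cfg.simulate.seed = cfg.seed
    return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in dependency order and write the run manifest.

    Returns the manifest dict.  Stage outputs land under ``cfg.outdir``;
    stage names in ``cfg.skip_stages`` are skipped.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "regrescue",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def stage_done(name: str, outputs: dict[str, str]) -> None:
        manifest["stages"][name] = {"outputs": outputs}

    def skip(name: str) -> bool:
        return name in cfg.skip_stages

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            _run_stages(cfg, out, manifest, stage_done, skip)
        except Exception as exc:
            manifest["error"] = str(exc)
            raise
        finally:
            caught = [str(w.message) for w in wlist]
            manifest["warnings"] = caught
            tmp = out / "run_manifest.yaml.tmp"
            with open(tmp, "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=False)
            tmp.rename(out / "run_manifest.yaml")
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest, stage_done, skip) -> None:
    # ---- stage: simulate (or point at provided data)
    if cfg.data_dir is not None:
        data = Path(cfg.data_dir)
    else:
        data = out / "data"
        # reuse cached simulated data when a previous run used the same config
        prev = out / "run_manifest.yaml"
        cached = False
        if prev.exists() and (data / "manifest.tsv").exists():
            with open(prev) as fh:
                cached = yaml.safe_load(fh).get("config_hash") == cfg.config_hash()
        if cached:
            manifest["stages"]["simulate"] = {"cached": True}
        elif not skip("simulate"):
            paths = simulate_all(cfg.simulate, data)
            stage_done("simulate", {k: str(v) for k, v in paths.items()})
    manifest["input_checksums"] = {
        p.name: _checksum(p) for p in sorted(data.glob("*.tsv"))
    }

    genome = rio.read_chrom_sizes(data / "chrom.sizes")
    annotation = rio.read_annotation(data / "annotation.tsv")
    sample_manifest = rio.read_manifest(data / "manifest.tsv")

    # ---- stage: classify
    peak_sets = load_peak_sets(sample_manifest, data)
    tracks = load_tracks(sample_manifest, data, genome)
    sites = consolidate_replicates(peak_sets, cfg.classification)
    for s in sites:
        site_signal(s, tracks, cfg.classification)
    classify_sites(sites, cfg.classification)
    consensus = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.interval.chrom for s in sites],
            "start": [s.interval.start for s in sites],
            "end": [s.interval.end for s in sites],
            "summit": [s.summit for s in sites],
            **{
                f"support_{c.label}": [round(s.support[c], 4) for s in sites]
                for c in CONDITIONS
            },
            **{
                f"rpm_{c.label}": [round(s.signal[c], 4) for s in sites]
                for c in CONDITIONS
            },
            "class": [s.site_class.value for s in sites],
        }
    )
    consensus.to_csv(out / "consensus_sites.tsv", sep="\t", index=False)
    sets = class_sets(sites)
    for cls, ivs in sets.items():
        rio.write_bed(ivs, out / f"sites_{cls.value}.bed")
    stage_done(
        "classify",
        {"consensus": "consensus_sites.tsv", "n_sites": str(len(sites))},
    )

    by_class = {
        cls.value: [s for s in sites if s.site_class == cls]
        for cls in (SiteClass.LOST, SiteClass.RESCUED, SiteClass.ENHANCED)
    }
    nonempty = {k: v for k, v in by_class.items() if v}

    # ---- stage: profiles (mean profile per class x condition)
    if not skip("profile") and nonempty:
        rows = {}
        for cls_name, cls_sites in nonempty.items():
            for cond in CONDITIONS:
                m = profile_matrix(
                    cls_sites, tracks[cond], cond.label,
                    cfg.profile_half_width, cfg.profile_bin_width,
                )
                rows[f"{cls_name}|{cond.label}"] = mean_profile(m)
        prof = pd.DataFrame(rows).T
        prof.columns = m.positions
        prof.to_csv(out / "mean_profiles.tsv", sep="\t")
        stage_done("profile", {"mean_profiles": "mean_profiles.tsv"})

    # ---- stage: co-occurrence (classes as both tests and queries)
    if not skip("cooccur") and len(nonempty) >= 2:
        interval_sets = {k: [s.interval for s in v] for k, v in nonempty.items()}
        cooc = cooccurrence_zscores(interval_sets, interval_sets)
        cooc.raw.to_csv(out / "cooccurrence_raw.tsv", sep="\t")
        cooc.z.to_csv(out / "cooccurrence_z.tsv", sep="\t")
        stage_done(
            "cooccur",
            {"raw": "cooccurrence_raw.tsv", "z": "cooccurrence_z.tsv",
             "normalization": cooc.normalization},
        )

    # ---- stage: genomic distribution
    if not skip("distribution") and nonempty:
        dist = genomic_distribution(nonempty, genome, annotation, cfg.tss_bins)
        table = pd.concat(
            [dist.fractions, dist.background.to_frame("genome_background").T]
        )
        table.to_csv(out / "distribution_fractions.tsv", sep="\t")
        dist.fold.to_csv(out / "distribution_fold.tsv", sep="\t")
        outputs = {"fractions": "distribution_fractions.tsv", "fold": "distribution_fold.tsv"}
        if "rescued" in nonempty and "lost" in nonempty:
            pair = dist.pairwise_fold("rescued", "lost")
            pair.to_frame("rescued_vs_lost").to_csv(out / "distribution_rescued_vs_lost.tsv", sep="\t")
            outputs["rescued_vs_lost"] = "distribution_rescued_vs_lost.tsv"
            manifest["stages"].setdefault("metrics", {})[
                "rescued_vs_lost_upstream_fold"
            ] = float(pair[UPSTREAM_FAR])
        stage_done("distribution", outputs)

    # ---- stage: differential expression (xenograft two-group)
    xeno = rio.read_expression(data / "xenograft_expression.tsv")
    xmeta = rio.read_metadata(data / "xenograft_metadata.tsv")
    deg = differential_expression(
        xeno, xmeta["group"], "HES6", "EV", cfg.deg_q_cutoff
    )
    deg.table.round(6).to_csv(out / "deg_table.tsv", sep="\t", index_label="gene_id")
    rio.write_gene_list(sorted(deg.deg_set), out / "deg_list.txt")
    stage_done("deg", {"table": "deg_table.tsv", "list": "deg_list.txt",
                       "n_deg": str(len(deg.deg_set)), "method": deg.method})

    # ---- stage: target enrichment (rescued-site targets vs DEGs)
    tumor = rio.read_expression(data / "tumor_expression.tsv")
    universe = set(map(str, tumor.index))
    if not skip("enrich") and by_class["rescued"]:
        targets = target_geneset(
            by_class["rescued"], annotation, cfg.enrichment_max_dist,
            cfg.enrichment_closest_only,
        ) & universe
        degs_in_universe = deg.deg_set & universe
        if targets and degs_in_universe:
            res = overlap_enrichment(targets, degs_in_universe, universe)
            pd.DataFrame(
                [{"N": res.N, "K": res.K, "n": res.n, "k": res.k,
                  "overlap_percent": round(res.percent, 2), "pvalue": res.pvalue}]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            stage_done("enrich", {"report": "enrichment.tsv"})

    # ---- stage: signature
    sig = derive_signature(
        tumor, cfg.anchor, deg.deg_set, cfg.signature_r_cutoff,
        cfg.signature_top_fraction, cfg.signature_absolute,
    )
    rio.write_gene_list(sorted(sig.members), out / "signature_genes.txt")
    with open(out / "signature_provenance.yaml", "w") as fh:
        yaml.safe_dump(sig.provenance, fh, sort_keys=True)
    stage_done("signature", {"genes": "signature_genes.txt",
                             "provenance": "signature_provenance.yaml",
                             "n_members": str(len(sig.members))})

    # ---- stage: survival stratification
    if skip("stratify"):
        return
    meta = rio.read_metadata(data / "tumor_metadata.tsv")
    present = [g for g in sig.members if g in tumor.index]
    outputs = {}
    if len(present) >= 2:
        clusters = two_cluster_partition(tumor.loc[present])
        clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t", index_label="sample")
        outputs["clusters"] = "clusters.tsv"
        aligned = meta.loc[clusters.index]
        chi2, p = logrank_test(aligned["time"], aligned["event"].astype(bool), clusters.values)
        km_rows = []
        for label in (1, 2):
            mask = clusters.values == label
            curve = km_estimate(aligned.loc[mask, "time"], aligned.loc[mask, "event"].astype(bool))
            km_rows.append(pd.DataFrame({
                "cluster": label, "time": curve.timeline,
                "survival": curve.survival, "at_risk": curve.at_risk,
            }))
        pd.concat(km_rows).to_csv(out / "km_clusters.tsv", sep="\t", index=False)
        outputs["km"] = "km_clusters.tsv"

        cox_df = aligned[["time", "event", "age", "psa", "gleason", "margin"]].copy()
        cox_df["cluster2"] = (clusters.values == 2).astype(float)
        cox = cox_fit(cox_df)
        cox.summary.round(6).to_csv(out / "cox_summary.tsv", sep="\t", index_label="covariate")
        outputs["cox"] = "cox_summary.tsv"
        metrics = manifest["stages"].setdefault("metrics", {})
        metrics["logrank_chi2"] = float(chi2)
        metrics["logrank_p"] = float(p)
        metrics["cox_cluster_hr"] = float(cox.summary.loc["cluster2", "hr"])

    if cfg.anchor in tumor.index:
        cut = single_gene_cutpoint(
            tumor.loc[cfg.anchor].to_numpy(), meta.loc[tumor.columns, "time"].to_numpy(),
            meta.loc[tumor.columns, "event"].to_numpy(bool),
            n_permutations=cfg.cutpoint_permutations,
            rng=np.random.default_rng(cfg.seed),
        )
        pd.DataFrame(
            [{"threshold": cut.threshold, "chi2": cut.chi2, "pvalue": cut.pvalue,
              "p_permutation": cut.p_permutation}]
        ).to_csv(out / "anchor_cutpoint.tsv", sep="\t", index=False)
        outputs["anchor_cutpoint"] = "anchor_cutpoint.tsv"
    stage_done("stratify", outputs)
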