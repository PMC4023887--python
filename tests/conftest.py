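"""Shared fixtures: small genomes, per-base oracles and classified synthetic runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regrescue.intervals import Genome, Interval


@pytest.fixture
def genome() -> Genome:
    return Genome({"chr1": 10_000, "chr2": 10_000})


@pytest.fixture
def one_gene_annotation() -> pd.DataFrame:
    """Single + strand gene, TSS 5,000, on a 10 kb chromosome."""
    return pd.DataFrame(
        [{"gene_id": "G1", "chrom": "chr1", "strand": "+", "tss": 5_000,
          "start": 5_000, "end": 8_000}]
    )


# ---------------------------------------------------------------- oracles


def base_set(intervals: list[Interval]) -> set[tuple[str, int]]:
    """Per-base membership set — the independent oracle for interval algebra."""
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        out.update((iv.chrom, b) for b in range(iv.start, iv.end))
    return out


def random_intervals(rng: np.random.Generator, n: int, genome_size: int = 10_000):
    """Random interval set on a 2-chromosome toy genome of <= genome_size bp."""
    out = []
    for _ in range(n):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, genome_size - 1))
        end = int(rng.integers(start + 1, min(start + 500, genome_size) + 1))
        out.append(Interval(chrom, start, end))
    return out


@pytest.fixture(scope="session")
def classified_default_run():
    """Default-scale synthetic study run once and classified (shared, expensive)."""
    import tempfile
    from pathlib import Path

    from regrescue import io as rio
    from regrescue.classify import classify_sites, consolidate_replicates, site_signal
    from regrescue.simulate import SimConfig, load_peak_sets, load_tracks, simulate_all

    cfg = SimConfig(seed=11)
    with tempfile.TemporaryDirectory() as tmp:
        data = Path(tmp) / "data"
        simulate_all(cfg, data)
        gnm = rio.read_chrom_sizes(data / "chrom.sizes")
        manifest = rio.read_manifest(data / "manifest.tsv")
        sites = consolidate_replicates(load_peak_sets(manifest, data))
        tracks = load_tracks(manifest, data, gnm)
        for s in sites:
            site_signal(s, tracks)
        classify_sites(sites)
        truth = pd.read_csv(data / "sites_truth.tsv", sep="\t")
        annotation = rio.read_annotation(data / "annotation.tsv")
    return {"cfg": cfg, "sites": sites, "truth": truth, "genome": gnm,
            "annotation": annotation}
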