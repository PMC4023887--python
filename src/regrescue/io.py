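"""Readers and writers for the plain-text genomic formats the pipeline consumes.

BED-family files are 0-based half-open on disk, so no coordinate shift is
needed; TSS/annotation TSVs use the same convention.  All writers emit
deterministic byte streams for a given input (stable ordering, fixed float
formatting) so that seeded runs are byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import Genome, Interval, SignalTrack

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def read_chrom_sizes(path: str | Path) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return Genome(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, n in genome.lengths.items():
            fh.write(f"{name}\t{n}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ (first six columns honoured; strand from column 6 if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.empty:
        return []
    strands = df[5].astype(str) if df.shape[1] >= 6 else ["."] * len(df)
    return [
        Interval(str(c), int(s), int(e), st if st in "+-" else ".")
        for c, s, e, st in zip(df[0], df[1], df[2], strands)
    ]


def write_bed(intervals: list[Interval], path: str | Path, names: list[str] | None = None) -> None:
    """Write BED6; an empty input yields an empty (but existing) file."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_narrowpeak(path: str | Path) -> list[tuple[Interval, int, float]]:
    """Read narrowPeak as ``(interval, absolute summit, score)`` triples.

    Column 10 is the summit offset from start (-1 if absent, in which case the
    interval midpoint is used).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        strand = str(row[5]) if len(row) >= 6 and str(row[5]) in "+-" else "."
        score = float(row[4]) if len(row) >= 5 else 0.0
        offset = int(row[9]) if len(row) >= 10 else -1
        summit = start + offset if offset >= 0 else (start + end) // 2
        peaks.append((Interval(chrom, start, end, strand), summit, score))
    return peaks


def write_narrowpeak(peaks: list[tuple[Interval, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (iv, summit, score) in enumerate(peaks):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i + 1}\t{score:g}\t{iv.strand}"
                f"\t0\t-1\t-1\t{summit - iv.start}\n"
            )


def read_bedgraph(
    path: str | Path, library_size: float, genome: Genome | None = None
) -> SignalTrack:
    """Read a bedGraph into a step-function :class:`SignalTrack`."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    segments = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        segments[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(float),
        )
    return SignalTrack(segments, library_size, genome)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write non-zero segments as bedGraph (zero runs are omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chrom, strand, tss, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    bad = ~((df["tss"] >= df["start"]) & (df["tss"] <= df["end"]))
    if bad.any():
        raise ValueError(f"TSS outside gene span for {df.loc[bad, 'gene_id'].tolist()[:5]}")
    return df[ANNOTATION_COLUMNS]


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix of normalized log-intensities (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV indexed by sample id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Samples manifest: sample, background, treatment, replicate, library_size,
    peaks_path, bedgraph_path (paths relative to the manifest's directory)."""
    df = pd.read_csv(path, sep="\t")
    required = {"background", "treatment", "replicate", "library_size", "peaks_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
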