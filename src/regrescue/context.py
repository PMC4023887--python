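"""Summit-centred signal profiles, interval co-occurrence Z-scores and
TSS-relative genomic distribution.

The co-occurrence score of a test interval set against a query set is the
total base-pair overlap of their occupancies divided by the query set's total
base-pair occupancy (a strandless quantity in [0, 1]).  Because test sets
differ in size, scores are compared across queries after normalisation to
Z-scores within each test set (sample standard deviation, n-1).

Genomic distribution assigns each site, located by its summit, to one of an
ordered set of TSS-relative bins (distal upstream 500-2,000 bp, proximal
promoter 0-500 bp upstream, 0-500 bp downstream, gene body, intergenic) with
promoter bins taking precedence over gene body, relative to the nearest TSS
only.  Per-set bin fractions are compared against the whole-genome base
composition of the same bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ConsensusSite
from .intervals import Genome, Interval, SignalTrack, bp_occupancy, bp_overlap, rpm

__all__ = [
    "ProfileMatrix",
    "profile_matrix",
    "mean_profile",
    "CooccurrenceResult",
    "cooccurrence_score",
    "cooccurrence_zscores",
    "TssBinScheme",
    "assign_bin",
    "assign_bins",
    "assign_bin_codes",
    "genome_background",
    "DistributionResult",
    "genomic_distribution",
]


# ---------------------------------------------------------------- profiles


@dataclass
class ProfileMatrix:
    """Sites x positions matrix of RPM-normalised signal around summits."""

    site_ids: list[str]
    positions: np.ndarray  # bin start offsets relative to summit, bp
    values: np.ndarray  # shape (n_sites, n_bins)
    condition: str = ""

    def reorder(self, order: np.ndarray) -> "ProfileMatrix":
        return ProfileMatrix(
            [self.site_ids[i] for i in order], self.positions, self.values[order], self.condition
        )

    def order_by_mean(self) -> np.ndarray:
        """Row order of descending mean signal (stable), e.g. for heatmap sorting."""
        return np.argsort(-self.values.mean(axis=1), kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.positions)


def profile_matrix(
    sites: list[ConsensusSite],
    tracks: list[SignalTrack],
    condition: str = "",
    half_width: int = 1000,
    bin_width: int = 10,
) -> ProfileMatrix:
    """RPM signal per site in ``summit +/- half_width``, averaged over the
    given replicate tracks, binned at ``bin_width`` bp.

    Rows follow the input site order; use :meth:`ProfileMatrix.order_by_mean`
    on a reference condition's matrix to sort for display.
    """
    if 2 * half_width % bin_width != 0:
        raise ValueError("window must divide evenly into bins")
    n_bins = 2 * half_width // bin_width
    values = np.zeros((len(sites), n_bins))
    for i, site in enumerate(sites):
        rows = [
            rpm(1.0, t.library_size)
            * t.window_counts(site.interval.chrom, site.summit, half_width, n_bins)
            for t in tracks
        ]
        values[i] = np.mean(rows, axis=0)
    positions = -half_width + bin_width * np.arange(n_bins)
    return ProfileMatrix([s.site_id for s in sites], positions, values, condition)


def mean_profile(m: ProfileMatrix) -> np.ndarray:
    """Column means — the average signal profile across binding sites."""
    if m.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    return m.values.mean(axis=0)


# ---------------------------------------------------------------- co-occurrence


def cooccurrence_score(test: list[Interval], query: list[Interval]) -> float:
    """bp_overlap(test, query) / bp_occupancy(query); in [0, 1]."""
    occ = bp_occupancy(query)
    if occ == 0:
        raise ValueError("empty query set: co-occurrence score undefined")
    return bp_overlap(test, query) / occ


@dataclass
class CooccurrenceResult:
    raw: pd.DataFrame  # tests x queries, scores in [0, 1]
    z: pd.DataFrame  # row-standardised within each test set
    normalization: str = "sample standard deviation (n-1)"


def cooccurrence_zscores(
    tests: dict[str, list[Interval]], queries: dict[str, list[Interval]]
) -> CooccurrenceResult:
    """Raw co-occurrence matrix plus within-test-set Z-scores.

    Each row is standardised by its mean and *sample* standard deviation.
    A degenerate row (zero spread) yields all-zero Z with a warning.
    """
    if len(queries) < 2:
        raise ValueError("need at least 2 query sets for Z-normalisation")
    raw = pd.DataFrame(
        {q: [cooccurrence_score(tv, qv) for tv in tests.values()] for q, qv in queries.items()},
        index=list(tests),
    )
    z = raw.copy()
    for name, row in raw.iterrows():
        sd = row.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"test set {name!r}: constant co-occurrence row, Z set to 0")
            z.loc[name] = 0.0
        else:
            z.loc[name] = (row - row.mean()) / sd
    return CooccurrenceResult(raw, z)


# ---------------------------------------------------------------- TSS bins

UPSTREAM_FAR = "upstream_2000_500"
UPSTREAM_NEAR = "upstream_500_0"
DOWNSTREAM = "downstream_0_500"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


@dataclass
class TssBinScheme:
    """Strand-aware TSS-relative bins with precedence promoter > gene body > intergenic.

    Offsets are in bp from the nearest TSS, positive upstream.  The distal
    promoter bin covers offsets in ``(far_lo, far_hi]`` (default 500-2,000 bp
    upstream), the proximal bin ``(0, far_lo]``, and the downstream bin
    ``[0, down)``.
    """

    far_lo: int = 500
    far_hi: int = 2000
    down: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.far_lo < self.far_hi) or self.down <= 0:
            raise ValueError("bin boundaries must satisfy 0 < far_lo < far_hi, down > 0")

    @property
    def labels(self) -> list[str]:
        return [UPSTREAM_FAR, UPSTREAM_NEAR, DOWNSTREAM, GENE_BODY, INTERGENIC]


def _chrom_annotation(annotation: pd.DataFrame, chrom: str):
    ann = annotation[annotation["chrom"] == chrom]
    if ann.empty:
        return None
    tss = ann["tss"].to_numpy(np.int64)
    order = np.argsort(tss, kind="stable")
    starts = ann["start"].to_numpy(np.int64)
    ends = ann["end"].to_numpy(np.int64)
    gorder = np.argsort(starts, kind="stable")
    return (
        tss[order],
        (ann["strand"].to_numpy() == "-")[order],
        starts[gorder],
        np.maximum.accumulate(ends[gorder]),
    )


def assign_bin_codes(
    positions: np.ndarray,
    chrom: str,
    annotation: pd.DataFrame,
    scheme: TssBinScheme | None = None,
    genome: Genome | None = None,
) -> np.ndarray:
    """Vectorised bin assignment returning int8 codes indexing ``scheme.labels``.

    Each position is referred to its nearest TSS (ties to the lower
    coordinate); if its strand-aware offset falls in no promoter bin, it is
    gene body when inside any gene span, else intergenic.
    """
    scheme = scheme or TssBinScheme()
    positions = np.asarray(positions, dtype=np.int64)
    if genome is not None and chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    out = np.full(positions.shape, scheme.labels.index(INTERGENIC), dtype=np.int8)
    ca = _chrom_annotation(annotation, chrom)
    if ca is None:
        return out
    tss, minus, gstarts, gends_cummax = ca

    right = np.searchsorted(tss, positions)
    left = np.clip(right - 1, 0, len(tss) - 1)
    right = np.clip(right, 0, len(tss) - 1)
    pick_left = np.abs(positions - tss[left]) <= np.abs(tss[right] - positions)
    nearest = np.where(pick_left, left, right)
    # upstream offset relative to the nearest TSS, strand-aware
    u = np.where(minus[nearest], positions - tss[nearest], tss[nearest] - positions)

    in_far = (u > scheme.far_lo) & (u <= scheme.far_hi)
    in_near = (u > 0) & (u <= scheme.far_lo)
    in_down = (u <= 0) & (u > -scheme.down)

    j = np.searchsorted(gstarts, positions, side="right") - 1
    in_body = (j >= 0) & (positions < gends_cummax[np.clip(j, 0, None)])

    labels = scheme.labels
    out[in_body] = labels.index(GENE_BODY)
    out[in_down] = labels.index(DOWNSTREAM)
    out[in_near] = labels.index(UPSTREAM_NEAR)
    out[in_far] = labels.index(UPSTREAM_FAR)
    return out


def assign_bins(
    positions: np.ndarray,
    chrom: str,
    annotation: pd.DataFrame,
    scheme: TssBinScheme | None = None,
    genome: Genome | None = None,
) -> np.ndarray:
    """Bin labels (strings) for base positions on one chromosome."""
    scheme = scheme or TssBinScheme()
    codes = assign_bin_codes(positions, chrom, annotation, scheme, genome)
    return np.array(scheme.labels, dtype=object)[codes]


def assign_bin(
    position: int,
    chrom: str,
    annotation: pd.DataFrame,
    scheme: TssBinScheme | None = None,
    genome: Genome | None = None,
) -> str:
    """Bin label for a single summit position."""
    return str(assign_bins(np.array([position]), chrom, annotation, scheme, genome)[0])


def genome_background(
    genome: Genome,
    annotation: pd.DataFrame,
    scheme: TssBinScheme | None = None,
    chunk: int = 1_000_000,
) -> pd.Series:
    """Fraction of genomic bases per bin (exact, computed base-by-base in chunks)."""
    scheme = scheme or TssBinScheme()
    counts = np.zeros(len(scheme.labels), dtype=np.int64)
    for chrom, length in genome.lengths.items():
        for lo in range(0, length, chunk):
            pos = np.arange(lo, min(lo + chunk, length), dtype=np.int64)
            codes = assign_bin_codes(pos, chrom, annotation, scheme, genome)
            counts += np.bincount(codes, minlength=len(scheme.labels))
    s = pd.Series(counts.astype(float), index=scheme.labels)
    return s / s.sum()


# ---------------------------------------------------------------- distribution


@dataclass
class DistributionResult:
    """Per-set bin fractions, whole-genome background and fold enrichments."""

    fractions: pd.DataFrame  # sets x bins, rows sum to 1
    background: pd.Series  # bins, sums to 1
    fold: pd.DataFrame = field(init=False)  # fractions / background

    def __post_init__(self) -> None:
        self.fold = self.fractions.div(self.background, axis=1)

    def pairwise_fold(self, set_a: str, set_b: str) -> pd.Series:
        """Per-bin ratio of set_a's fraction over set_b's (e.g. rescued vs lost)."""
        return self.fractions.loc[set_a] / self.fractions.loc[set_b]


def genomic_distribution(
    site_sets: dict[str, list[ConsensusSite]],
    genome: Genome,
    annotation: pd.DataFrame,
    scheme: TssBinScheme | None = None,
) -> DistributionResult:
    """TSS-relative bin fractions per named site set versus whole genome.

    Sites are located by their summits.  Empty sets raise.
    """
    scheme = scheme or TssBinScheme()
    rows = {}
    for name, sites in site_sets.items():
        if not sites:
            raise ValueError(f"site set {name!r} is empty")
        counts = {label: 0 for label in scheme.labels}
        by_chrom: dict[str, list[int]] = {}
        for s in sites:
            by_chrom.setdefault(s.interval.chrom, []).append(s.summit)
        for chrom, summits in by_chrom.items():
            labels, n = np.unique(
                assign_bins(np.array(summits), chrom, annotation, scheme, genome),
                return_counts=True,
            )
            for lab, c in zip(labels, n):
                counts[str(lab)] += int(c)
        rows[name] = pd.Series(counts, dtype=float) / len(sites)
    fractions = pd.DataFrame(rows).T[scheme.labels]
    background = genome_background(genome, annotation, scheme)[scheme.labels]
    return DistributionResult(fractions, background)
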