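"""Exact interval algebra and coverage extraction for genomic binding-site analysis.

Coordinates are 0-based half-open throughout (BED convention); readers convert
into this convention and writers convert out of it.  Strand is carried on
:class:`Interval` but ignored by occupancy/overlap — the base-pair
co-occurrence statistic built on top of these primitives is strandless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genome",
    "Interval",
    "SignalTrack",
    "merge_intervals",
    "bp_occupancy",
    "bp_overlap",
    "rpm",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval ``[start, end)`` on ``chrom``.

    Invariants: ``0 <= start < end``; strand one of ``+ - .``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in _STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Chromosome names and lengths (insertion-ordered)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome has no chromosomes")
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {n}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_size(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def check(self, iv: Interval) -> None:
        """Raise if *iv* lies off any known chromosome."""
        if iv.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(f"{iv} exceeds chromosome length {self.lengths[iv.chrom]}")


def merge_intervals(
    intervals: list[Interval],
    genome: Genome | None = None,
    max_gap: int = 0,
) -> list[Interval]:
    """Merge into a disjoint sorted list; the base union is preserved exactly.

    Touching intervals (``[0,10)``, ``[10,20)``) merge (gap 0 means overlap or
    abutment).  Strand is dropped on output.  With *genome* given, inputs on
    unknown chromosomes raise.
    """
    if genome is not None:
        for iv in intervals:
            genome.check(iv)
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def bp_occupancy(intervals: list[Interval]) -> int:
    """Number of distinct bases covered (total base-pair occupancy)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def bp_overlap(set_a: list[Interval], set_b: list[Interval]) -> int:
    """Bases in the intersection of the merged unions of the two sets.

    Symmetric in its arguments.
    """
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    a_by: dict[str, list[Interval]] = {}
    for iv in a:
        a_by.setdefault(iv.chrom, []).append(iv)
    total = 0
    for chrom, bl in _group(b).items():
        al = a_by.get(chrom)
        if not al:
            continue
        i = j = 0
        while i < len(al) and j < len(bl):
            lo = max(al[i].start, bl[j].start)
            hi = min(al[i].end, bl[j].end)
            if hi > lo:
                total += hi - lo
            if al[i].end < bl[j].end:
                i += 1
            else:
                j += 1
    return total


def _group(intervals: list[Interval]) -> dict[str, list[Interval]]:
    d: dict[str, list[Interval]] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append(iv)
    return d


def rpm(count: float, library_size: float) -> float:
    """Reads-per-million normalization: ``count * 1e6 / library_size``."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return count * 1e6 / library_size


@dataclass
class SignalTrack:
    """Per-chromosome step function of read counts per bp.

    ``segments`` maps chromosome -> ``(starts, ends, values)`` arrays of
    sorted, pairwise-disjoint half-open runs with per-bp count ``values``;
    gaps carry zero signal.  ``library_size`` is the RPM denominator and need
    not equal the summed track signal (the track may cover a subset of the
    genome).
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    library_size: float
    genome: Genome | None = None
    _prefix: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for chrom, (s, e, v) in self.segments.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            if np.any(v < 0):
                raise ValueError(f"negative signal on {chrom}")
            if np.any(e <= s) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"segments on {chrom} not sorted/disjoint")
            self.segments[chrom] = (s, e, v)
            # prefix[i] = integral of the track over segments 0..i-1
            self._prefix[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])

    def _integral_to(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the step function over ``(-inf, x)``, vectorised in x."""
        if chrom not in self.segments:
            return np.zeros_like(np.asarray(x, dtype=float))
        starts, ends, values = self.segments[chrom]
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(starts, x, side="right") - 1
        out = self._prefix[chrom][np.maximum(i, 0)]
        inside = i >= 0
        ii = np.where(inside, i, 0)
        partial = np.clip(x - starts[ii], 0, ends[ii] - starts[ii]) * values[ii]
        return np.where(inside, out + partial, 0.0)

    def counts(self, chrom: str, start: int, end: int) -> float:
        """Total read count over ``[start, end)`` (clipped below at 0)."""
        start = max(start, 0)
        if end <= start:
            return 0.0
        lo, hi = self._integral_to(chrom, np.array([start, end]))
        return float(hi - lo)

    def window_counts(
        self, chrom: str, center: int, half_width: int, n_bins: int
    ) -> np.ndarray:
        """Binned counts over ``[center - half_width, center + half_width)``.

        Bin *i* sums counts over its half-open sub-window; the bins partition
        the window so their sum equals the total window count.  Windows
        extending past chromosome ends are clipped: clipped bins report the
        signal actually present.  An off-chromosome center raises.
        """
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if 2 * half_width % n_bins != 0:
            raise ValueError("window width must be divisible by n_bins")
        length = None
        if self.genome is not None and chrom in self.genome:
            length = self.genome.lengths[chrom]
        if center < 0 or (length is not None and center >= length):
            raise ValueError(f"center {center} off chromosome {chrom}")
        step = 2 * half_width // n_bins
        edges = center - half_width + step * np.arange(n_bins + 1, dtype=np.int64)
        edges = np.clip(edges, 0, length if length is not None else edges[-1])
        return np.diff(self._integral_to(chrom, edges))
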