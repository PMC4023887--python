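"""Nearest-gene target assignment and hypergeometric gene-set overlap.

A binding site's candidate target genes are all genes whose TSS lies within
``max_dist`` (default 25 kb) of the site summit; ``closest_only`` restricts
to the single nearest TSS within range.  Enrichment of a peak-target gene set
against a differentially-expressed-gene (DEG) list is scored by the upper
tail of the hypergeometric distribution over an explicit gene universe, with
the overlap percentage reported relative to the DEG list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ConsensusSite

__all__ = [
    "genes_near_site",
    "target_geneset",
    "hypergeom_tail",
    "OverlapTest",
    "overlap_enrichment",
]


def genes_near_site(
    site: ConsensusSite,
    annotation: pd.DataFrame,
    max_dist: int = 25_000,
    closest_only: bool = False,
) -> set[str]:
    """Gene ids with ``|TSS - summit| <= max_dist`` on the site's chromosome."""
    ann = annotation[annotation["chrom"] == site.interval.chrom]
    if ann.empty:
        return set()
    dist = (ann["tss"] - site.summit).abs()
    hit = ann.loc[dist <= max_dist, "gene_id"]
    if closest_only and not hit.empty:
        return {str(ann.loc[dist.idxmin(), "gene_id"])}
    return set(hit.astype(str))


def target_geneset(
    sites: list[ConsensusSite],
    annotation: pd.DataFrame,
    max_dist: int = 25_000,
    closest_only: bool = False,
) -> set[str]:
    """Deduplicated union of :func:`genes_near_site` over all sites."""
    out: set[str] = set()
    for chrom, grp in annotation.groupby("chrom"):
        tss = grp["tss"].to_numpy(np.int64)
        order = np.argsort(tss, kind="stable")
        tss = tss[order]
        ids = grp["gene_id"].to_numpy()[order]
        for s in sites:
            if s.interval.chrom != chrom:
                continue
            lo = np.searchsorted(tss, s.summit - max_dist, side="left")
            hi = np.searchsorted(tss, s.summit + max_dist, side="right")
            if hi <= lo:
                continue
            if closest_only:
                k = lo + int(np.argmin(np.abs(tss[lo:hi] - s.summit)))
                out.add(str(ids[k]))
            else:
                out.update(map(str, ids[lo:hi]))
    return out


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = marked genes, n = drawn genes, k = marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if k < 0 or k > min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
    if N < K + n - k:
        raise ValueError("overlap k too small for the given set sizes")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapTest:
    """Result of a hypergeometric overlap test between two gene sets."""

    N: int  # universe size
    K: int  # target-set size
    n: int  # query (DEG) set size
    k: int  # overlap
    percent: float  # 100 * k / n, relative to the DEG list
    pvalue: float


def overlap_enrichment(
    targets: set[str], degs: set[str], universe: set[str]
) -> OverlapTest:
    """Hypergeometric enrichment of ``targets`` against ``degs`` in ``universe``.

    Both sets must be contained in the universe (supplied explicitly to avoid
    silent universe inflation).  The p-value is symmetric in (targets, degs)
    by hypergeometric duality; this is asserted numerically.
    """
    if not targets <= universe:
        raise ValueError(f"{len(targets - universe)} target genes outside universe")
    if not degs <= universe:
        raise ValueError(f"{len(degs - universe)} DEGs outside universe")
    N, K, n = len(universe), len(targets), len(degs)
    k = len(targets & degs)
    p = hypergeom_tail(N, K, n, k)
    p_swapped = hypergeom_tail(N, n, K, k)
    if not math.isclose(p, p_swapped, rel_tol=1e-9, abs_tol=1e-300):
        raise AssertionError(f"hypergeometric symmetry violated: {p} vs {p_swapped}")
    percent = 100.0 * k / n if n else 0.0
    return OverlapTest(N, K, n, k, percent, p)
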