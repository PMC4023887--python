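"""Differential expression, anchor-gene correlation and signature derivation.

The anchor-associated signature is the intersection of two independently
obtained gene sets: (i) genes whose expression across a tumour cohort is
strongly correlated with an anchor gene (Pearson r at or above a cutoff,
default 0.9), and (ii) genes differentially expressed in a two-group model
system (Welch t-test with Benjamini-Hochberg adjustment).  The correlation
cutoff is the operative filter; an optional ``top_fraction`` truncation
(keep only the top fraction of genes by r) is available for platforms where
a fixed-size list is wanted, and all cutoffs and intermediate set sizes are
recorded in the signature's provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegResult",
    "differential_expression",
    "bh_adjust",
    "correlate_with_anchor",
    "Signature",
    "derive_signature",
]


@dataclass
class DegResult:
    """Per-gene moderation-free two-sample test results with BH q-values."""

    table: pd.DataFrame  # columns: effect, pvalue, qvalue
    deg_set: set[str]
    q_cutoff: float
    group_a: str
    group_b: str
    method: str = "Welch t-test + Benjamini-Hochberg"


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    q_cutoff: float = 0.05,
) -> DegResult:
    """Per-gene Welch t-test of group_a vs group_b on log expression, BH-adjusted.

    ``groups`` maps sample id -> group label; both groups need >= 2 samples.
    The effect is the mean log difference (group_a minus group_b).
    """
    cols_a = [s for s in expr.columns if groups.get(s) == group_a]
    cols_b = [s for s in expr.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(cols_a)} in {group_a!r}, "
            f"{len(cols_b)} in {group_b!r}"
        )
    a = expr[cols_a].to_numpy(float)
    b = expr[cols_b].to_numpy(float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both genes: no evidence
    q = bh_adjust(p)
    table = pd.DataFrame({"effect": effect, "pvalue": p, "qvalue": q}, index=expr.index)
    deg_set = set(table.index[table["qvalue"] <= q_cutoff].astype(str))
    return DegResult(table, deg_set, q_cutoff, group_a, group_b)


def correlate_with_anchor(
    expr: pd.DataFrame, anchor: str, method: str = "pearson"
) -> pd.Series:
    """Correlation of each gene's profile with the anchor's across samples.

    The anchor itself is excluded from the returned ranking; zero-variance
    genes are reported as NaN.  Needs >= 3 samples.
    """
    if anchor not in expr.index:
        raise ValueError(f"anchor gene {anchor!r} not in matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    x = expr.to_numpy(float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    a = x[expr.index.get_loc(anchor)]
    a = a - a.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((a**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ a) / denom
    out = pd.Series(r, index=expr.index, name="r").drop(index=anchor)
    return out


@dataclass
class Signature:
    """An anchor-correlated, differentially-expressed gene set with provenance."""

    anchor: str
    members: list[str]
    correlated_set: list[str]
    deg_set: list[str]
    r_cutoff: float
    top_fraction: float | None
    provenance: dict = field(default_factory=dict)


def derive_signature(
    expr: pd.DataFrame,
    anchor: str,
    deg_set: set[str],
    r_cutoff: float = 0.9,
    top_fraction: float | None = None,
    absolute: bool = False,
    method: str = "pearson",
) -> Signature:
    """Intersect anchor-correlated genes with a DEG list.

    ``correlated_set`` = genes with (signed, or absolute if ``absolute``)
    correlation >= ``r_cutoff``; if ``top_fraction`` is given and the set is
    larger than that fraction of ranked genes, it is truncated to the
    highest-r genes.  ``members`` = correlated_set intersected with
    ``deg_set``.  Deterministic given the matrix; an empty correlated set
    warns and yields an empty signature.
    """
    if not deg_set:
        raise ValueError("deg_set is empty")
    r = correlate_with_anchor(expr, anchor, method=method)
    score = r.abs() if absolute else r
    score = score.dropna()
    correlated = score[score >= r_cutoff].sort_values(ascending=False)
    truncated = False
    if top_fraction is not None and len(correlated) > 0:
        n_top = math.ceil(top_fraction * len(score))
        if len(correlated) > n_top:
            correlated = correlated.iloc[:n_top]
            truncated = True
    if correlated.empty:
        warnings.warn(f"no genes correlated with {anchor!r} at r >= {r_cutoff}")
    correlated_ids = [str(g) for g in correlated.index]
    members = [g for g in correlated_ids if g in deg_set]
    provenance = {
        "anchor": anchor,
        "correlation_method": method,
        "absolute": absolute,
        "r_cutoff": r_cutoff,
        "top_fraction": top_fraction,
        "truncated_to_top_fraction": truncated,
        "n_genes_ranked": int(len(score)),
        "n_correlated": len(correlated_ids),
        "n_deg": len(deg_set),
        "n_members": len(members),
    }
    return Signature(
        anchor, members, correlated_ids, sorted(deg_set), r_cutoff, top_fraction, provenance
    )
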