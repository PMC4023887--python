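"""Survival stratification: Kaplan-Meier, logrank, maximally selected
cut-points, two-cluster expression partitioning and Cox regression.

Patients are split either by a single gene's expression at the threshold
maximising the logrank statistic (the standard reading of "recursive
partitioning" for a two-group survival figure; candidate cuts are restricted
to the 10th-90th expression percentiles and an optional permutation p-value
accounts for the post hoc selection), or into two clusters by Ward/Euclidean
hierarchical clustering of per-gene-standardised signature expression.
Association with outcome is quantified by the Mantel-Haenszel logrank test
and by Cox proportional-hazards models (Efron tie handling) with clinical
covariates, using listwise deletion of missing covariate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "CutpointResult",
    "single_gene_cutpoint",
    "two_cluster_partition",
    "CoxResult",
    "cox_fit",
]


def _check_times(time: np.ndarray) -> None:
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")


@dataclass
class KmCurve:
    """Product-limit survival estimate: S non-increasing, S(0) = 1."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Censored times reduce the at-risk count without creating steps.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("no records")
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    timeline = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(float)
    return KmCurve(timeline, surv, at_risk)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Mantel-Haenszel logrank over >= 2 groups: (chi-square, p).

    p is from a chi-square with (n_groups - 1) degrees of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    _check_times(time)
    if len(np.unique(group)) < 2:
        raise ValueError("need >= 2 groups")
    if not event.any():
        raise ValueError("no events: logrank undefined")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CutpointResult:
    threshold: float
    chi2: float
    pvalue: float  # unadjusted (the cut is selected post hoc)
    labels: np.ndarray  # "low" / "high" per sample
    p_permutation: float | None = None


def single_gene_cutpoint(
    expression,
    time,
    event,
    lower_q: float = 0.10,
    upper_q: float = 0.90,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Maximally selected logrank cut on one gene's expression.

    Scans all inter-sample midpoints with expression between the
    ``lower_q``-``upper_q`` percentiles and returns the threshold with the
    largest logrank chi-square (ties broken toward the smallest midpoint).
    ``n_permutations > 0`` additionally estimates a selection-adjusted
    p-value by re-running the scan on permuted expression.
    """
    x = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if x.size < 10:
        raise ValueError("need >= 10 samples for cut-point selection")
    if np.all(x == x[0]):
        raise ValueError("constant expression: no cut-point exists")
    _check_times(time)

    def best_cut(values: np.ndarray) -> tuple[float, float, float]:
        lo, hi = np.quantile(values, [lower_q, upper_q])
        uniq = np.unique(values)
        mids = (uniq[:-1] + uniq[1:]) / 2
        mids = mids[(mids >= lo) & (mids <= hi)]
        if mids.size == 0:
            mids = np.array([(uniq[0] + uniq[-1]) / 2])
        top = (0.0, 1.0, float(mids[0]))
        for m in mids:
            labels = np.where(values > m, "high", "low")
            if len(np.unique(labels)) < 2:
                continue
            chi2, p = logrank_test(time, event, labels)
            if chi2 > top[0]:
                top = (chi2, p, float(m))
        return top

    chi2, p, threshold = best_cut(x)
    labels = np.where(x > threshold, "high", "low")
    p_perm = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        exceed = sum(
            best_cut(rng.permutation(x))[0] >= chi2 for _ in range(n_permutations)
        )
        p_perm = (exceed + 1) / (n_permutations + 1)
    return CutpointResult(threshold, chi2, p, labels, p_perm)


def two_cluster_partition(expr: pd.DataFrame) -> pd.Series:
    """Split samples into 2 clusters on signature-gene expression.

    Genes (rows) are standardised, samples clustered by Ward linkage on
    Euclidean distance, and the tree cut at two.  Cluster 2 is the cluster
    with the higher mean standardised signature expression (the "high"
    group), making labels deterministic and order-invariant.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 signature genes present in the matrix")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = expr.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant signature genes")
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    labels = fcluster(linkage(z.T, method="ward"), t=2, criterion="maxclust")
    means = [z[:, labels == c].mean() for c in (1, 2)]
    if means[0] > means[1]:
        labels = 3 - labels
    return pd.Series(labels, index=expr.columns, name="cluster")


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary.

    ``summary`` has one row per covariate: coef, hr (= exp(coef)), its 95%
    CI, and p.  ``n_dropped`` counts records removed listwise for missing
    covariates.
    """

    summary: pd.DataFrame
    n_used: int
    n_dropped: int
    ties: str = "efron"
    _fitter: CoxPHFitter = field(default=None, repr=False)


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> CoxResult:
    """Fit a Cox model with Efron tie handling.

    ``df`` holds durations, event flags and covariate columns (categorical
    string columns are dummy-coded against their first level).  Rows with
    missing covariates are dropped listwise (count reported).  Degenerate
    inputs — constant covariates, < 2 events, separation/non-convergence —
    raise with a diagnostic.
    """
    covariates = covariates or [c for c in df.columns if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col] + covariates].copy()
    n_total = len(data)
    data = data.dropna()
    n_dropped = n_total - len(data)
    _check_times(data[duration_col].to_numpy(float))
    if int(data[event_col].sum()) < 2:
        raise ValueError("need >= 2 events for a Cox fit")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant across samples")
    data = pd.get_dummies(data, columns=[c for c in covariates if data[c].dtype == object],
                          drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise RuntimeError(f"Cox fit failed (possible separation): {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower95": s["exp(coef) lower 95%"],
            "hr_upper95": s["exp(coef) upper 95%"],
            "pvalue": s["p"],
        }
    )
    return CoxResult(summary, len(data), n_dropped, _fitter=cph)
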