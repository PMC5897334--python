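"""Per-miRNA differential expression and unsupervised sample clustering.

Two scans are provided, matching the two arms of a smoking/exposure panel
design:

* :func:`unpaired_de_scan` — cross-sectional two-sample t-test (e.g. smokers
  vs never-smokers) with Benjamini–Hochberg FDR and fold change;
* :func:`paired_de_scan` — two-sided paired t-test on within-subject
  differences (e.g. baseline vs 4 weeks of exposure), producing the per-miRNA
  p_DE values consumed by the pair-level combined statistic.

The unpaired test defaults to the classical pooled-variance t (the
"parametric p-value" convention of array-analysis suites); Welch's unequal
variance form is available via ``equal_var=False``.  Fold change is defined
as ``base ** (mean_a - mean_b)`` on log-scale input (default base 2), so a
fold change of 1 means no change.

:func:`hierarchical_cluster` reproduces the standard array-tools heat-map
clustering: agglomerative clustering of samples under correlation distance
(1 − Pearson) with average linkage, cut into two clusters and scored against
the known groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, SampleMetadata

__all__ = [
    "DEResult",
    "ClusteringReport",
    "bh_fdr",
    "unpaired_de_scan",
    "paired_de_scan",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class DEResult:
    """One feature's differential-expression record.

    ``degenerate`` marks features where the test statistic was undefined
    (zero variance); the reported p-value is then 1 (no evidence) so that a
    scan never aborts mid-matrix.
    """

    feature: str
    p_value: float
    fdr: float
    fold_change: float
    direction: int  # sign of (mean_a - mean_b), or of the mean paired difference
    degenerate: bool = False


@dataclass(frozen=True)
class ClusteringReport:
    """Two-cluster agglomerative clustering of samples, scored against groups.

    ``agreement`` is the fraction of samples whose cluster matches their known
    group under the best of the two label assignments, so it lies in
    [0.5, 1] for two balanced groups and is invariant to label naming.
    """

    linkage: np.ndarray
    labels: dict[str, int]
    agreement: float


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Adjusted values are monotone in the ranks and clipped at 1.  Input
    p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_fdr expects a non-empty 1-D array of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[(~np.isfinite(p)) | (p <= 0) | (p > 1)]
        raise ValueError(f"p-values outside (0, 1]: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(matrix: ExpressionMatrix, meta: SampleMetadata, label: str) -> np.ndarray:
    ids = meta.samples_for(label)
    index = {s: i for i, s in enumerate(matrix.samples)}
    return np.array([index[s] for s in ids if s in index], dtype=int)


def unpaired_de_scan(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
    log_base: float = 2.0,
) -> list[DEResult]:
    """Two-sample t-test per feature between two sample groups.

    Returns one :class:`DEResult` per feature in matrix order, with two-sided
    p-values, BH-FDR across the scan, and fold change
    ``log_base ** (mean_a - mean_b)``.  Features where both groups are
    constant are degenerate: p = 1 when the means agree as well (no
    evidence), p floored near 0 when they differ deterministically.
    """
    meta.validate_against(matrix)
    if not matrix.is_complete():
        raise ValueError("matrix has missing values; impute or filter first")
    cols_a = _group_columns(matrix, meta, group_a)
    cols_b = _group_columns(matrix, meta, group_b)
    for label, cols in ((group_a, cols_a), (group_b, cols_b)):
        if cols.size < 2:
            raise ValueError(f"group {label!r} has {cols.size} sample(s); need >= 2")
    a = matrix.values[:, cols_a]
    b = matrix.values[:, cols_b]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant rows
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    scale = np.maximum(1.0, np.abs(mean_diff))
    degenerate = (a.std(axis=1) <= 1e-12 * scale) & (b.std(axis=1) <= 1e-12 * scale)
    # zero pooled variance: equal means carry no evidence (p = 1); unequal
    # means separate deterministically (p at the floor)
    p = np.where(degenerate & np.isclose(mean_diff, 0.0), 1.0, p)
    p = np.where(degenerate & ~np.isclose(mean_diff, 0.0), np.nextafter(0.0, 1.0), p)
    p = np.where(~np.isfinite(p), np.nextafter(0.0, 1.0), p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    fdr = bh_fdr(p)
    fold = np.power(float(log_base), mean_diff)
    return [
        DEResult(
            feature=f,
            p_value=float(p[i]),
            fdr=float(fdr[i]),
            fold_change=float(fold[i]),
            direction=int(np.sign(mean_diff[i])),
            degenerate=bool(degenerate[i]),
        )
        for i, f in enumerate(matrix.features)
    ]


def paired_de_scan(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    baseline: str,
    followup: str,
    log_base: float = 2.0,
) -> list[DEResult]:
    """Two-sided paired t-test per feature on within-subject differences.

    Every subject must contribute exactly one sample at each timepoint
    (unmatched subjects are reported by id); at least 3 subjects are
    required.  The p-value is the p_DE consumed by the pair-level combined
    statistic.  Features whose differences have zero variance are degenerate:
    p = 1 when all differences are zero, floored near 0 otherwise.
    """
    meta.validate_against(matrix)
    if not matrix.is_complete():
        raise ValueError("matrix has missing values; impute or filter first")
    pairs = meta.paired_subjects(baseline, followup)
    if len(pairs) < 3:
        raise ValueError(f"paired t-test needs >= 3 subjects, got {len(pairs)}")
    index = {s: i for i, s in enumerate(matrix.samples)}
    cols_b = np.array([index[b] for _, b, _ in pairs], dtype=int)
    cols_f = np.array([index[f] for _, _, f in pairs], dtype=int)
    diffs = matrix.values[:, cols_f] - matrix.values[:, cols_b]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant differences
        res = stats.ttest_rel(matrix.values[:, cols_f], matrix.values[:, cols_b], axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    mean_diff = diffs.mean(axis=1)
    degenerate = diffs.std(axis=1) <= 1e-12 * np.maximum(1.0, np.abs(mean_diff))
    p = np.where(degenerate & np.isclose(mean_diff, 0.0), 1.0, p)
    p = np.where(degenerate & ~np.isclose(mean_diff, 0.0), np.nextafter(0.0, 1.0), p)
    p = np.where(~np.isfinite(p), np.nextafter(0.0, 1.0), p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    fdr = bh_fdr(p)
    fold = np.power(float(log_base), mean_diff)
    return [
        DEResult(
            feature=f,
            p_value=float(p[i]),
            fdr=float(fdr[i]),
            fold_change=float(fold[i]),
            direction=int(np.sign(mean_diff[i])),
            degenerate=bool(degenerate[i]),
        )
        for i, f in enumerate(matrix.features)
    ]


def hierarchical_cluster(matrix: ExpressionMatrix, meta: SampleMetadata) -> ClusteringReport:
    """Cluster samples by correlation distance; score the two-cluster cut.

    Distance between samples is 1 − Pearson correlation of their expression
    profiles; linkage is average (UPGMA).  The tree is cut into two clusters
    and ``agreement`` is computed against the metadata condition labels under
    the best of the two cluster↔group assignments.
    """
    meta.validate_against(matrix)
    if not matrix.is_complete():
        raise ValueError("matrix has missing values; impute or filter first")
    if matrix.n_samples < 4:
        raise ValueError(f"need >= 4 samples to cluster, got {matrix.n_samples}")
    X = matrix.values.T  # samples x features
    sds = X.std(axis=1)
    constant = np.where(sds == 0)[0]
    if constant.size:
        names = [matrix.samples[i] for i in constant]
        raise ValueError(f"constant sample vector(s), correlation undefined: {names}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(matrix.samples, cut)}
    groups = np.array([meta.condition_of(s) for s in matrix.samples])
    group_names = sorted(set(groups))
    if len(group_names) != 2:
        raise ValueError(f"agreement scoring needs exactly 2 groups, got {group_names}")
    g = (groups == group_names[1]).astype(int)
    c = (cut == 2).astype(int)
    match = float(np.mean(g == c))
    return ClusteringReport(linkage=linkage, labels=labels, agreement=max(match, 1.0 - match))
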