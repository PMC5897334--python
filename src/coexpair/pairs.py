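"""Coordinated differential-expression statistics for miRNA pairs.

Mean-level tests on a small paired panel can miss an exposure effect when
only a subset of subjects responds.  The pair-level statistic implemented
here instead asks, for every pair of miRNAs, whether the two are strongly
co-expressed *and* each shows some evidence of a pre/post shift, and fuses
the three evidence streams with a weighted Stouffer z-score:

    Z(miR1, miR2) = [ w_DE * Z_DE(miR1) + w_DE * Z_DE(miR2)
                      + w_CC * Z_CC(miR1, miR2) ]
                    / sqrt(w_DE^2 + w_DE^2 + w_CC^2)

where ``Z_DE(miR) = Phi^-1(1 - p_DE)`` is the normal z-score of the miRNA's
paired-t differential-expression p-value, and ``Z_CC`` is obtained the same
way from ``p_CC``, the tail probability of the pair's Spearman rank
correlation.  Default weights are ``w_CC = 1`` and ``w_DE = 0.5``: the
co-expression evidence counts double each single differential-expression
stream.  Z is converted back to an upper-tail normal p-value, adjusted by
Benjamini–Hochberg across the full all-pairs scan, and pairs are selected at
``FDR < 0.01`` with the side condition that at least one member has
``p_DE < 0.05``.

Conventions that matter and are deliberately fixed here:

* ``p_CC`` is **one-sided on |cc|** (half the two-sided p of the t
  approximation ``t = cc * sqrt((n-2)/(1-cc^2))`` with ``n-2`` df).  This is
  the convention under which strongly *anti*-correlated pairs also score
  highly — the scan treats coordinated expression as coordination of
  magnitude, not sign.
* All Phi^-1 / Phi evaluations use survival-function forms, so p-values down
  to the floor of 1e-300 map to finite z without 1 − CDF cancellation.
* Pair ordering is deterministic (lexicographic by feature id), making scan
  outputs byte-for-byte reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr, paired_de_scan
from .matrix import ExpressionMatrix, SampleMetadata

__all__ = [
    "P_FLOOR",
    "StoufferWeights",
    "PairStat",
    "z_from_p",
    "p_from_z",
    "spearman_cc",
    "spearman_p",
    "stouffer_pair_z",
    "pair_scan",
    "pair_scan_from_stats",
    "select_pairs",
    "pairs_to_frame",
    "write_pairs",
]

#: Probabilities below this are floored (and flagged) rather than returned as
#: 0, keeping every z-score finite.
P_FLOOR = 1e-300

#: Upper clip for component p-values entering the z-transform; a degenerate
#: p = 1 maps to a large negative but finite z.
_P_CEIL = 1.0 - 1e-12

#: Table-style column order for pair outputs.
PAIR_COLUMNS = (
    "miRNA",
    "miRNA2",
    "P_DE(miRNA1)",
    "P_DE(miRNA2)",
    "CC",
    "P_CC",
    "Min_ttest_pval",
    "Stouffer_Zscore",
    "pval_Zscore",
    "FDR_Zscore",
)


@dataclass(frozen=True)
class StoufferWeights:
    """Weights of the two evidence streams in the combined z-score.

    ``w_de`` weights each of the two differential-expression z-scores,
    ``w_cc`` the co-expression z-score.  The normalizing denominator is
    ``sqrt(w_de^2 + w_de^2 + w_cc^2)`` — ``sqrt(1.5)`` at the defaults
    (w_de = 0.5, w_cc = 1), which keeps Z standard normal when the three
    component p-values are independent and uniform.
    """

    w_de: float = 0.5
    w_cc: float = 1.0

    def __post_init__(self) -> None:
        if self.w_de <= 0 or self.w_cc <= 0:
            raise ValueError("weights must be positive")

    @property
    def denominator(self) -> float:
        return math.sqrt(2.0 * self.w_de**2 + self.w_cc**2)


@dataclass(frozen=True)
class PairStat:
    """Full evidence record for one miRNA pair (one output-table row)."""

    mirna1: str
    mirna2: str
    p_de1: float
    p_de2: float
    cc: float
    p_cc: float
    z: float
    p_z: float
    fdr_z: float = float("nan")
    flags: tuple[str, ...] = field(default=())

    @property
    def min_p_de(self) -> float:
        return min(self.p_de1, self.p_de2)


def z_from_p(p):
    """Normal z-score of an upper-tail probability: ``Phi^-1(1 - p)``.

    Evaluated as the inverse survival function, so extreme p (down to
    ~1e-300) map to accurate finite z.  Accepts scalars or arrays; every
    value must lie strictly inside (0, 1).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"p-value(s) outside (0, 1): {arr[(arr <= 0) | (arr >= 1) | ~np.isfinite(arr)] if arr.ndim else arr}")
    out = stats.norm.isf(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def p_from_z(z):
    """Upper-tail standard normal probability ``P(Z > z)`` via the survival
    function (no 1 − CDF cancellation for large z)."""
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("z must be finite")
    out = stats.norm.sf(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def spearman_cc(x, y) -> float:
    """Spearman rank correlation (average ranks for ties) of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError(f"need n >= 4 samples, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values present; impute first")
    for name, v in (("x", x), ("y", y)):
        if np.all(v == v[0]):
            raise ValueError(f"constant vector {name}: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_p(cc: float, n: int, method: str = "t") -> float:
    """Tail probability of a Spearman correlation, one-sided on ``|cc|``.

    ``method="t"`` (default) uses the t approximation
    ``t = |cc| * sqrt((n-2) / (1-cc^2))`` with ``n-2`` degrees of freedom and
    returns ``P(T > t)`` — half the two-sided p.  ``method="exact"``
    enumerates all ``n!`` rank permutations (n <= 10) and returns
    ``P(rho >= |cc|)`` under the permutation null.

    ``|cc| = 1`` cannot be mapped through the t approximation; the documented
    underflow floor ``P_FLOOR`` is returned instead.
    """
    if not -1.0 <= cc <= 1.0:
        raise ValueError(f"correlation {cc} outside [-1, 1]")
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        return _spearman_p_exact(abs(cc), n)
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    a = abs(cc)
    if a == 1.0:
        return P_FLOOR
    t = a * math.sqrt((n - 2) / (1.0 - a * a))
    return max(float(stats.t.sf(t, n - 2)), P_FLOOR)


def _spearman_p_exact(abs_cc: float, n: int) -> float:
    """One-sided permutation tail P(rho >= |cc|) by full enumeration."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        d2 = float(np.sum((base - base[list(perm)]) ** 2))
        rho = 1.0 - d2 / denom
        if rho >= abs_cc - 1e-12:
            count += 1
        total += 1
    return count / total


def stouffer_pair_z(
    p_de1: float,
    p_de2: float,
    p_cc: float,
    weights: StoufferWeights | None = None,
) -> float:
    """Weighted Stouffer combination of a pair's three evidence p-values.

    Each p-value is mapped to ``Phi^-1(1 - p)`` and the three z-scores are
    combined with weights ``(w_de, w_de, w_cc)``, normalized by
    ``sqrt(2 w_de^2 + w_cc^2)``.  Symmetric in the two differential-expression
    streams.  Every p must lie strictly in (0, 1).
    """
    weights = weights or StoufferWeights()
    for name, p in (("p_de1", p_de1), ("p_de2", p_de2), ("p_cc", p_cc)):
        if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 < p < 1.0):
            raise ValueError(f"{name} = {p!r} outside (0, 1)")
    num = (
        weights.w_de * z_from_p(p_de1)
        + weights.w_de * z_from_p(p_de2)
        + weights.w_cc * z_from_p(p_cc)
    )
    return num / weights.denominator


def _clip_p(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip p into [P_FLOOR, 1-1e-12]; return (clipped, was_clipped)."""
    clipped = np.clip(p, P_FLOOR, _P_CEIL)
    return clipped, clipped != p


def pair_scan(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    weights: StoufferWeights | None = None,
    baseline: str = "baseline",
    followup: str = "week4",
) -> list[PairStat]:
    """Score every miRNA pair of a preprocessed paired-design matrix.

    Per feature, the paired-t p_DE (baseline vs follow-up) is computed once
    and reused; per pair, the Spearman correlation across all samples and its
    one-sided-on-|cc| tail probability feed the weighted Stouffer z.  The
    combined p_z values are BH-adjusted over all C(m, 2) pairs.  Pairs are
    returned in lexicographic feature-id order.

    The matrix must be complete (run ``filter_missing`` then
    ``impute_feature_mean`` first) and contain at least 2 features.
    """
    weights = weights or StoufferWeights()
    if matrix.n_features < 2:
        raise ValueError(f"need >= 2 features to form pairs, got {matrix.n_features}")
    de = paired_de_scan(matrix, meta, baseline=baseline, followup=followup)
    p_de = {r.feature: r.p_value for r in de}

    order = np.argsort(np.array(matrix.features, dtype=object))
    feats = [matrix.features[i] for i in order]
    X = matrix.values[order]

    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    sds = ranks.std(axis=1)
    constant = np.where(sds == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant feature(s), rank correlation undefined: {[feats[i] for i in constant]}"
        )
    rho = np.corrcoef(ranks)

    m = len(feats)
    iu, ju = np.triu_indices(m, k=1)
    cc = np.clip(rho[iu, ju], -1.0, 1.0)
    n = matrix.n_samples
    a = np.abs(cc)
    perfect = a >= 1.0 - 1e-15
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        tstat = np.where(perfect, np.inf, a * np.sqrt((n - 2) / np.maximum(1.0 - a * a, 1e-308)))
    p_cc = np.where(perfect, P_FLOOR, stats.t.sf(tstat, n - 2))
    p_cc = np.maximum(p_cc, P_FLOOR)

    p1 = np.array([p_de[feats[i]] for i in iu])
    p2 = np.array([p_de[feats[j]] for j in ju])
    p1c, clip1 = _clip_p(p1)
    p2c, clip2 = _clip_p(p2)
    z = (
        weights.w_de * stats.norm.isf(p1c)
        + weights.w_de * stats.norm.isf(p2c)
        + weights.w_cc * stats.norm.isf(p_cc)
    ) / weights.denominator
    p_z = np.maximum(stats.norm.sf(z), P_FLOOR)
    fdr_z = bh_fdr(p_z)

    out: list[PairStat] = []
    for k in range(len(iu)):
        flags: list[str] = []
        if perfect[k]:
            flags.append("perfect_correlation")
        if clip1[k] or clip2[k]:
            flags.append("clipped_p_de")
        out.append(
            PairStat(
                mirna1=feats[iu[k]],
                mirna2=feats[ju[k]],
                p_de1=float(p1[k]),
                p_de2=float(p2[k]),
                cc=float(cc[k]),
                p_cc=float(p_cc[k]),
                z=float(z[k]),
                p_z=float(p_z[k]),
                fdr_z=float(fdr_z[k]),
                flags=tuple(flags),
            )
        )
    return out


def pair_scan_from_stats(
    stats_table: pd.DataFrame,
    weights: StoufferWeights | None = None,
) -> list[PairStat]:
    """Combined z / p / FDR from precomputed per-pair evidence.

    ``stats_table`` needs columns ``p_de1``, ``p_de2``, ``p_cc`` and may carry
    ``mirna1``, ``mirna2`` and ``cc``; the FDR universe is exactly the rows
    given.  This entry point lets a published pair-evidence table be
    re-scored without the underlying expression data.
    """
    weights = weights or StoufferWeights()
    required = {"p_de1", "p_de2", "p_cc"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"stats table missing column(s): {sorted(missing)}")
    df = stats_table.reset_index(drop=True)
    zs = np.array(
        [
            stouffer_pair_z(float(r.p_de1), float(r.p_de2), float(r.p_cc), weights)
            for r in df.itertuples()
        ]
    )
    p_z = np.maximum(stats.norm.sf(zs), P_FLOOR)
    fdr_z = bh_fdr(p_z)
    out = []
    for k, row in df.iterrows():
        out.append(
            PairStat(
                mirna1=str(row.get("mirna1", f"pair{k}_a")),
                mirna2=str(row.get("mirna2", f"pair{k}_b")),
                p_de1=float(row["p_de1"]),
                p_de2=float(row["p_de2"]),
                cc=float(row.get("cc", np.nan)),
                p_cc=float(row["p_cc"]),
                z=float(zs[k]),
                p_z=float(p_z[k]),
                fdr_z=float(fdr_z[k]),
            )
        )
    return out


def select_pairs(
    scan: list[PairStat],
    fdr_threshold: float = 0.01,
    p_de_threshold: float = 0.05,
) -> list[PairStat]:
    """Pairs with ``fdr_z < fdr_threshold`` and at least one member's
    ``p_DE < p_de_threshold``, sorted by combined p ascending."""
    if not scan:
        raise ValueError("empty pair scan")
    kept = [
        s
        for s in scan
        if s.fdr_z < fdr_threshold and s.min_p_de < p_de_threshold
    ]
    return sorted(kept, key=lambda s: (s.p_z, s.mirna1, s.mirna2))


def pairs_to_frame(pairs: list[PairStat]) -> pd.DataFrame:
    """Pair records as a DataFrame in the fixed output column order."""
    return pd.DataFrame(
        {
            "miRNA": [p.mirna1 for p in pairs],
            "miRNA2": [p.mirna2 for p in pairs],
            "P_DE(miRNA1)": [p.p_de1 for p in pairs],
            "P_DE(miRNA2)": [p.p_de2 for p in pairs],
            "CC": [p.cc for p in pairs],
            "P_CC": [p.p_cc for p in pairs],
            "Min_ttest_pval": [p.min_p_de for p in pairs],
            "Stouffer_Zscore": [p.z for p in pairs],
            "pval_Zscore": [p.p_z for p in pairs],
            "FDR_Zscore": [p.fdr_z for p in pairs],
        },
        columns=list(PAIR_COLUMNS),
    )


def write_pairs(pairs: list[PairStat], path) -> None:
    """Write pair records as TSV in the fixed column order."""
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
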