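"""Shared fixtures and independent oracle routines.

The oracles here deliberately avoid the code paths they check:
``inv_norm_upper`` inverts the erfc-based normal CDF by bisection (no scipy
inverse functions), ``bh_stepup`` is a literal transcription of the
Benjamini–Hochberg step-up definition, and ``spearman_oracle`` is
rank-then-Pearson by hand.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from coexpair import ExpressionMatrix, SampleMetadata


# ---------------------------------------------------------------- oracles


def norm_upper_tail(z: float) -> float:
    """P(Z > z) via erfc — no scipy."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def inv_norm_upper(p: float) -> float:
    """z with P(Z > z) = p, by bisection on the erfc form."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if norm_upper_tail(mid) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def stouffer_oracle(p_de1: float, p_de2: float, p_cc: float,
                    w_de: float = 0.5, w_cc: float = 1.0) -> float:
    """Literal transcription of the weighted combination formula."""
    z1 = inv_norm_upper(p_de1)
    z2 = inv_norm_upper(p_de2)
    zc = inv_norm_upper(p_cc)
    return (w_de * z1 + w_de * z2 + w_cc * zc) / math.sqrt(w_de**2 + w_de**2 + w_cc**2)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Brute-force BH: adj_i = min_{j: p_(j) >= p_(i)} min(1, m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, m * p[idx] / (rank_from_top + 1))
        adjusted[idx] = min(running, 1.0)
    return adjusted


def rank_average(x: np.ndarray) -> np.ndarray:
    """Average ranks by hand (ties share the mean of their positions)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of hand-computed average ranks."""
    rx = rank_average(np.asarray(x, dtype=float))
    ry = rank_average(np.asarray(y, dtype=float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_matrix(values, features=None, samples=None, mask=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    f, s = values.shape
    return ExpressionMatrix(
        features=features or [f"m{i}" for i in range(f)],
        samples=samples or [f"s{j}" for j in range(s)],
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool),
    )


def paired_metadata(n_subjects: int, baseline="baseline", followup="week4") -> SampleMetadata:
    rows = []
    for j in range(n_subjects):
        subj = f"S{j + 1:02d}"
        rows.append({"sample_id": f"{subj}_{baseline}", "subject_id": subj, "condition": baseline})
        rows.append({"sample_id": f"{subj}_{followup}", "subject_id": subj, "condition": followup})
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_paired(rng):
    """8 features x 6 subjects paired design, complete, no structure."""
    n_subj = 6
    meta = paired_metadata(n_subj)
    values = rng.normal(10, 1, size=(8, 2 * n_subj))
    matrix = make_matrix(values, samples=list(meta.sample_ids))
    return matrix, meta


@pytest.fixture
def two_group_meta():
    rows = []
    for j in range(5):
        rows.append({"sample_id": f"a{j}", "subject_id": f"ua{j}", "condition": "smoker"})
    for j in range(5):
        rows.append({"sample_id": f"b{j}", "subject_id": f"ub{j}", "condition": "never"})
    return SampleMetadata(pd.DataFrame(rows))
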