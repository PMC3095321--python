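"""Statistical primitives: Wilcoxon rank-sum, Pearson correlation, broadness.

The broadness score of a gene is the area under its own max-1-normalized,
length-normalized body coverage profile: a profile flat at its maximum scores
``std_len`` (maximally broad), a one-position spike scores 1. Because each
gene is scaled by its own maximum, the score compares shapes and is invariant
to peak height; cohort-level peak normalization is a separate display step.

Two cohorts of broadness scores are compared with the two-sided Wilcoxon
rank-sum test: exact by enumeration for small tie-free samples, otherwise the
normal approximation with mid-ranks, tie-corrected variance, and a continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_LIMIT = 12  # exact enumeration when n_a + n_b <= this and no ties


@dataclass(frozen=True)
class WilcoxonResult:
    """Rank-sum test result; U is the Mann-Whitney statistic for group A."""

    U: float
    n_a: int
    n_b: int
    z: float
    p: float
    method: str


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Ties get mid-ranks. With ``n_a + n_b <= exact_limit`` and no ties the
    two-sided p is computed by enumerating every assignment of ranks to group
    A; otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction is used. The p-value is invariant under strictly
    monotone transforms of the pooled scores, and swapping the groups maps
    U -> n_a*n_b - U with the same p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    ranks = sps.rankdata(pooled)
    U = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    mu = n_a * n_b / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var > 0:
        z = float(np.sign(U - mu) * max(abs(U - mu) - 0.5, 0.0) / np.sqrt(var))
    else:
        z = 0.0

    if n <= exact_limit and not has_ties:
        # Enumerate all C(n, n_a) ways the pooled ranks 1..n can fall in group A.
        target = U
        count_le = count_ge = total = 0
        offset = n_a * (n_a + 1) / 2.0
        for combo in combinations(range(1, n + 1), n_a):
            u = sum(combo) - offset
            total += 1
            if u <= target:
                count_le += 1
            if u >= target:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        method = "exact"
    else:
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(U=U, n_a=n_a, n_b=n_b, z=z, p=p, method=method)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def broadness_score(gene_profile: Sequence[float]) -> float:
    """Area under a gene's max-1-normalized body profile (sum over positions)."""
    v = np.asarray(gene_profile, dtype=float)
    m = v.max(initial=-np.inf)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("all-zero gene profile: broadness undefined")
    return float(v.sum() / m)


def broadness_scores(matrix: np.ndarray) -> np.ndarray:
    """Per-gene broadness over a (genes x positions) matrix; zero rows dropped."""
    matrix = np.asarray(matrix, dtype=float)
    maxima = matrix.max(axis=1)
    keep = maxima > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%d all-zero gene profiles excluded from broadness scoring", n_dropped)
    return matrix[keep].sum(axis=1) / maxima[keep]
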