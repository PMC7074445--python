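"""Cross-marker and cross-caste agreement: correlations of sPC1 scores and
of distance matrices.

sPCA axes are sign-arbitrary, so score comparisons report both the signed
Pearson r and the sign-aligned |r| (axis b flipped to make the correlation
nonnegative, with the flip recorded).  Distance-matrix comparisons use the
lower-triangle entries; the parametric p-value treats those entries as
independent (the convention of the source analyses), so a Mantel permutation
p-value over row/column permutations is offered alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ordination import DistanceMatrix


@dataclass
class ConcordanceReport:
    pair: tuple[str, str]
    r: float  # signed Pearson r
    p_value: float  # parametric two-sided p (t transform, n-2 df)
    n: int
    method: str  # vector_pearson | matrix_pearson | mantel
    r_aligned: float | None = None  # |r| after sign alignment (score vectors)
    flipped: bool | None = None
    mantel_p: float | None = None
    mantel_nperm: int | None = None


def score_correlation(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    ids_a: list[str] | None = None,
    ids_b: list[str] | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> ConcordanceReport:
    """Pearson correlation of two matched score vectors (e.g. two sPC1s)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if ids_a is not None or ids_b is not None:
        if ids_a is None or ids_b is None:
            raise ValueError("provide ids for both vectors or neither")
        if set(ids_a) != set(ids_b):
            unmatched = sorted(set(ids_a) ^ set(ids_b))
            raise ValueError(f"unmatched sample ids: {unmatched[:10]}")
        order = {s: i for i, s in enumerate(ids_b)}
        b = b[[order[s] for s in ids_a]]
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1D of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 matched scores")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant score vector: correlation undefined")
    res = stats.pearsonr(a, b)
    return ConcordanceReport(
        pair=labels,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(a),
        method="vector_pearson",
        r_aligned=abs(float(res.statistic)),
        flipped=bool(res.statistic < 0),
    )


def matrix_correlation(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    mantel_nperm: int = 0,
    rng_seed: int | None = None,
    labels: tuple[str, str] = ("D1", "D2"),
) -> ConcordanceReport:
    """Pearson r over the lower triangles of two labelled distance matrices.

    The parametric p mirrors the plain-Pearson convention; with
    ``mantel_nperm`` > 0 a two-sided Mantel permutation p (joint row/column
    permutations of the second matrix) is also computed, which respects the
    non-independence of triangle entries.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    m = len(d1.labels)
    if m < 4:
        raise ValueError("need at least 4 labels")
    x = d1.lower_triangle()
    y = d2.lower_triangle()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    res = stats.pearsonr(x, y)
    report = ConcordanceReport(
        pair=labels,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        method="matrix_pearson",
    )
    if mantel_nperm > 0:
        if rng_seed is None:
            raise ValueError("rng_seed is required for the Mantel permutation p")
        rng = np.random.default_rng(rng_seed)
        tri = np.tril_indices(m, k=-1)
        obs = abs(report.r)
        count = 0
        v2 = d2.values
        for _ in range(mantel_nperm):
            perm = rng.permutation(m)
            yp = v2[np.ix_(perm, perm)][tri]
            if yp.std() == 0:
                count += 1
                continue
            r = np.corrcoef(x, yp)[0, 1]
            if abs(r) >= obs:
                count += 1
        report.mantel_p = (1.0 + count) / (1.0 + mantel_nperm)
        report.mantel_nperm = mantel_nperm
        report.method = "mantel"
    return report
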