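"""Canonical variate analysis of colony mean shapes and site distance matrices.

Procrustes coordinates are rank-deficient (2k - 4 for k 2D landmarks after
similarity alignment), so the CVA first projects onto leading principal
components before solving the generalized eigenproblem that maximizes
between-group relative to pooled within-group variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .procrustes_core import ColonyMeanShape, procrustes_distance


@dataclass
class CvaResult:
    canonical_axes: np.ndarray  # (p, n_axes) loadings in the original variable space
    scores: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # (n_axes,) descending
    group_labels: list[str]
    n_pca_used: int = 0


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray  # (m, m)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape must match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        self.values = v

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]


def _as_flat(colony_shapes: Sequence[ColonyMeanShape] | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(colony_shapes, np.ndarray):
        x = np.asarray(colony_shapes, dtype=float)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        return x, None
    shapes = list(colony_shapes)
    x = np.stack([c.mean_landmarks.ravel() for c in shapes])
    return x, [c.colony_id for c in shapes]


def cva(
    colony_shapes: Sequence[ColonyMeanShape] | np.ndarray,
    site_of_colony: Mapping[str, str] | Sequence[str],
    n_pca_keep: int | None = None,
    var_explained: float = 0.999,
) -> CvaResult:
    """Canonical variate analysis of shapes grouped by site.

    Variables (flattened landmark coordinates) are first projected onto the
    leading principal components — either ``n_pca_keep`` of them or enough to
    explain ``var_explained`` of the variance — to remove the rank deficiency
    of Procrustes data.  Canonical axes then solve the generalized
    eigenproblem B v = lambda W v with B the between-group and W the pooled
    within-group covariance; eigenvalues are returned in descending order and
    scores for every colony.
    """
    x, ids = _as_flat(colony_shapes)
    n, p = x.shape
    if ids is not None and isinstance(site_of_colony, Mapping):
        groups = [site_of_colony[c] for c in ids]
    elif isinstance(site_of_colony, Mapping):
        raise ValueError("pass group labels as a sequence when shapes are a bare array")
    else:
        groups = [str(g) for g in site_of_colony]
    if len(groups) != n:
        raise ValueError("one group label per colony required")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = {g: groups.count(g) for g in labels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"every group needs >= 2 members; too small: {small}")

    xc = x - x.mean(axis=0)
    # PCA pre-projection to the leading components
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank_tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > rank_tol).sum())
    if n_pca_keep is None:
        var = s**2
        cum = np.cumsum(var) / var.sum()
        q = int(np.searchsorted(cum, var_explained) + 1)
    else:
        q = int(n_pca_keep)
    # cap at the matrix rank and the pooled within-group degrees of freedom,
    # otherwise the within-group covariance cannot be positive definite
    q = min(q, rank, n - len(labels))
    if q < 1:
        raise ValueError("no variance left after PCA projection")
    basis = vt[:q].T  # (p, q)
    y = xc @ basis  # (n, q)

    garr = np.asarray(groups)
    g = len(labels)
    grand = y.mean(axis=0)
    sw = np.zeros((q, q))
    sb = np.zeros((q, q))
    for lab in labels:
        yi = y[garr == lab]
        mi = yi.mean(axis=0)
        d = yi - mi
        sw += d.T @ d
        diff = (mi - grand)[:, None]
        sb += yi.shape[0] * (diff @ diff.T)
    sw /= n - g
    sb /= g - 1

    try:
        evals, evecs = scipy.linalg.eigh(sb, sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:  # pragma: no cover
        raise ValueError(
            "singular pooled within-group covariance; retry with smaller n_pca_keep"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, q)
    order = order[:n_axes]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = (y - grand) @ evecs
    axes = basis @ evecs
    return CvaResult(
        canonical_axes=axes,
        scores=scores,
        eigenvalues=evals,
        group_labels=groups,
        n_pca_used=q,
    )


def site_mean_shapes(
    colony_shapes: Sequence[ColonyMeanShape],
    site_of_colony: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Per-site per-landmark mean of colony mean shapes (site order sorted)."""
    unmapped = [c.colony_id for c in colony_shapes if c.colony_id not in site_of_colony]
    if unmapped:
        raise ValueError(f"colonies with no site assignment: {unmapped[:5]}")
    groups: dict[str, list[np.ndarray]] = {}
    for c in colony_shapes:
        groups.setdefault(site_of_colony[c.colony_id], []).append(c.mean_landmarks)
    empty = set(site_of_colony.values()) - set(groups)
    if empty:
        warnings.warn(f"sites with zero colonies excluded: {sorted(empty)[:5]}", RuntimeWarning)
    return {site: np.mean(shapes, axis=0) for site, shapes in sorted(groups.items())}


def pairwise_procrustes(site_means: Mapping[str, np.ndarray]) -> DistanceMatrix:
    """All pairwise partial Procrustes distances between site mean shapes."""
    labels = list(site_means)
    if len(labels) < 2:
        raise ValueError("need >= 2 sites for a distance matrix")
    m = len(labels)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = procrustes_distance(site_means[labels[i]], site_means[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)
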