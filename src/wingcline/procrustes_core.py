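"""Generalized Procrustes superimposition and Procrustes shape distances.

Shapes are k x 2 landmark configurations.  Superimposition removes
translation (centering on the centroid), size (rescaling to unit centroid
size, the root summed squared landmark deviation) and orientation (proper
rotation; reflections are never allowed, since all wings are right
forewings).  The iterative GPA aligns every configuration to a consensus
that is recomputed as the per-landmark mean and renormalized each round,
until the consensus stabilizes.

Distances are *partial* Procrustes distances: the residual root sum of
squares between two unit-size, centered, optimally rotated configurations
(the MorphoJ convention for group differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration


class DegenerateShapeError(ValueError):
    """All landmarks coincident: shape has zero centroid size."""


@dataclass
class AlignedShapeSet:
    """Procrustes-superimposed configurations with their consensus."""

    shapes: np.ndarray  # (n, k, 2), centered, unit centroid size, rotated
    consensus: np.ndarray  # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,) original centroid sizes
    ids: list[str]
    iterations_run: int
    converged: bool

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]


@dataclass
class ColonyMeanShape:
    colony_id: str
    mean_landmarks: np.ndarray  # (k, 2)
    n_wings_used: int
    caste: str = ""


def filter_missing(
    configs: Iterable[LandmarkConfiguration],
) -> tuple[list[LandmarkConfiguration], list[LandmarkConfiguration]]:
    """Partition wings into complete (kept) and any-landmark-missing (removed)."""
    kept, removed = [], []
    for c in configs:
        (kept if c.is_complete else removed).append(c)
    return kept, removed


def centroid_size(coords: np.ndarray) -> float:
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def preshape(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Center on the centroid and scale to unit centroid size.

    Returns the preshape and the original centroid size.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("preshape requires complete, finite landmarks")
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0.0 or not np.isfinite(size):
        raise DegenerateShapeError("all landmarks coincident: centroid size is 0")
    return centered / size, size


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimizing ||a @ R - b||_F over rotations.

    Closed-form orthogonal solution with the reflection suppressed (the
    smaller singular direction is sign-flipped when the unconstrained
    optimum is a reflection).  A rank-deficient cross-covariance makes the
    optimum ambiguous; the SVD solution (smallest-angle branch) is returned
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = a.T @ b
    u, s, vt = np.linalg.svd(m)
    if s[-1] <= s[0] * 1e-12:
        warnings.warn(
            "rank-deficient cross-covariance: optimal rotation is ambiguous",
            RuntimeWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    return u @ np.diag([1.0, d]) @ vt


def _rotate_onto(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each (k,2) shape in ``shapes`` onto ``target``, vectorized.

    For 2D proper rotations the optimum has the closed form
    theta = arg(sum conj(z_shape) * z_target) in complex coordinates.
    """
    z = shapes[..., 0] + 1j * shapes[..., 1]  # (n, k)
    w = target[:, 0] + 1j * target[:, 1]  # (k,)
    c = (np.conj(z) * w).sum(axis=1)  # (n,)
    theta = np.angle(c)
    rot = np.exp(1j * theta)[:, None]
    zr = z * rot
    return np.stack([zr.real, zr.imag], axis=-1)


def gpa(
    shapes: Sequence[LandmarkConfiguration] | np.ndarray,
    ids: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of complete configurations.

    Algorithm: convert to preshapes; initialize the consensus as the first
    preshape; rotate every shape onto the consensus; recompute the consensus
    as the per-landmark mean rescaled to unit centroid size; iterate until
    the RMS landmark displacement of the consensus falls below ``tol`` or
    ``max_iter`` is reached.
    """
    if isinstance(shapes, np.ndarray):
        arr = np.asarray(shapes, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(arr.shape[0])]
    else:
        configs = list(shapes)
        incomplete = [c.wing_id for c in configs if not c.is_complete]
        if incomplete:
            raise ValueError(
                f"GPA requires complete configurations; missing landmarks in {incomplete[:5]}"
            )
        arr = np.stack([c.landmarks for c in configs])
        if ids is None:
            ids = [c.wing_id for c in configs]
    if arr.ndim != 3 or arr.shape[-1] != 2 or arr.shape[0] < 1:
        raise ValueError("expected a non-empty (n, k, 2) array of configurations")

    n, k, _ = arr.shape
    pre = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        pre[i], sizes[i] = preshape(arr[i])

    consensus = pre[0].copy()
    converged = False
    iterations = 0
    aligned = pre
    for iterations in range(1, max_iter + 1):
        aligned = _rotate_onto(pre, consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm == 0:
            raise DegenerateShapeError("consensus collapsed to a point")
        new_consensus /= norm
        shift = np.sqrt(((new_consensus - consensus) ** 2).sum() / k)
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    aligned = _rotate_onto(pre, consensus)
    return AlignedShapeSet(
        shapes=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        ids=list(ids),
        iterations_run=iterations,
        converged=converged,
    )


def procrustes_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Root of the minimized sum of squared differences between the unit-size,
    centered, optimally rotated shapes.  Symmetric; zero iff the shapes are
    identical up to a similarity transform.
    """
    a, _ = preshape(s1)
    b, _ = preshape(s2)
    r = optimal_rotation(a, b)
    return float(np.sqrt(((a @ r - b) ** 2).sum()))


def colony_means(
    aligned: AlignedShapeSet,
    colony_of_wing: Mapping[str, str],
    caste_of_colony: Mapping[str, str] | None = None,
) -> list[ColonyMeanShape]:
    """Per-colony, per-landmark arithmetic means of aligned shapes.

    Colony order follows first appearance in the aligned set.  Wings with no
    colony assignment raise; a colony mapped by the metadata but absent from
    the aligned set is simply not produced (it has zero wings), with a
    warning.
    """
    unmapped = [w for w in aligned.ids if w not in colony_of_wing]
    if unmapped:
        raise ValueError(f"wings with no colony assignment: {unmapped[:5]}")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for idx, wing in enumerate(aligned.ids):
        colony = colony_of_wing[wing]
        if colony not in groups:
            groups[colony] = []
            order.append(colony)
        groups[colony].append(idx)
    empty = set(colony_of_wing.values()) - set(order)
    if empty:
        warnings.warn(
            f"colonies with zero wings excluded: {sorted(empty)[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    out = []
    for colony in order:
        idx = groups[colony]
        out.append(
            ColonyMeanShape(
                colony_id=colony,
                mean_landmarks=aligned.shapes[idx].mean(axis=0),
                n_wings_used=len(idx),
                caste=(caste_of_colony or {}).get(colony, ""),
            )
        )
    return out
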