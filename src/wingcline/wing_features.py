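"""Inter-landmark distance features for the spatial analysis.

The spatial PCA of the morphometric data does not run on raw Procrustes
coordinates but on the distances between *proximal* landmark pairs —
junctions adjacent along the forewing venation — averaged per colony.
The default pair list follows the venation connectivity of the stylized
19-landmark wing and ships as an editable table, so the feature set is an
explicit, reproducible choice rather than an implicit one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmark_io import N_LANDMARKS
from .procrustes_core import ColonyMeanShape

# Landmark pairs adjacent along the venation sketch (1-based, i < j):
# outer margin arc 1..8, posterior return arc 8..15..1, and the inner
# median/cubital chain with its crossveins.
DEFAULT_PROXIMAL_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8),
    (8, 9), (9, 10), (10, 11), (11, 12), (12, 13), (13, 14), (14, 15), (1, 15),
    (2, 16), (16, 17), (17, 18), (18, 19), (6, 19),
    (13, 16), (12, 17), (11, 18), (10, 19),
)


@dataclass(frozen=True)
class ProximalPairList:
    """Validated list of 1-based landmark index pairs, i < j, no duplicates."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i <= N_LANDMARKS and 1 <= j <= N_LANDMARKS):
                raise ValueError(f"pair ({i},{j}) out of landmark range 1..{N_LANDMARKS}")
            if i >= j:
                raise ValueError(f"pair ({i},{j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i},{j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def column_names(self) -> list[str]:
        return [f"d_{i}_{j}" for i, j in self.pairs]


DEFAULT_PAIRS = ProximalPairList(DEFAULT_PROXIMAL_PAIRS)


def read_pair_list(path: str | Path) -> ProximalPairList:
    """Read a pair list CSV with columns i,j (1-based indices)."""
    df = pd.read_csv(path)
    if not {"i", "j"}.issubset(df.columns):
        raise ValueError("pair list must have columns i,j")
    return ProximalPairList(tuple((int(r.i), int(r.j)) for r in df.itertuples()))


def write_pair_list(pairs: ProximalPairList, path: str | Path) -> None:
    pd.DataFrame(pairs.pairs, columns=["i", "j"]).to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """Rows of features (morphometric distances or SNP calls) with coordinates.

    ``coords`` holds one (latitude, longitude) per row, aligned with
    ``row_ids``; this is the shared container handed to the spatial PCA for
    either marker.
    """

    row_ids: list[str]
    column_ids: list[str]
    values: np.ndarray  # (n, p)
    coords: np.ndarray  # (n, 2) latitude, longitude

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.values.shape
        if len(self.row_ids) != n or len(self.column_ids) != p:
            raise ValueError("ids do not match values shape")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2) aligned with rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def proximal_distances(
    colony_mean: np.ndarray, pairs: ProximalPairList = DEFAULT_PAIRS
) -> np.ndarray:
    """Euclidean distance for each listed landmark pair, in list order."""
    coords = np.asarray(colony_mean, dtype=float)
    if coords.shape != (N_LANDMARKS, 2):
        raise ValueError(f"expected a ({N_LANDMARKS}, 2) mean shape")
    if not np.all(np.isfinite(coords)):
        raise ValueError("mean shape must be complete (finite)")
    idx = np.asarray(pairs.pairs) - 1
    return np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)


def build_feature_matrix(
    colony_shapes: Sequence[ColonyMeanShape],
    pairs: ProximalPairList = DEFAULT_PAIRS,
    coords_of_colony: Mapping[str, tuple[float, float]] | None = None,
) -> FeatureMatrix:
    """One row of proximal-pair distances per colony, aligned with coordinates.

    Shapes are expected to be GPA-aligned colony means (unit centroid-size
    scale), so the features measure shape, not size.
    """
    if coords_of_colony is None:
        raise ValueError("coords_of_colony is required")
    missing = [c.colony_id for c in colony_shapes if c.colony_id not in coords_of_colony]
    if missing:
        raise ValueError(f"colonies with no coordinates: {missing[:10]}")
    values = np.stack([proximal_distances(c.mean_landmarks, pairs) for c in colony_shapes])
    coords = np.asarray([coords_of_colony[c.colony_id] for c in colony_shapes], dtype=float)
    return FeatureMatrix(
        row_ids=[c.colony_id for c in colony_shapes],
        column_ids=pairs.column_names,
        values=values,
        coords=coords,
    )
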