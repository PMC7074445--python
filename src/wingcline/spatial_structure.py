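"""Spatial connectivity, Moran's I, spatial PCA and Monte-Carlo structure tests.

The spatial PCA (sPCA) seeks axes maximizing the product of variance and
spatial autocorrelation (Moran's I) of the scores: with Xc the column-
centered data and L the row-normalized spatial weight matrix, it is the
eigen-decomposition of H = Xc' (L + L') Xc / (2n).  Axes with positive
eigenvalues carry *global* structure (neighbours alike: clines, patches),
negative ones *local* structure (neighbours contrasting).

Whether either kind of structure is statistically supported is decided by a
Monte-Carlo test on the max(t) statistic: project the data columns onto the
Moran eigenvector basis of the connectivity network, average the squared
correlations (R^2) per eigenvector, smooth the profile over adjacent
eigenvectors, and take the maximum over the positive-I (global) or
negative-I (local) half; the null distribution comes from jointly permuting
the rows of the data matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .wing_features import FeatureMatrix

EARTH_RADIUS_KM = 6371.0088


@dataclass
class ConnectionNetwork:
    """K-nearest-neighbour spatial weights over sample coordinates."""

    coords: np.ndarray  # (n, 2) latitude, longitude in decimal degrees
    weights: np.ndarray  # (n, n), zero diagonal
    row_normalized: bool
    k: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.coords.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape must match coordinates")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.row_normalized:
            sums = self.weights.sum(axis=1)
            nz = sums > 0
            if not np.allclose(sums[nz], 1.0, atol=1e-12):
                raise ValueError("row_normalized network has rows not summing to 1")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def row_normalize(self) -> "ConnectionNetwork":
        if self.row_normalized:
            return self
        sums = self.weights.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return ConnectionNetwork(self.coords, self.weights / sums, True, self.k)


@dataclass
class MoranEigenbasis:
    """Orthonormal spatial patterns of a network, each with its own Moran's I.

    Eigenvectors of the doubly centered symmetrized weight matrix, restricted
    to the orthogonal complement of the constant vector, sorted by eigenvalue
    descending (most positively autocorrelated pattern first).
    """

    vectors: np.ndarray  # (n, n-1), orthonormal, orthogonal to 1
    eigenvalues: np.ndarray  # (n-1,) descending
    morans_i_of_vector: np.ndarray  # (n-1,)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray  # descending (most positive first)
    axis_loadings: np.ndarray  # (p, n_axes)
    scores: np.ndarray  # (n, n_axes)
    lag_scores: np.ndarray  # (n, n_axes) = L @ scores
    morans_i_per_axis: np.ndarray
    variance_per_axis: np.ndarray
    row_ids: list[str] | None = None


@dataclass
class StructureTestResult:
    kind: str  # "global" | "local"
    observed_max_t: float
    permuted_max_t: np.ndarray
    p_value: float
    nperm: int
    seed: int | None = None


def great_circle_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances in km for (lat, lon) decimal degrees."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def knn_network(
    coords: np.ndarray, k: int = 5, row_normalize: bool = True
) -> ConnectionNetwork:
    """Symmetrized K-nearest-neighbour graph over geographic coordinates.

    Each node is linked to its k nearest neighbours by great-circle distance;
    an edge present in either direction is kept.  Exactly tied distances
    (e.g. duplicate coordinates) are broken by node index, with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} nodes, got {n}")
    d = great_circle_distances(coords)
    np.fill_diagonal(d, np.inf)
    if np.any(d[np.isfinite(d)] == 0):
        warnings.warn(
            "duplicate coordinates: nearest neighbours tie-broken by node index",
            RuntimeWarning,
            stacklevel=2,
        )
    w = np.zeros((n, n))
    # stable argsort => ties resolved by index order
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    w[rows, nn.ravel()] = 1.0
    w = np.maximum(w, w.T)  # symmetrize: keep edge if present either way
    net = ConnectionNetwork(coords, w, False, k)
    return net.row_normalize() if row_normalize else net


def morans_i(x: np.ndarray, network: ConnectionNetwork) -> float:
    """Moran's spatial autocorrelation I of values x on the network.

    I = (n / sum(W)) * sum_ij W_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = np.asarray(x, dtype=float)
    n = network.n_nodes
    if x.shape != (n,):
        raise ValueError("x must have one value per network node")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for constant x (zero variance)")
    w = network.weights
    return float(n / w.sum() * (z @ w @ z) / denom)


def moran_eigenbasis(network: ConnectionNetwork) -> MoranEigenbasis:
    """Eigen-analysis of the spatial connectivity.

    Diagonalizes (I - 11'/n) (W + W')/2 (I - 11'/n) on the complement of the
    constant vector, via an explicit orthonormal (Helmert) basis of that
    complement so the returned vectors are exactly orthogonal to 1.
    """
    n = network.n_nodes
    if n < 3:
        raise ValueError("Moran eigenbasis needs at least 3 nodes")
    s = (network.weights + network.weights.T) / 2.0
    # Helmert sub-basis: orthonormal complement of the constant vector
    h = np.zeros((n, n - 1))
    for j in range(1, n):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    m = h.T @ s @ h
    evals, evecs = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    vectors = h @ evecs[:, order]
    total_w = network.weights.sum()
    mi = np.array([n * lam / total_w for lam in evals])
    return MoranEigenbasis(vectors=vectors, eigenvalues=evals, morans_i_of_vector=mi)


def spca(
    features: FeatureMatrix | np.ndarray, network: ConnectionNetwork
) -> SpcaResult:
    """Spatial principal component analysis.

    Eigen-decomposition of H = Xc' (L + L') Xc / (2n) with L the row-
    normalized weights.  For every axis the eigenvalue equals the variance of
    its scores times their Moran's I; positive eigenvalues are global axes,
    negative ones local.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        row_ids = features.row_ids
    else:
        x = np.asarray(features, dtype=float)
        row_ids = None
    n = network.n_nodes
    if x.shape[0] != n:
        raise ValueError("feature rows must match network nodes")
    net = network.row_normalize()
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        x = x[:, keep]
    xc = x - x.mean(axis=0)
    l = net.weights
    h = xc.T @ (l + l.T) @ xc / (2.0 * n)
    evals, evecs = np.linalg.eigh((h + h.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    scores = xc @ evecs
    lag = l @ scores
    variance = (scores**2).mean(axis=0)
    mi = np.full(evals.shape, np.nan)
    for a in range(scores.shape[1]):
        if variance[a] > 0:
            mi[a] = morans_i(scores[:, a], net)
    return SpcaResult(
        eigenvalues=evals,
        axis_loadings=evecs,
        scores=scores,
        lag_scores=lag,
        morans_i_per_axis=mi,
        variance_per_axis=variance,
        row_ids=row_ids,
    )


def _smooth_profile(r2: np.ndarray, window: int) -> np.ndarray:
    """Edge-truncated moving average along the last axis (eigenvalue order)."""
    if window <= 1:
        return r2
    half = window // 2
    m = r2.shape[-1]
    lo = np.maximum(0, np.arange(m) - half)
    hi = np.minimum(m, np.arange(m) + half + 1)
    csum = np.concatenate([np.zeros(r2.shape[:-1] + (1,)), np.cumsum(r2, axis=-1)], axis=-1)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def _max_t_profiles(
    x: np.ndarray,
    basis: MoranEigenbasis,
    nperm: int,
    rng: np.random.Generator,
    window: int,
    batch: int = 200,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Observed and permuted max(t) for both sign classes in one pass.

    t_j is the mean over data columns of the squared Pearson correlation with
    Moran eigenvector j, smoothed over eigenvectors adjacent in eigenvalue
    order; max is taken over eigenvectors with positive (global) or negative
    (local) Moran's I.  Permutations shuffle data rows jointly.
    """
    n, p = x.shape
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    if np.any(norms == 0):
        xc = xc[:, norms > 0]
        norms = norms[norms > 0]
        p = xc.shape[1]
        if p == 0:
            raise ValueError("all feature columns constant")
    xs = xc / norms  # unit-norm centered columns
    u = basis.vectors  # unit-norm, orthogonal to 1 => correlations are plain dots
    pos = basis.morans_i_of_vector > 0
    neg = basis.morans_i_of_vector < 0
    if not pos.any() or not neg.any():
        raise ValueError("network eigenbasis lacks one Moran's I sign class")

    def both_max(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # mat: (..., p, n-1) correlations
        r2 = (mat**2).mean(axis=-2)  # (..., n-1)
        sm = _smooth_profile(r2, window)
        return sm[..., pos].max(axis=-1), sm[..., neg].max(axis=-1)

    obs_g, obs_l = both_max(xs.T @ u)
    perm_g = np.empty(nperm)
    perm_l = np.empty(nperm)
    done = 0
    while done < nperm:
        b = min(batch, nperm - done)
        idx = np.stack([rng.permutation(n) for _ in range(b)])  # (b, n)
        xp = xs[idx]  # (b, n, p)
        corr = np.einsum("bnp,nk->bpk", xp, u, optimize=True)
        g, loc = both_max(corr)
        perm_g[done : done + b] = g
        perm_l[done : done + b] = loc
        done += b
    observed = {"global": float(obs_g), "local": float(obs_l)}
    permuted = {"global": perm_g, "local": perm_l}
    return observed, permuted


def structure_test_pair(
    features: FeatureMatrix | np.ndarray,
    network: ConnectionNetwork,
    nperm: int = 10_000,
    rng_seed: int | None = None,
    window: int = 3,
) -> tuple[StructureTestResult, StructureTestResult]:
    """Global and local structure tests sharing one set of permutations."""
    if rng_seed is None:
        raise ValueError("rng_seed is required for permutation tests")
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    basis = moran_eigenbasis(network)
    rng = np.random.default_rng(rng_seed)
    observed, permuted = _max_t_profiles(x, basis, nperm, rng, window)
    results = []
    for kind in ("global", "local"):
        obs = observed[kind]
        perm = permuted[kind]
        p = (1.0 + np.count_nonzero(perm >= obs)) / (1.0 + nperm)
        results.append(
            StructureTestResult(
                kind=kind,
                observed_max_t=obs,
                permuted_max_t=perm,
                p_value=float(p),
                nperm=nperm,
                seed=rng_seed,
            )
        )
    return results[0], results[1]


def structure_test(
    features: FeatureMatrix | np.ndarray,
    network: ConnectionNetwork,
    kind: str = "global",
    nperm: int = 10_000,
    rng_seed: int | None = None,
    window: int = 3,
) -> StructureTestResult:
    """Monte-Carlo max(t) test for global or local spatial structure.

    p = (1 + #{permuted >= observed}) / (1 + nperm), so the smallest
    attainable p with 10,000 permutations is ~1e-4.
    """
    if kind not in ("global", "local"):
        raise ValueError("kind must be 'global' or 'local'")
    g, l = structure_test_pair(features, network, nperm=nperm, rng_seed=rng_seed, window=window)
    return g if kind == "global" else l


def interpolate_scores(
    scores: np.ndarray,
    coords: np.ndarray,
    grid_shape: tuple[int, int] = (50, 50),
    power: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-distance-weighted interpolation of scores onto a lat/lon grid.

    Returns (lat_axis, lon_axis, grid) with grid[i, j] the interpolated value
    at (lat_axis[i], lon_axis[j]); cells outside the samples' convex hull are
    NaN, and a cell coinciding with a sample takes that sample's score
    exactly.
    """
    from scipy.spatial import Delaunay

    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sample points")
    nlat, nlon = grid_shape
    if nlat < 1 or nlon < 1:
        raise ValueError("grid must have at least one cell per axis")
    try:
        tri = Delaunay(coords)
    except Exception as exc:
        raise ValueError("sample points are collinear; convex hull undefined") from exc
    lat_axis = np.linspace(coords[:, 0].min(), coords[:, 0].max(), nlat)
    lon_axis = np.linspace(coords[:, 1].min(), coords[:, 1].max(), nlon)
    glat, glon = np.meshgrid(lat_axis, lon_axis, indexing="ij")
    cells = np.column_stack([glat.ravel(), glon.ravel()])
    inside = tri.find_simplex(cells) >= 0
    d = np.sqrt(((cells[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    out = np.full(cells.shape[0], np.nan)
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        wts = 1.0 / d**power
    wts[has_exact] = 0.0
    wts[exact] = 1.0
    num = wts @ scores
    den = wts.sum(axis=1)
    valid = inside & (den > 0)
    out[valid] = num[valid] / den[valid]
    return lat_axis, lon_axis, out.reshape(nlat, nlon)
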