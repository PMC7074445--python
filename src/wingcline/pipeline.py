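"""Convenience drivers chaining the stages of the spatial morphometric analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .landmark_io import GenotypeMatrix, LandmarkConfiguration
from .procrustes_core import AlignedShapeSet, ColonyMeanShape, colony_means, filter_missing, gpa
from .spatial_structure import ConnectionNetwork, SpcaResult, knn_network, spca
from .wing_features import DEFAULT_PAIRS, FeatureMatrix, ProximalPairList, build_feature_matrix


@dataclass
class WingAnalysis:
    aligned: AlignedShapeSet
    means: list[ColonyMeanShape]
    features: FeatureMatrix
    network: ConnectionNetwork
    spca: SpcaResult
    n_removed_missing: int


def analyze_wings(
    configs: Sequence[LandmarkConfiguration],
    colony_coords: Mapping[str, tuple[float, float]],
    pairs: ProximalPairList = DEFAULT_PAIRS,
    k: int = 5,
) -> WingAnalysis:
    """Filter incomplete wings, run one joint GPA, average per colony, build
    proximal-distance features and run the spatial PCA at colony level."""
    kept, removed = filter_missing(configs)
    if not kept:
        raise ValueError("no complete wings left after filtering")
    aligned = gpa(kept)
    colony_of_wing = {c.wing_id: c.colony_id for c in kept}
    means = colony_means(aligned, colony_of_wing)
    features = build_feature_matrix(means, pairs, colony_coords)
    network = knn_network(features.coords, k=k)
    result = spca(features, network)
    return WingAnalysis(
        aligned=aligned,
        means=means,
        features=features,
        network=network,
        spca=result,
        n_removed_missing=len(removed),
    )


@dataclass
class SnpAnalysis:
    features: FeatureMatrix
    network: ConnectionNetwork
    spca: SpcaResult


def analyze_snps(
    genotypes: GenotypeMatrix,
    sample_coords: Mapping[str, tuple[float, float]],
    k: int = 5,
) -> SnpAnalysis:
    """Spatial PCA of the haploid allele matrix at sample (colony) level.

    Missing calls are mean-imputed per locus before the eigen-analysis, the
    standard allele-matrix treatment for PCA-family ordinations.
    """
    missing = [s for s in genotypes.sample_ids if s not in sample_coords]
    if missing:
        raise ValueError(f"samples with no coordinates: {missing[:10]}")
    calls = genotypes.calls.copy()
    if np.isnan(calls).any():
        col_mean = np.nanmean(calls, axis=0)
        nan_r, nan_c = np.where(np.isnan(calls))
        calls[nan_r, nan_c] = col_mean[nan_c]
    coords = np.asarray([sample_coords[s] for s in genotypes.sample_ids])
    features = FeatureMatrix(
        row_ids=list(genotypes.sample_ids),
        column_ids=list(genotypes.locus_ids),
        values=calls,
        coords=coords,
    )
    network = knn_network(coords, k=k)
    return SnpAnalysis(features=features, network=network, spca=spca(features, network))
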