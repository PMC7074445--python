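"""Site allele frequencies and pairwise F_ST from haploid SNP genotypes.

F_ST uses a Hudson-type estimator adapted to haploid sample counts, combined
across loci as a ratio of averages (sum of per-locus numerators over sum of
per-locus denominators), the combination that is robust to low-information
loci.  Per locus, with allele frequencies p1, p2 estimated from n1, n2
haploid calls:

    numerator   = (p1 - p2)^2 - p1(1 - p1)/(n1 - 1) - p2(1 - p2)/(n2 - 1)
    denominator = p1(1 - p2) + p2(1 - p1)

Missing calls are excluded locus-wise (pairwise-complete).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import GenotypeMatrix
from .ordination import DistanceMatrix


@dataclass
class SiteFrequencies:
    """Per-locus allele-1 frequency and haploid sample size at one site."""

    site_id: str
    freqs: np.ndarray  # (L,) in [0,1], NaN where no calls
    sizes: np.ndarray  # (L,) int, calls contributing per locus

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        defined = ~np.isnan(self.freqs)
        if np.any(self.sizes[defined] < 1):
            raise ValueError("frequency defined at a locus with zero calls")
        if np.any((self.freqs[defined] < 0) | (self.freqs[defined] > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


def site_allele_freqs(genotypes: GenotypeMatrix) -> list[SiteFrequencies]:
    """Per site and locus, the mean of non-missing haploid calls.

    Sites are returned in sorted order; a locus with no calls at a site gets
    frequency NaN (flagged missing) and size 0.
    """
    sites = sorted(set(genotypes.site_of_sample.values()))
    sample_site = np.array([genotypes.site_of_sample[s] for s in genotypes.sample_ids])
    out = []
    for site in sites:
        calls = genotypes.calls[sample_site == site]
        n = np.sum(~np.isnan(calls), axis=0)
        sums = np.nansum(calls, axis=0)
        freq = np.where(n >= 1, sums / np.maximum(n, 1), np.nan)
        out.append(SiteFrequencies(site_id=site, freqs=freq, sizes=n))
    return out


def hudson_fst_pair(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> float:
    """Hudson-type haploid F_ST for one site pair, ratio of averages over loci.

    Loci where either site has fewer than 2 calls (or an undefined
    frequency) are excluded; the raw ratio is returned unclamped.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    ok = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("no locus with >= 2 calls in both sites")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_den = den.sum()
    if total_den == 0.0:
        # both sites fixed for the same allele at every usable locus
        return 0.0
    return float(num.sum() / total_den)


def pairwise_fst(
    freqs: list[SiteFrequencies],
) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise haploid F_ST between all sites.

    Returns the matrix clamped to [0, 1] plus the raw (unclamped) values,
    since slightly negative estimates are informative about sampling noise.
    """
    if len(freqs) < 2:
        raise ValueError("need >= 2 sites")
    labels = [f.site_id for f in freqs]
    m = len(labels)
    raw = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            v = hudson_fst_pair(freqs[i].freqs, freqs[j].freqs, freqs[i].sizes, freqs[j].sizes)
            raw[i, j] = raw[j, i] = v
    clamped = np.clip(raw, 0.0, 1.0)
    np.fill_diagonal(clamped, 0.0)
    return DistanceMatrix(labels=labels, values=clamped), raw
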