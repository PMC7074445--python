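"""Synthetic clinal wing-landmark and haploid SNP datasets with known truth.

The generator emulates the Iberian sampling design: 23 sites on three
north–south transects (Atlantic 8, Central 9, Mediterranean 6), ~10 apiaries
of 3 colonies per site, ~5 wings per colony per caste, 19 landmarks per
wing, and 383 biallelic haploid SNP loci genotyped in one drone per colony.
A single latent variable q per colony — the logistic of the projection of
its coordinates onto a northeast–southwest axis — drives both a smooth wing
shape deformation and per-locus allele-frequency clines, so the wing and
SNP markers share their spatial structure by construction and concordance
has a known target.

Noise has three nested morphometric levels (colony, wing, digitizing) plus
caste-specific missing-landmark rates, higher in haploid drones, matching
the empirical pattern that drones express more venation anomalies.
All randomness flows from one seed; the same seed reproduces the dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .landmark_io import GenotypeMatrix, LandmarkConfiguration, SiteRecord

# Stylized right forewing: 19 vein-junction landmarks in image units
# (arbitrary pixel-like scale; the exact geometry is a synthetic fixture,
# not a measured wing).  Landmarks 1-8 run along the anterior margin to the
# tip, 9-15 return along the posterior margin, 16-19 sit on the inner
# median/cubital veins.
TEMPLATE_WING = np.array(
    [
        [30.0, 65.0],
        [70.0, 95.0],
        [110.0, 100.0],
        [150.0, 105.0],
        [195.0, 110.0],
        [240.0, 100.0],
        [280.0, 90.0],
        [310.0, 75.0],
        [285.0, 60.0],
        [250.0, 55.0],
        [210.0, 50.0],
        [170.0, 48.0],
        [130.0, 45.0],
        [95.0, 40.0],
        [60.0, 35.0],
        [100.0, 70.0],
        [145.0, 75.0],
        [190.0, 78.0],
        [235.0, 72.0],
    ]
)

TRANSECT_LAYOUT = {"AT": -8.5, "CT": -5.0, "MT": -1.5}
LAT_RANGE = (37.2, 43.0)


def default_deformation_axis() -> np.ndarray:
    """Unit-norm smooth shape deformation: distal stretch, dorsoventral squeeze.

    Displacement grows linearly with distance from the wing base along the
    long axis, with a compensating vertical compression, so distal landmarks
    move relative to proximal ones without a similarity transform component.
    """
    t = TEMPLATE_WING - TEMPLATE_WING.mean(axis=0)
    d = np.column_stack([t[:, 0] * 1.0, -t[:, 1] * 0.6])
    d -= d.mean(axis=0)
    # remove the component parallel to the template (pure scaling direction)
    tn = t / np.linalg.norm(t)
    d -= (d.ravel() @ tn.ravel()) * tn
    return d / np.linalg.norm(d)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-size parameters of the synthetic cline."""

    sites_per_transect: tuple[int, int, int] = (8, 9, 6)  # AT, CT, MT
    apiaries_per_site: int = 10
    colonies_per_apiary: int = 3
    wings_per_colony: int = 5
    n_landmarks: int = 19
    n_loci: int = 383
    cline_axis_bearing: float = 45.0  # degrees clockwise from north (NE-SW axis)
    cline_strength_shape: float = 0.08  # Procrustes units across the full cline
    cline_strength_snp: float = 3.0  # per-locus logit slope magnitude
    colony_sd: float = 0.002  # per-coordinate, Procrustes units
    wing_sd: float = 0.004
    digitize_sd: float = 0.001
    missing_rate_drone: float = 0.003  # per landmark
    missing_rate_worker: float = 0.0002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate_drone", "missing_rate_worker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missing_rate_drone < self.missing_rate_worker:
            raise ValueError("drone missing rate must be >= worker missing rate")
        for name in ("colony_sd", "wing_sd", "digitize_sd",
                     "cline_strength_shape", "cline_strength_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if min(self.sites_per_transect) < 1 or self.apiaries_per_site < 1 \
                or self.colonies_per_apiary < 1 or self.wings_per_colony < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_sites(self) -> int:
        return sum(self.sites_per_transect)

    @property
    def n_colonies(self) -> int:
        return self.n_sites * self.apiaries_per_site * self.colonies_per_apiary


@dataclass
class SimulationTruth:
    """Generative parameters against which recovery is scored."""

    colony_ids: list[str]
    q: np.ndarray  # latent cline value per colony, in [0, 1]
    deformation_axis: np.ndarray  # (19, 2), unit norm
    locus_baseline: np.ndarray  # logit-scale intercepts
    locus_slope: np.ndarray  # logit-scale slopes on (q - 1/2)
    site_coords: dict[str, tuple[float, float]]  # site -> (lat, lon)


@dataclass
class SimulationResult:
    wings: dict[str, list[LandmarkConfiguration]]  # caste -> configurations
    genotypes: GenotypeMatrix
    truth: SimulationTruth
    sites: list[SiteRecord]
    wing_meta: pd.DataFrame  # wing_id, colony_id, site_id, caste
    colony_coords: dict[str, tuple[float, float]]  # colony -> (lat, lon)
    site_of_colony: dict[str, str]
    config: SimulationConfig


def _unit_preshape(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate the full two-caste wing + SNP dataset from one seed."""
    rng = np.random.default_rng(config.seed)
    template = _unit_preshape(TEMPLATE_WING)
    axis = default_deformation_axis()

    # --- sites on three north-south transects
    sites: list[SiteRecord] = []
    for (transect, lon), n_sites in zip(TRANSECT_LAYOUT.items(), config.sites_per_transect):
        lats = np.linspace(LAT_RANGE[0], LAT_RANGE[1], n_sites)
        for i, lat in enumerate(lats, start=1):
            sites.append(SiteRecord(f"{transect}{i}", transect, float(lat), lon))

    # --- colony coordinates: apiary jitter around the site, colony jitter
    colony_ids: list[str] = []
    colony_coords: dict[str, tuple[float, float]] = {}
    site_of_colony: dict[str, str] = {}
    for site in sites:
        for a in range(1, config.apiaries_per_site + 1):
            ap_lat = site.latitude + rng.normal(0.0, 0.08)
            ap_lon = site.longitude + rng.normal(0.0, 0.08)
            for c in range(1, config.colonies_per_apiary + 1):
                cid = f"{site.site_id}_a{a}_c{c}"
                colony_ids.append(cid)
                colony_coords[cid] = (
                    ap_lat + rng.normal(0.0, 0.01),
                    ap_lon + rng.normal(0.0, 0.01),
                )
                site_of_colony[cid] = site.site_id

    # --- latent cline: logistic of the projection on the NE-SW axis
    theta = np.radians(config.cline_axis_bearing)
    coords_arr = np.array([colony_coords[c] for c in colony_ids])  # (n, 2) lat, lon
    proj = coords_arr[:, 1] * np.sin(theta) + coords_arr[:, 0] * np.cos(theta)
    t = 2.0 * (proj - proj.min()) / (proj.max() - proj.min()) - 1.0
    q = expit(3.0 * t)

    # --- wings per caste
    missing_rates = {"drone": config.missing_rate_drone, "worker": config.missing_rate_worker}
    wings: dict[str, list[LandmarkConfiguration]] = {}
    meta_rows = []
    k = config.n_landmarks
    if k != template.shape[0]:
        raise ValueError("template wing has 19 landmarks; other counts unsupported")
    for caste in ("drone", "worker"):
        rate = missing_rates[caste]
        configs = []
        for ci, cid in enumerate(colony_ids):
            colony_mean = (
                template
                + (q[ci] - 0.5) * config.cline_strength_shape * axis
                + rng.normal(0.0, config.colony_sd, (k, 2))
            )
            for w in range(1, config.wings_per_colony + 1):
                shape = (
                    colony_mean
                    + rng.normal(0.0, config.wing_sd, (k, 2))
                    + rng.normal(0.0, config.digitize_sd, (k, 2))
                )
                # raw digitized coordinates: random similarity transform into pixels
                ang = rng.uniform(0.0, 2.0 * np.pi)
                rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
                scale = 400.0 * np.exp(rng.normal(0.0, 0.1))
                shift = rng.uniform(50.0, 450.0, 2)
                raw = shape @ rot * scale + shift
                mask = rng.random(k) < rate
                raw = raw.copy()
                raw[mask] = np.nan
                wid = f"{cid}_{caste}_w{w}"
                configs.append(
                    LandmarkConfiguration(
                        wing_id=wid,
                        landmarks=raw,
                        missing_mask=mask,
                        colony_id=cid,
                        caste=caste,
                    )
                )
                meta_rows.append((wid, cid, site_of_colony[cid], caste))
        wings[caste] = configs

    # --- haploid genotypes: one drone per colony
    base_p = rng.uniform(0.2, 0.8, config.n_loci)
    alpha = np.log(base_p / (1 - base_p))
    slope = config.cline_strength_snp * rng.choice([-1.0, 1.0], config.n_loci)
    p = expit(alpha[None, :] + slope[None, :] * (q[:, None] - 0.5))
    calls = rng.binomial(1, p).astype(float)
    genotypes = GenotypeMatrix(
        sample_ids=list(colony_ids),
        locus_ids=[f"locus_{i + 1}" for i in range(config.n_loci)],
        calls=calls,
        site_of_sample=dict(site_of_colony),
    )

    truth = SimulationTruth(
        colony_ids=list(colony_ids),
        q=q,
        deformation_axis=axis,
        locus_baseline=alpha,
        locus_slope=slope,
        site_coords={s.site_id: (s.latitude, s.longitude) for s in sites},
    )
    meta = pd.DataFrame(meta_rows, columns=["wing_id", "colony_id", "site_id", "caste"])
    return SimulationResult(
        wings=wings,
        genotypes=genotypes,
        truth=truth,
        sites=sites,
        wing_meta=meta,
        colony_coords=colony_coords,
        site_of_colony=site_of_colony,
        config=config,
    )


def recovery_score(
    truth: SimulationTruth, scores: np.ndarray, colony_ids: list[str] | None = None
) -> float:
    """|Pearson r| between the latent cline q and a score vector (e.g. sPC1).

    Sign-invariant because sPCA axes are sign-arbitrary.
    """
    scores = np.asarray(scores, float)
    if colony_ids is not None:
        unknown = set(colony_ids) - set(truth.colony_ids)
        if unknown:
            raise ValueError(f"colony ids not in the simulation truth: {sorted(unknown)[:5]}")
        # scored colonies may be a subset (e.g. colonies losing every wing
        # to the missing-landmark filter); correlate over the matched set
        truth_idx = {c: i for i, c in enumerate(truth.colony_ids)}
        q = truth.q[[truth_idx[c] for c in colony_ids]]
    else:
        q = truth.q
    if scores.shape != q.shape:
        raise ValueError("need one score per colony")
    return float(abs(np.corrcoef(q, scores)[0, 1]))
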