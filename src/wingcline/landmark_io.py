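"""Reading and writing TPS landmark files and the tabular inputs of the pipeline.

The TPS format is the de-facto interchange format of 2D geometric
morphometrics (tpsUtil/tpsDig family): each record starts with an
``LM=<count>`` line, followed by ``<count>`` whitespace-separated ``x y``
coordinate lines, optionally followed by ``IMAGE=``, ``ID=`` and ``SCALE=``
lines.  TPS has no standard missing-landmark code; this package writes the
sentinel pair ``-1.0 -1.0`` and interprets it as missing on read, which keeps
files loadable by tpsDig-family tools while preserving the mask.

Tabular inputs are plain CSV with a header row: a site table
(``site_id,transect,latitude,longitude``), wing metadata
(``wing_id,colony_id,site_id,caste``) and a haploid genotype matrix
(``sample_id,site_id,locus_1..locus_L`` with calls in {0,1,NA}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_LANDMARKS = 19
MISSING_SENTINEL = -1.0
CASTES = ("drone", "worker")
TRANSECTS = ("AT", "CT", "MT")


class TpsParseError(ValueError):
    """Malformed TPS input; message carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class LandmarkConfiguration:
    """One wing's digitized landmarks plus sampling metadata.

    Coordinates are in image units (pixels, or dimensionless after SCALE is
    applied).  ``missing_mask[i]`` is True where landmark ``i`` was not
    digitized; those coordinates are NaN.  A record whose landmark count
    differs from the standard 19 is kept but ``flagged``.
    """

    wing_id: str
    landmarks: np.ndarray  # (k, 2) float
    missing_mask: np.ndarray  # (k,) bool
    colony_id: str = ""
    caste: str = ""
    image_ref: str | None = None
    scale: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must be a (k, 2) array")
        if self.missing_mask.shape != (self.landmarks.shape[0],):
            raise ValueError("missing_mask length must match landmark count")
        if self.caste and self.caste not in CASTES:
            raise ValueError(f"caste must be one of {CASTES}, got {self.caste!r}")
        present = self.landmarks[~self.missing_mask]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError(
                f"wing {self.wing_id}: non-finite coordinates at non-missing landmarks"
            )
        if self.landmarks.shape[0] != N_LANDMARKS:
            self.flagged = True

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()


@dataclass(frozen=True)
class SiteRecord:
    """A georeferenced sampling site on one of the three transects."""

    site_id: str
    transect: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.transect not in TRANSECTS:
            raise ValueError(f"transect must be one of {TRANSECTS}, got {self.transect!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of [-180, 180]")


@dataclass
class GenotypeMatrix:
    """Haploid biallelic SNP calls, one row per sample (drone/colony).

    ``calls`` is float with values 0.0, 1.0 or NaN (missing); haploid coding
    is enforced (a value of 2 is a contract violation, not a heterozygote).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray  # (n_samples, n_loci) float with NaN for missing
    site_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("calls shape does not match sample/locus ids")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0))):
            bad = sorted(set(observed) - {0.0, 1.0})
            raise ValueError(
                f"non-haploid genotype values {bad}: recode calls as haploid 0/1 "
                "(diploid '2' coding is not accepted)"
            )
        missing_sites = [s for s in self.sample_ids if s not in self.site_of_sample]
        if missing_sites:
            raise ValueError(f"samples with no site assignment: {missing_sites[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


# ---------------------------------------------------------------------------
# TPS reading / writing


def _is_missing_pair(x: float, y: float) -> bool:
    return x == MISSING_SENTINEL and y == MISSING_SENTINEL


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations, order preserved.

    SCALE lines are applied multiplicatively; absence means scale 1.  Records
    whose ``LM=`` count differs from 19 are returned flagged, never dropped.
    Malformed input raises :class:`TpsParseError` naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    n = len(lines)
    record_index = 0
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(f"expected 'LM=' record header, got {line!r}", i + 1)
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise TpsParseError(f"malformed LM line {line!r}", i + 1) from None
        if k < 0:
            raise TpsParseError(f"negative landmark count in {line!r}", i + 1)
        i += 1
        coords = np.empty((k, 2), dtype=float)
        mask = np.zeros(k, dtype=bool)
        for j in range(k):
            if i >= n:
                raise TpsParseError(
                    f"truncated record: expected {k} coordinate lines, got {j}", n
                )
            parts = lines[i].split()
            if len(parts) != 2 or parts[0].upper().startswith(("LM=", "IMAGE=", "ID=", "SCALE=")):
                raise TpsParseError(
                    f"expected {k} coordinate lines, found {j} before {lines[i].strip()!r}",
                    i + 1,
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise TpsParseError(f"non-numeric coordinate {lines[i].strip()!r}", i + 1) from None
            if _is_missing_pair(x, y):
                mask[j] = True
                coords[j] = (math.nan, math.nan)
            else:
                coords[j] = (x, y)
            i += 1
        image_ref: str | None = None
        wing_id = ""
        scale: float | None = None
        while i < n:
            tail = lines[i].strip()
            up = tail.upper()
            if up.startswith("IMAGE="):
                image_ref = tail.split("=", 1)[1]
            elif up.startswith("ID="):
                wing_id = tail.split("=", 1)[1]
            elif up.startswith("SCALE="):
                try:
                    scale = float(tail.split("=", 1)[1])
                except ValueError:
                    raise TpsParseError(f"non-numeric SCALE in {tail!r}", i + 1) from None
            else:
                break
            i += 1
        if scale is not None:
            coords[~mask] *= scale
        if not wing_id:
            wing_id = f"record_{record_index}"
        configs.append(
            LandmarkConfiguration(
                wing_id=wing_id,
                landmarks=coords,
                missing_mask=mask,
                image_ref=image_ref,
                scale=scale,
            )
        )
        record_index += 1
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file (missing landmarks as ``-1.0 -1.0``).

    Coordinates are printed with 6 decimals, so a read/write round trip is
    lossless to 1e-6.  SCALE is not re-emitted: coordinates are written
    post-scale, which keeps the round trip the identity.
    """
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.n_landmarks}")
        for (x, y), miss in zip(c.landmarks, c.missing_mask):
            if miss:
                out.append(f"{MISSING_SENTINEL:.6f} {MISSING_SENTINEL:.6f}")
            else:
                out.append(f"{x:.6f} {y:.6f}")
        if c.image_ref is not None:
            out.append(f"IMAGE={c.image_ref}")
        out.append(f"ID={c.wing_id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def attach_metadata(
    configs: Iterable[LandmarkConfiguration], meta: pd.DataFrame
) -> list[LandmarkConfiguration]:
    """Fill colony_id/caste on configurations from a wing-metadata table."""
    required = {"wing_id", "colony_id", "caste"}
    if not required.issubset(meta.columns):
        raise ValueError(f"wing metadata must have columns {sorted(required)}")
    lookup = meta.set_index("wing_id")
    out = []
    for c in configs:
        if c.wing_id in lookup.index:
            row = lookup.loc[c.wing_id]
            c.colony_id = str(row["colony_id"])
            c.caste = str(row["caste"])
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Tabular inputs


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the site table CSV (site_id,transect,latitude,longitude)."""
    df = pd.read_csv(path)
    required = {"site_id", "transect", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id values: {dups}")
    return [
        SiteRecord(
            site_id=str(r.site_id),
            transect=str(r.transect),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
        )
        for r in df.itertuples()
    ]


def read_wing_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"wing_id", "colony_id", "site_id", "caste"}
    if not required.issubset(df.columns):
        raise ValueError(f"wing metadata must have columns {sorted(required)}")
    bad = set(df["caste"]) - set(CASTES)
    if bad:
        raise ValueError(f"unknown caste values {sorted(bad)}; expected {CASTES}")
    return df


def read_genotypes(
    path: str | Path, sites: Sequence[SiteRecord] | None = None
) -> GenotypeMatrix:
    """Read the haploid genotype CSV (sample_id,site_id,locus_...).

    Calls must be 0, 1 or NA; a value of 2 raises with an instruction to use
    haploid coding.  If ``sites`` is given, every sample's site must be known.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "site_id" not in df.columns:
        raise ValueError("genotype table must have sample_id and site_id columns")
    locus_cols = [c for c in df.columns if c not in ("sample_id", "site_id")]
    if not locus_cols:
        raise ValueError("genotype table has no locus columns")
    calls = df[locus_cols].to_numpy(dtype=float)
    site_of_sample = dict(zip(df["sample_id"].astype(str), df["site_id"].astype(str)))
    if sites is not None:
        known = {s.site_id for s in sites}
        unknown = sorted(set(site_of_sample.values()) - known)
        if unknown:
            raise ValueError(f"samples reference unknown sites: {unknown}")
    return GenotypeMatrix(
        sample_ids=df["sample_id"].astype(str).tolist(),
        locus_ids=locus_cols,
        calls=calls,
        site_of_sample=site_of_sample,
    )
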