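"""Predictor (model) distance matrices from a taxon metadata table.

Three explanatory matrices are built from per-taxon metadata:

* taxonomy — 0 for pairs in the same subgenus, 1 otherwise;
* habitat  — 0 for pairs whose habitat sets intersect, 1 otherwise
  (a taxon occupying e.g. both streams and caves is equally close to
  stream and cave taxa);
* geography — great-circle (haversine) distance in meters between sample
  coordinates on a sphere of radius 6,371,008.8 m (IUGG mean).

Habitat codes form a closed vocabulary {cave, burrow, stream}; unknown
codes are rejected at load so typos cannot silently corrupt a model matrix.
Distances are computed between samples (table rows), so multiple rows per
species are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo_distance import DistanceMatrix

__all__ = [
    "TaxonTableError",
    "TaxonTable",
    "HABITAT_CODES",
    "EARTH_RADIUS_M",
    "taxonomy_matrix",
    "habitat_matrix",
    "geographic_matrix",
    "haversine_m",
]

HABITAT_CODES = frozenset({"cave", "burrow", "stream"})
EARTH_RADIUS_M = 6_371_008.8  # IUGG mean Earth radius


class TaxonTableError(ValueError):
    """Invalid taxon metadata."""


@dataclass(frozen=True)
class TaxonTable:
    """Per-taxon metadata driving model-matrix construction.

    ``habitats`` maps each taxon to a nonempty subset of
    :data:`HABITAT_CODES`; coordinates are decimal degrees.
    """

    labels: tuple[str, ...]
    subgenus: tuple[str, ...]
    habitats: tuple[frozenset[str], ...]
    lat: tuple[float, ...]
    lon: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise TaxonTableError("taxon table is empty")
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise TaxonTableError(f"duplicate taxon labels: {dupes}")
        for fld in ("subgenus", "habitats", "lat", "lon"):
            if len(getattr(self, fld)) != n:
                raise TaxonTableError(f"column {fld!r} length mismatch")
        for lab, hset in zip(self.labels, self.habitats):
            if not hset:
                raise TaxonTableError(f"taxon {lab!r} has an empty habitat set")
            unknown = hset - HABITAT_CODES
            if unknown:
                raise TaxonTableError(
                    f"taxon {lab!r}: unknown habitat code(s) {sorted(unknown)}; "
                    f"allowed: {sorted(HABITAT_CODES)}"
                )
        for lab, la, lo in zip(self.labels, self.lat, self.lon):
            if not (-90.0 <= la <= 90.0):
                raise TaxonTableError(f"taxon {lab!r}: latitude {la} out of range")
            if not (-180.0 <= lo <= 180.0):
                raise TaxonTableError(f"taxon {lab!r}: longitude {lo} out of range")
        if any(not s for s in self.subgenus):
            raise TaxonTableError("every taxon needs a subgenus")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TaxonTable":
        required = {"taxon", "subgenus", "habitats", "lat", "lon"}
        missing = required - set(df.columns)
        if missing:
            raise TaxonTableError(f"metadata missing column(s): {sorted(missing)}")
        habitats = tuple(
            frozenset(h.strip() for h in str(cell).split("+") if h.strip())
            for cell in df["habitats"]
        )
        return cls(
            labels=tuple(str(t) for t in df["taxon"]),
            subgenus=tuple(str(s) for s in df["subgenus"]),
            habitats=habitats,
            lat=tuple(float(v) for v in df["lat"]),
            lon=tuple(float(v) for v in df["lon"]),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonTable":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.labels,
                "subgenus": self.subgenus,
                "habitats": ["+".join(sorted(h)) for h in self.habitats],
                "lat": self.lat,
                "lon": self.lon,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def taxonomy_matrix(table: TaxonTable) -> DistanceMatrix:
    """0/1 taxonomic distance: 0 within a subgenus, 1 across subgenera."""
    sub = np.asarray(table.subgenus, dtype=object)
    values = (sub[:, None] != sub[None, :]).astype(float)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(table.labels, values, units="model-units")


def habitat_matrix(table: TaxonTable) -> DistanceMatrix:
    """0/1 habitat distance: 0 when habitat sets intersect, 1 otherwise."""
    n = table.n
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.0 if table.habitats[i] & table.habitats[j] else 1.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(table.labels, values, units="model-units")


def haversine_m(
    lat1: np.ndarray,
    lon1: np.ndarray,
    lat2: np.ndarray,
    lon2: np.ndarray,
    radius: float = EARTH_RADIUS_M,
) -> np.ndarray:
    """Great-circle distance in meters between coordinate arrays (degrees)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def geographic_matrix(
    table: TaxonTable,
    radius: float = EARTH_RADIUS_M,
    units: str = "meters",
) -> DistanceMatrix:
    """Pairwise great-circle distances between sample coordinates.

    ``units="kilometers"`` rescales by 1/1000 for regression-friendly
    magnitudes; the default is meters.
    """
    lat = np.asarray(table.lat, dtype=float)
    lon = np.asarray(table.lon, dtype=float)
    values = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :], radius)
    np.fill_diagonal(values, 0.0)
    if units == "kilometers":
        values = values / 1000.0
    elif units != "meters":
        raise TaxonTableError(f"unsupported geographic units {units!r}")
    return DistanceMatrix(table.labels, values, units=units)
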