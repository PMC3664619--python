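"""Shared data containers, CSV IO and site alignment.

All downstream stages operate on three containers: a binary site-by-species
:class:`IncidenceMatrix`, a :class:`SiteTable` holding planar coordinates and
environmental columns, and a symmetric :class:`DistMatrix`.  Site order is
canonicalised by the incidence matrix; every derived matrix inherits it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: kilometres per degree of latitude (spherical Earth, mean radius)
KM_PER_DEG = 111.32

__all__ = [
    "IncidenceMatrix",
    "SiteTable",
    "DistMatrix",
    "read_incidence",
    "read_sites",
    "align",
    "project_lonlat",
]


@dataclass
class IncidenceMatrix:
    """Binary site x species occurrence table (1 = species recorded)."""

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray  # (n_sites, n_species) of 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("incidence values must be a 2-D array")
        n, s = self.values.shape
        if n != len(self.site_ids) or s != len(self.species_ids):
            raise ValueError("incidence shape does not match label counts")
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site labels in incidence matrix")
        if len(set(self.species_ids)) != s:
            raise ValueError("duplicate species labels in incidence matrix")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary incidence entry {self.values[i, j]!r} at "
                f"site {self.site_ids[i]!r}, species {self.species_ids[j]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def richness(self) -> np.ndarray:
        """Per-site species count."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.species_ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())


@dataclass
class SiteTable:
    """Per-site planar coordinates (km) and environmental columns."""

    site_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    env: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.site_ids)
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site labels in site table")
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("coordinate arrays must be 1-D of length n_sites")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite site coordinates")
        if self.env is None or len(self.env) == 0:
            self.env = pd.DataFrame(index=pd.Index(self.site_ids))
        else:
            self.env = self.env.copy()
            self.env.index = pd.Index(self.site_ids)
        pairs = set(zip(self.x.tolist(), self.y.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicated coordinate pairs (graphs require distinct points)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, ids: list[str]) -> "SiteTable":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        idx = [pos[s] for s in ids]
        return SiteTable(list(ids), self.x[idx], self.y[idx], self.env.iloc[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y}, index=self.site_ids)
        return pd.concat([df, self.env], axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site")


@dataclass
class DistMatrix:
    """Symmetric zero-diagonal site x site dissimilarity/distance matrix."""

    labels: list[str]
    values: np.ndarray

    SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=self.SYM_TOL, rtol=0):
            raise ValueError("distance matrix not symmetric within tolerance")
        if not np.all(np.diag(v) == 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        # %.17g guarantees an exact binary round-trip through text
        self.to_frame().to_csv(path, index_label="site", float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "DistMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(list(map(str, df.index)), df.to_numpy(dtype=float))

    def reorder(self, ids: list[str]) -> "DistMatrix":
        pos = {s: i for i, s in enumerate(self.labels)}
        idx = [pos[s] for s in ids]
        return DistMatrix(list(ids), self.values[np.ix_(idx, idx)])


def read_incidence(path) -> IncidenceMatrix:
    """Read a site-by-species incidence CSV (header = species, first column = sites)."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(values):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric incidence entry {cell!r} at site "
                        f"{df.index[i]!r}, species {df.columns[j]!r}"
                    ) from None
        values = values.astype(float)
    return IncidenceMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)


def read_sites(path) -> SiteTable:
    """Read a site table CSV with columns ``x``/``y`` (km) or ``lon``/``lat`` (degrees).

    Decimal-degree input is projected to km internally (equirectangular at the
    mean latitude); everything downstream works in km.
    """
    df = pd.read_csv(path, index_col=0)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        x = df[cols["x"]].to_numpy(float)
        y = df[cols["y"]].to_numpy(float)
        env = df.drop(columns=[cols["x"], cols["y"]])
    elif "lon" in cols and "lat" in cols:
        lon = df[cols["lon"]].to_numpy(float)
        lat = df[cols["lat"]].to_numpy(float)
        x, y = project_lonlat(lon, lat, ref_lat=float(np.mean(lat)))
        env = df.drop(columns=[cols["lon"], cols["lat"]])
    else:
        raise ValueError("site table needs either x/y (km) or lon/lat (degrees) columns")
    return SiteTable(list(map(str, df.index)), x, y, env)


def align(inc: IncidenceMatrix, sites: SiteTable) -> tuple[IncidenceMatrix, SiteTable]:
    """Restrict both inputs to their common sites, in the incidence matrix's order.

    Sites present in only one input are dropped with a logged warning; an empty
    intersection is an error.
    """
    common = [s for s in inc.site_ids if s in set(sites.site_ids)]
    if not common:
        raise ValueError("no common site labels between incidence matrix and site table")
    dropped = (set(inc.site_ids) | set(sites.site_ids)) - set(common)
    if dropped:
        logger.warning("align dropped %d site(s): %s", len(dropped), sorted(dropped))
    pos = {s: i for i, s in enumerate(inc.site_ids)}
    idx = [pos[s] for s in common]
    inc2 = IncidenceMatrix(common, list(inc.species_ids), inc.values[idx])
    return inc2, sites.subset(common)


def project_lonlat(lon, lat, ref_lat: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of decimal degrees to planar km.

    x = 111.32 * cos(ref_lat) * lon, y = 111.32 * lat.  Adequate for island-scale
    extents (distance error < 1% for spans up to ~50 km); larger domains would
    need a proper geodetic projection.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 90):
        raise ValueError("latitude must satisfy |lat| < 90")
    lon = np.asarray(lon, dtype=float)
    x = KM_PER_DEG * math.cos(math.radians(ref_lat)) * lon
    y = KM_PER_DEG * lat
    return x, y
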