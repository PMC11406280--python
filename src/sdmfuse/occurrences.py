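"""Occurrence reading, validation and spatial curation.

Raw citizen-science occurrence tables are noisy: repeated uploads of the
same plant, vague coordinates, records outside the covariate rasters, and
species whose entire record set sits in one spot (usually a single heavily
photographed individual).  The curation chain applied here is:

1. read + validate (drop rows with missing species / non-finite coordinates,
   optionally drop records with coordinate uncertainty above 120 m),
2. deduplicate same-species records within 150 m,
3. drop species confined to a 256 m disc around their centroid,
4. clip to the study boundary and the covariate rasters,
5. (after neighbor imputation) drop species with fewer than 500 label-set
   memberships.

All radii are Euclidean in a projected meter CRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.prepared import prep

from . import geo

log = logging.getLogger(__name__)

#: records with reported coordinate uncertainty above this (meters) are
#: dropped at read time when the column is present.
MAX_COORD_UNCERTAINTY_M = 120.0


@dataclass(frozen=True)
class Occurrence:
    """One georeferenced species record in the working projected CRS."""

    record_id: str
    species: str
    x: float
    y: float
    observed_date: str | None = None
    source: str = ""


@dataclass(frozen=True)
class TaxonomyTable:
    """Total mapping species -> (genus, family).

    The genus -> family relation must be functional: a genus appearing under
    two families is a data error and rejected at construction.
    """

    genus_of: dict[str, str]
    family_of_genus: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTable":
        required = {"species", "genus", "family"}
        if not required.issubset(frame.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        genus_of: dict[str, str] = {}
        family_of_genus: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            sp, gen, fam = str(row.species), str(row.genus), str(row.family)
            if sp in genus_of and genus_of[sp] != gen:
                raise ValueError(f"species {sp!r} mapped to two genera")
            if gen in family_of_genus and family_of_genus[gen] != fam:
                raise ValueError(f"genus {gen!r} mapped to two families")
            genus_of[sp] = gen
            family_of_genus[gen] = fam
        return cls(genus_of, family_of_genus)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TaxonomyTable":
        return cls.from_frame(pd.read_csv(path))

    def genus(self, species: str) -> str:
        return self.genus_of[species]

    def family(self, species: str) -> str:
        return self.family_of_genus[self.genus_of[species]]

    def __contains__(self, species: str) -> bool:
        return species in self.genus_of


def _coords(occs: Sequence[Occurrence]) -> np.ndarray:
    return np.array([(o.x, o.y) for o in occs], dtype=float).reshape(-1, 2)


def read_occurrences(path: str | Path, crs: str) -> list[Occurrence]:
    """Read an occurrence CSV into the working projected CRS.

    The file must provide ``record_id`` and ``species`` plus either
    projected ``x, y`` (assumed to already be in ``crs``) or geographic
    ``lon, lat`` which are reprojected into ``crs``.  Rows with missing
    species or non-finite coordinates are dropped and counted in the log;
    rows with ``coord_uncertainty_m`` above 120 m are dropped when that
    column exists.
    """
    projected = geo.parse_crs(crs)
    if projected is None:
        raise geo.CRSError("working CRS must be projected (UTM), not geographic")
    try:
        frame = pd.read_csv(path)
    except OSError as exc:  # unreadable file is fatal
        raise OSError(f"cannot read occurrence file {path}: {exc}") from exc
    for col in ("record_id", "species"):
        if col not in frame.columns:
            raise ValueError(f"occurrence file missing required column {col!r}")

    if {"x", "y"}.issubset(frame.columns):
        xs = pd.to_numeric(frame["x"], errors="coerce").to_numpy()
        ys = pd.to_numeric(frame["y"], errors="coerce").to_numpy()
    elif {"lon", "lat"}.issubset(frame.columns):
        lon = pd.to_numeric(frame["lon"], errors="coerce").to_numpy()
        lat = pd.to_numeric(frame["lat"], errors="coerce").to_numpy()
        xs, ys = geo.geodetic_to_projected(lon, lat, projected)
    else:
        raise ValueError("occurrence file needs x,y or lon,lat columns")

    species = frame["species"].astype("string")
    keep = np.isfinite(xs) & np.isfinite(ys) & species.notna().to_numpy()
    keep &= (species.fillna("").str.strip() != "").to_numpy()
    n_bad = int((~keep).sum())
    if n_bad:
        log.info("dropped %d rows with missing species or bad coordinates", n_bad)

    if "coord_uncertainty_m" in frame.columns:
        unc = pd.to_numeric(frame["coord_uncertainty_m"], errors="coerce").to_numpy()
        vague = keep & np.isfinite(unc) & (unc > MAX_COORD_UNCERTAINTY_M)
        if vague.any():
            log.info("dropped %d rows with coordinate uncertainty > %g m",
                     int(vague.sum()), MAX_COORD_UNCERTAINTY_M)
        keep &= ~vague
    else:
        log.warning("no coord_uncertainty_m column; uncertainty filter skipped")

    ids = frame["record_id"].astype(str)
    if ids[keep].duplicated().any():
        raise ValueError("record_id values are not unique")
    dates = frame["date"].astype("string") if "date" in frame.columns else None
    sources = frame["source"].astype("string") if "source" in frame.columns else None
    out = []
    for i in np.flatnonzero(keep):
        out.append(Occurrence(
            record_id=ids.iat[i],
            species=str(species.iat[i]).strip(),
            x=float(xs[i]),
            y=float(ys[i]),
            observed_date=None if dates is None or pd.isna(dates.iat[i]) else str(dates.iat[i]),
            source="" if sources is None or pd.isna(sources.iat[i]) else str(sources.iat[i]),
        ))
    return out


def dedup_within_radius(occs: Sequence[Occurrence],
                        radius_m: float = 150.0) -> list[Occurrence]:
    """Greedy same-species deduplication in stable input order.

    For each species independently, a record is kept iff no previously kept
    record of that species lies within ``radius_m``.  The first record wins,
    making the pass deterministic for a fixed input order, and the output
    preserves input order.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if not occs:
        return []
    keep = np.zeros(len(occs), dtype=bool)
    by_species: dict[str, list[int]] = {}
    for i, o in enumerate(occs):
        by_species.setdefault(o.species, []).append(i)
    xy = _coords(occs)
    for idxs in by_species.values():
        pts = xy[idxs]
        tree = cKDTree(pts)
        kept_local: list[int] = []
        for j in range(len(idxs)):
            close = tree.query_ball_point(pts[j], radius_m)
            if any(k in close for k in kept_local if k != j):
                continue
            kept_local.append(j)
            keep[idxs[j]] = True
    return [o for i, o in enumerate(occs) if keep[i]]


def drop_confined_species(occs: Sequence[Occurrence],
                          radius_m: float = 256.0) -> list[Occurrence]:
    """Remove species whose every record sits within ``radius_m`` of the
    species' coordinate centroid.

    Such species have no usable range signal — typically a single plant or
    planting photographed repeatedly.  Single-record species are trivially
    confined and removed.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    xy = _coords(occs)
    confined: set[str] = set()
    by_species: dict[str, list[int]] = {}
    for i, o in enumerate(occs):
        by_species.setdefault(o.species, []).append(i)
    for sp, idxs in by_species.items():
        pts = xy[idxs]
        centroid = pts.mean(axis=0)
        if np.hypot(*(pts - centroid).T).max() <= radius_m:
            confined.add(sp)
    if confined:
        log.info("removed %d spatially confined species", len(confined))
    return [o for o in occs if o.species not in confined]


def clip_to_extent(occs: Sequence[Occurrence], boundary,
                   rasters: Iterable) -> list[Occurrence]:
    """Keep records inside the (closed) boundary polygon and inside every
    raster's valid-data extent."""
    rasters = list(rasters)
    if not occs:
        return []
    xy = _coords(occs)
    prepared = prep(boundary)
    keep = np.array([prepared.covers(Point(p)) for p in xy])
    for raster in rasters:
        keep &= raster.contains(xy[:, 0], xy[:, 1])
    out = [o for i, o in enumerate(occs) if keep[i]]
    if not out:
        log.warning("clip_to_extent removed every occurrence")
    return out


def filter_min_count(labels, species_names: Sequence[str],
                     min_count: int = 500):
    """Drop species with fewer than ``min_count`` label-set memberships.

    Runs after neighbor imputation, so the counts include imputed
    memberships.  Species indices are re-compacted; anchors left with empty
    species sets are dropped.  Returns ``(labels, kept_species_names)``.
    """
    counts = np.zeros(len(species_names), dtype=int)
    for ls in labels:
        for s in ls.species_idx:
            counts[s] += 1
    kept = np.flatnonzero(counts >= min_count)
    if kept.size == 0:
        raise ValueError(
            f"no species has >= {min_count} label-set memberships; "
            "lower min_count or provide more data")
    remap = {old: new for new, old in enumerate(kept)}
    kept_names = [species_names[i] for i in kept]
    out = []
    n_dropped_anchors = 0
    for ls in labels:
        new_idx = {remap[s] for s in ls.species_idx if s in remap}
        if not new_idx:
            n_dropped_anchors += 1
            continue
        out.append(ls.replace_species(new_idx))
    if n_dropped_anchors:
        log.info("dropped %d anchors left without species", n_dropped_anchors)
    return out, kept_names
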