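"""Multilabel, multi-rank target construction via neighbor imputation.

Citizen-science records are presence-only and single-species, but a 256 m
aerial image around a record contains the whole local plant community.
Neighbor imputation approximates that community: every species observed
within 256 m of an anchor record (overlapping image footprints) is added to
the anchor's label set.  Genus and family label sets are the images of the
species set under the taxonomy, giving the three supervised ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .occurrences import Occurrence, TaxonomyTable


@dataclass(frozen=True)
class LabelSet:
    """Multilabel targets of one anchor occurrence.

    ``species_idx`` always contains the anchor's own species
    (``own_species_idx``); genus/family sets are filled by
    :func:`expand_ranks` and empty before that.
    """

    anchor_id: str
    x: float
    y: float
    own_species_idx: int
    species_idx: frozenset[int]
    genus_idx: frozenset[int] = frozenset()
    family_idx: frozenset[int] = frozenset()

    def replace_species(self, new_species: set[int]) -> "LabelSet":
        """Rebuild with a re-indexed species set (rank sets are reset)."""
        own = self.own_species_idx if self.own_species_idx in new_species \
            else min(new_species)
        return replace(self, species_idx=frozenset(new_species),
                       own_species_idx=own,
                       genus_idx=frozenset(), family_idx=frozenset())


@dataclass(frozen=True)
class TaxonIndex:
    """Lexicographic name <-> integer index maps for the three ranks.

    Serialized with every model checkpoint and prediction map so that
    column s always means the same species.
    """

    species_names: tuple[str, ...]
    genus_names: tuple[str, ...]
    family_names: tuple[str, ...]
    genus_of_species: tuple[int, ...]   # species index -> genus index
    family_of_genus: tuple[int, ...]    # genus index -> family index

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_genera(self) -> int:
        return len(self.genus_names)

    @property
    def n_families(self) -> int:
        return len(self.family_names)

    def family_of_species(self, s: int) -> int:
        return self.family_of_genus[self.genus_of_species[s]]

    def to_json(self) -> str:
        return json.dumps({
            "species": list(self.species_names),
            "genera": list(self.genus_names),
            "families": list(self.family_names),
            "genus_of_species": list(self.genus_of_species),
            "family_of_genus": list(self.family_of_genus),
        })

    @classmethod
    def from_json(cls, text: str) -> "TaxonIndex":
        d = json.loads(text)
        return cls(tuple(d["species"]), tuple(d["genera"]), tuple(d["families"]),
                   tuple(d["genus_of_species"]), tuple(d["family_of_genus"]))


def species_index(occs: Sequence[Occurrence]) -> list[str]:
    """Lexicographic species name -> index order for a curated dataset."""
    return sorted({o.species for o in occs})


def neighbor_impute(occs: Sequence[Occurrence],
                    radius_m: float = 256.0) -> tuple[list[LabelSet], list[str]]:
    """Build one label set per anchor occurrence.

    ``species_idx`` of anchor i is the set of species of all occurrences j
    (including i itself) with Euclidean center distance <= ``radius_m`` —
    the records whose 256 x 256 m image footprints overlap the anchor's.
    Anchors are never merged.  Returns the label sets (input order) and the
    lexicographic species index they use.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    names = species_index(occs)
    sp_idx = {name: i for i, name in enumerate(names)}
    xy = np.array([(o.x, o.y) for o in occs], dtype=float).reshape(-1, 2)
    own = np.array([sp_idx[o.species] for o in occs], dtype=int)
    out: list[LabelSet] = []
    if len(occs) == 0:
        return out, names
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, radius_m)
    for i, o in enumerate(occs):
        members = frozenset(int(own[j]) for j in neighbors[i]) | {int(own[i])}
        out.append(LabelSet(anchor_id=o.record_id, x=o.x, y=o.y,
                            own_species_idx=int(own[i]),
                            species_idx=frozenset(members)))
    return out, names


def expand_ranks(labels: Sequence[LabelSet], species_names: Sequence[str],
                 taxonomy: TaxonomyTable) -> tuple[list[LabelSet], TaxonIndex]:
    """Fill genus/family sets as taxonomy images of each species set.

    Genus and family index orders are lexicographic by name.  Species
    missing from the taxonomy are fatal (all offenders listed).
    """
    missing = [s for s in species_names if s not in taxonomy]
    if missing:
        raise KeyError(f"species missing from taxonomy: {missing}")
    genus_names = sorted({taxonomy.genus(s) for s in species_names})
    family_names = sorted({taxonomy.family(s) for s in species_names})
    g_idx = {g: i for i, g in enumerate(genus_names)}
    f_idx = {f: i for i, f in enumerate(family_names)}
    genus_of_species = tuple(g_idx[taxonomy.genus(s)] for s in species_names)
    family_of_genus = tuple(
        f_idx[taxonomy.family_of_genus[g]] for g in genus_names)
    index = TaxonIndex(tuple(species_names), tuple(genus_names),
                       tuple(family_names), genus_of_species, family_of_genus)
    out = []
    for ls in labels:
        genera = frozenset(genus_of_species[s] for s in ls.species_idx)
        families = frozenset(family_of_genus[g] for g in genera)
        out.append(replace(ls, genus_idx=genera, family_idx=families))
    return out, index


def labels_to_frame(labels: Sequence[LabelSet],
                    index: TaxonIndex) -> pd.DataFrame:
    """Serialize label sets as one row per (anchor, rank, taxon) membership."""
    rows = []
    for ls in labels:
        for s in sorted(ls.species_idx):
            rows.append((ls.anchor_id, "species", s, index.species_names[s]))
        for g in sorted(ls.genus_idx):
            rows.append((ls.anchor_id, "genus", g, index.genus_names[g]))
        for f in sorted(ls.family_idx):
            rows.append((ls.anchor_id, "family", f, index.family_names[f]))
    return pd.DataFrame(rows, columns=["anchor_id", "rank", "taxon_index",
                                       "taxon_name"])


def write_labels(directory: str | Path, labels: Sequence[LabelSet],
                 index: TaxonIndex) -> None:
    """Write labels.csv (memberships), anchors.csv (coordinates + own
    species) and the taxon index JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels_to_frame(labels, index).to_csv(directory / "labels.csv", index=False)
    anchors = pd.DataFrame(
        [(ls.anchor_id, ls.x, ls.y, ls.own_species_idx) for ls in labels],
        columns=["anchor_id", "x", "y", "own_species_idx"])
    anchors.to_csv(directory / "anchors.csv", index=False)
    (directory / "taxon_index.json").write_text(index.to_json())
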