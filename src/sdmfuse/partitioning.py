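"""Leakage-free train/test partitions.

Species observations are strongly spatially autocorrelated, and the climate
raster's coarse pixels mean two points up to ~1.2 km apart can share the
exact same covariate values.  Both split modes therefore enforce a 1,300 m
exclusion buffer between train and test:

* **uniform split** — seeded rejection sampling of test anchors from the
  whole extent; a candidate is accepted only if every non-overlapping
  neighbor (center distance > the 256 m image-overlap radius) is more than
  1,300 m away, and all of its overlapping neighbors are dragged into the
  test set with it;
* **latitudinal folds** — consecutive one-degree latitude bands; fold k
  tests on band k and trains on everything outside the band and farther
  than 1,300 m from the band's edges.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import geo
from .labeling import LabelSet

log = logging.getLogger(__name__)

DEFAULT_EXCLUSION_M = 1300.0
DEFAULT_OVERLAP_M = 256.0
#: realized held-out share of the reference uniform partition; a default
#: target, not a constraint.
DEFAULT_TEST_FRACTION = 0.0188


@dataclass(frozen=True)
class SplitSpec:
    """A train/test assignment of anchor ids.

    For ``kind='uniform'``, ``test_seed_ids`` are the anchors accepted by
    the exclusion test; the remaining test anchors are their overlapping
    neighbors, declared as overlaps rather than independently buffered.
    """

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    exclusion_radius_m: float
    kind: str  # "uniform" | "block"
    block_index: int | None = None
    test_seed_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValueError("train and test ids overlap")

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "train": sorted(self.train_ids),
            "test": sorted(self.test_ids),
            "test_seeds": sorted(self.test_seed_ids),
            "exclusion_radius_m": self.exclusion_radius_m,
            "block_index": self.block_index,
        })

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(frozenset(d["train"]), frozenset(d["test"]),
                   d["exclusion_radius_m"], d["kind"], d.get("block_index"),
                   frozenset(d.get("test_seeds", [])))


def _anchor_arrays(labels: Sequence[LabelSet]):
    ids = [ls.anchor_id for ls in labels]
    xy = np.array([(ls.x, ls.y) for ls in labels], dtype=float).reshape(-1, 2)
    return ids, xy


def uniform_split(labels: Sequence[LabelSet],
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  exclusion_radius_m: float = DEFAULT_EXCLUSION_M,
                  overlap_radius_m: float = DEFAULT_OVERLAP_M,
                  seed: int = 0) -> SplitSpec:
    """Sample a buffered uniform test set.

    Candidates are visited in a seeded random permutation.  A candidate is
    accepted iff its nearest non-overlapping neighbor (distance
    > ``overlap_radius_m``) is farther than ``exclusion_radius_m``; on
    acceptance, the candidate and every anchor within ``overlap_radius_m``
    of it join the test set.  Sampling stops once the test set reaches
    ``test_fraction`` of anchors, or with a warning when candidates run out.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(labels) < 2:
        raise ValueError("need at least 2 anchors to split")
    ids, xy = _anchor_arrays(labels)
    n = len(ids)
    target = max(1, round(test_fraction * n))
    tree = cKDTree(xy)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    in_test = np.zeros(n, dtype=bool)
    seeds: list[int] = []
    for i in order:
        if in_test[i]:
            continue
        if int(in_test.sum()) >= target:
            break
        near = tree.query_ball_point(xy[i], exclusion_radius_m)
        overlap = tree.query_ball_point(xy[i], overlap_radius_m)
        # any neighbor inside the buffer but outside the overlap radius
        # would leak; reject the candidate.
        if set(near) - set(overlap):
            continue
        seeds.append(int(i))
        in_test[overlap] = True
        in_test[i] = True
    if int(in_test.sum()) < target:
        if not seeds:
            log.warning("uniform_split: no eligible test candidates")
        else:
            log.warning("uniform_split: candidate exhaustion at %d/%d test "
                        "anchors", int(in_test.sum()), target)
    test_ids = frozenset(ids[i] for i in np.flatnonzero(in_test))
    train_ids = frozenset(ids[i] for i in np.flatnonzero(~in_test))
    return SplitSpec(train_ids, test_ids, exclusion_radius_m, "uniform",
                     test_seed_ids=frozenset(ids[i] for i in seeds))


def latitudinal_folds(labels: Sequence[LabelSet], crs: str,
                      n_bands: int = 10,
                      exclusion_radius_m: float = DEFAULT_EXCLUSION_M
                      ) -> list[SplitSpec]:
    """Spatial block cross-validation over one-degree latitude bands.

    Bands are half-open ``[lo, lo + 1)`` degree intervals starting at the
    integer degree below the southernmost anchor.  Fold k holds out band k;
    training anchors inside the band or within ``exclusion_radius_m`` of
    its edges (projected vertical distance) are removed.
    """
    projected = geo.parse_crs(crs)
    if projected is None:
        raise geo.CRSError("latitudinal folds need a projected working CRS")
    ids, xy = _anchor_arrays(labels)
    lat = np.atleast_1d(geo.latitude_of(xy[:, 0], xy[:, 1], projected))
    lo0 = math.floor(lat.min())
    folds: list[SplitSpec] = []
    for k in range(n_bands):
        lo, hi = lo0 + k, lo0 + k + 1
        in_band = (lat >= lo) & (lat < hi)
        if not in_band.any():
            log.warning("latitudinal fold %d: empty band [%d, %d)", k, lo, hi)
        # projected vertical distance from each anchor to the band envelope
        dist = np.zeros(len(ids))
        for i in np.flatnonzero(~in_band):
            x, y = xy[i]
            if lat[i] < lo:
                y_edge = geo.northing_of_latitude(x, y, lo, projected)
            else:
                y_edge = geo.northing_of_latitude(x, y, hi, projected)
            dist[i] = abs(y - y_edge)
        train = ~in_band & (dist > exclusion_radius_m)
        folds.append(SplitSpec(
            train_ids=frozenset(ids[i] for i in np.flatnonzero(train)),
            test_ids=frozenset(ids[i] for i in np.flatnonzero(in_band)),
            exclusion_radius_m=exclusion_radius_m,
            kind="block", block_index=k,
            test_seed_ids=frozenset(ids[i] for i in np.flatnonzero(in_band))))
    return folds


def check_exclusion(split: SplitSpec, labels: Sequence[LabelSet]) -> float:
    """Brute-force minimum distance from train anchors to buffered test
    anchors (the ``test_seed_ids``); ``inf`` when either side is empty.

    Test anchors that entered only as declared overlaps of a seed are
    excluded from the check, mirroring how the buffer is defined.
    """
    ids, xy = _anchor_arrays(labels)
    pos = {a: xy[i] for i, a in enumerate(ids)}
    train = np.array([pos[a] for a in split.train_ids]).reshape(-1, 2)
    seeds = split.test_seed_ids or split.test_ids
    test = np.array([pos[a] for a in seeds]).reshape(-1, 2)
    if len(train) == 0 or len(test) == 0:
        return float("inf")
    d = np.hypot(train[:, None, 0] - test[None, :, 0],
                 train[:, None, 1] - test[None, :, 1])
    return float(d.min())
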