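"""Strided map prediction and spatial/temporal community-change statistics.

A trained model is slid across an imagery raster: each window of
``window_px`` pixels (climate sampled at the window center) yields one
S-vector of species presence probabilities assigned to that window's
output cell.  With 1 m imagery and a stride of 50 this produces species
maps at 50 m resolution.

Two turnover statistics are computed on such probability stacks:

* **spatial community change** — an edge detector for ecotones: per cell,
  the mean Euclidean norm of the difference between the cell's S-vector
  and each of its (up to 8) neighbors' S-vectors;
* **temporal community change** — per cell, the Euclidean distance between
  the S-vectors predicted from imagery at two dates.

The same operators applied to per-band standardized, block-averaged raw
imagery provide the null comparison baselines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import _BaseModel, predict_probabilities
from .raster import GridTransform, Raster, block_average, write_raster, read_raster
from .sampling import ClimateNormalizer, extract_climate_vector, scale_image

log = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PredictionMap:
    """Georeferenced per-pixel, per-species presence probabilities.

    ``transform`` maps output (row, col) indices to the projected
    coordinates of each cell's *center* (the corresponding window center).
    """

    probs: np.ndarray  # (S, R, C) in [0, 1]
    transform: GridTransform
    crs: str
    species_names: list[str] = field(default_factory=list)
    window_px: int = 256
    stride_px: int = 256

    def __post_init__(self) -> None:
        if self.probs.ndim != 3 or min(self.probs.shape[1:]) < 1:
            raise ValueError("probs must be (S, R, C) with R, C >= 1")
        if not np.all(np.isfinite(self.probs)):
            raise ValueError("probabilities must be finite")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        write_raster(path, Raster(self.probs.astype(np.float32),
                                  self.transform, self.crs,
                                  band_names=list(self.species_names)))
        sidecar = {"window_px": self.window_px, "stride_px": self.stride_px,
                   "species": list(self.species_names)}
        path.with_suffix(path.suffix + ".map.json").write_text(
            json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "PredictionMap":
        path = Path(path)
        raster = read_raster(path)
        meta = json.loads(path.with_suffix(path.suffix + ".map.json").read_text())
        return cls(raster.data.astype(float), raster.transform, raster.crs,
                   meta["species"], meta["window_px"], meta["stride_px"])


def predict_map(model: _BaseModel, imagery: Raster, climate: Raster,
                normalizer: ClimateNormalizer, window_px: int = 256,
                stride_px: int = 50, species_names=None,
                batch_size: int = 128) -> PredictionMap:
    """Slide the model across ``imagery`` with the given stride.

    Output rows/cols count ``floor((H - window) / stride) + 1`` windows;
    each output cell carries the S probabilities of its window and is
    georeferenced to the window center, where the climate vector is also
    sampled (zero — the per-band mean — where climate is missing, with a
    warning).
    """
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    rows, cols = imagery.shape
    if rows < window_px or cols < window_px:
        raise ValueError(f"raster {rows}x{cols} smaller than the "
                         f"{window_px} px prediction window")
    r_out = (rows - window_px) // stride_px + 1
    c_out = (cols - window_px) // stride_px + 1
    centers_r = np.arange(r_out) * stride_px + window_px / 2.0
    centers_c = np.arange(c_out) * stride_px + window_px / 2.0

    n_missing = 0
    probs = np.empty((model.config.n_species, r_out, c_out))
    batch_img, batch_clim, batch_pos = [], [], []

    def flush():
        if not batch_img:
            return
        scores = predict_probabilities(
            model, (np.stack(batch_img), np.stack(batch_clim)))
        for (rr, cc), row in zip(batch_pos, scores):
            probs[:, rr, cc] = row
        batch_img.clear(), batch_clim.clear(), batch_pos.clear()

    for i in range(r_out):
        for j in range(c_out):
            r0, c0 = i * stride_px, j * stride_px
            patch = scale_image(
                imagery.data[:, r0:r0 + window_px, c0:c0 + window_px])
            x, y = imagery.transform.xy(centers_r[i], centers_c[j])
            clim = extract_climate_vector(climate, normalizer, float(x), float(y))
            if clim is None:
                clim = np.zeros(len(normalizer.mean))
                n_missing += 1
            batch_img.append(patch)
            batch_clim.append(clim)
            batch_pos.append((i, j))
            if len(batch_img) >= batch_size:
                flush()
    flush()
    if n_missing:
        log.warning("predict_map: %d windows had no climate pixel; used the "
                    "per-band mean", n_missing)

    t = imagery.transform
    x00, y00 = t.xy(centers_r[0], centers_c[0])
    out_transform = GridTransform(float(x00), float(y00),
                                  t.dx * stride_px, t.dy * stride_px)
    return PredictionMap(probs, out_transform, imagery.crs,
                         list(species_names or []), window_px, stride_px)


def spatial_community_change(pmap: PredictionMap) -> np.ndarray:
    """Averaged one-neighbor Euclidean norm: the ecotone edge detector.

    Per cell, the mean over its existing 8-neighborhood of
    ``||p(cell) - p(neighbor)||_2`` across the S species probabilities;
    border cells average over their available neighbors only.
    """
    probs = pmap.probs
    _, r, c = probs.shape
    if r < 2 and c < 2:
        log.warning("spatial_community_change on a single-cell map is zero")
        return np.zeros((r, c))
    return _spatial_on_stack(probs)


def temporal_community_change(map_a: PredictionMap,
                              map_b: PredictionMap) -> np.ndarray:
    """Per-cell Euclidean distance between two dates' probability stacks."""
    if map_a.probs.shape != map_b.probs.shape:
        raise ValueError("prediction maps have different grids or species")
    if map_a.species_names and map_b.species_names \
            and map_a.species_names != map_b.species_names:
        raise ValueError("prediction maps index different species")
    return np.sqrt(((map_a.probs - map_b.probs) ** 2).sum(axis=0))


def _standardized_blocks(raster: Raster, cell_m: float) -> np.ndarray:
    block = max(1, int(round(cell_m / raster.resolution)))
    data = raster.data.astype(float)
    mean = data.mean(axis=(1, 2), keepdims=True)
    std = data.std(axis=(1, 2), keepdims=True)
    std[std == 0] = 1.0
    return block_average((data - mean) / std, block)


def raw_image_change(raster_a: Raster, raster_b: Raster | None = None,
                     mode: str = "spatial", cell_m: float = 256.0) -> np.ndarray:
    """The community-change operators applied to raw imagery bands.

    Bands are z-scored over each raster and block-averaged to ``cell_m``
    resolution; then the spatial (8-neighbor averaged norm over band
    vectors of ``raster_a``) or temporal (per-cell distance between the two
    rasters) operator runs on the band vectors.  These are the null
    baselines the model-based change maps are compared against.
    """
    if mode not in ("spatial", "temporal"):
        raise ValueError("mode must be 'spatial' or 'temporal'")
    blocks_a = _standardized_blocks(raster_a, cell_m)
    if mode == "spatial":
        return _spatial_on_stack(blocks_a)
    if raster_b is None:
        raise ValueError("temporal mode needs two rasters")
    if raster_a.shape != raster_b.shape:
        raise ValueError("rasters are not co-registered")
    blocks_b = _standardized_blocks(raster_b, cell_m)
    return np.sqrt(((blocks_a - blocks_b) ** 2).sum(axis=0))


def _spatial_on_stack(stack: np.ndarray) -> np.ndarray:
    """8-neighbor averaged Euclidean norm on an arbitrary (B, R, C) stack."""
    _, r, c = stack.shape
    acc = np.zeros((r, c))
    cnt = np.zeros((r, c))
    for dr, dc in _NEIGHBOR_OFFSETS:
        src_r = slice(max(0, dr), r + min(0, dr))
        src_c = slice(max(0, dc), c + min(0, dc))
        dst_r = slice(max(0, -dr), r + min(0, -dr))
        dst_c = slice(max(0, -dc), c + min(0, -dc))
        diff = stack[:, dst_r, dst_c] - stack[:, src_r, src_c]
        acc[dst_r, dst_c] += np.sqrt((diff ** 2).sum(axis=0))
        cnt[dst_r, dst_c] += 1
    return acc / np.maximum(cnt, 1)
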