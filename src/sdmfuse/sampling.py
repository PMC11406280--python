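"""Per-anchor model inputs: image patches, climate vectors, completeness.

Each training/evaluation unit pairs a 4-band (RGB + infrared) image patch
centered on the anchor with the standardized climate vector of the pixel
containing the anchor.  Climate covariates are standardized per band to
mean 0 / SD 1 over the valid study region before any model sees them;
imagery is scaled into [0, 1] by the integer dtype maximum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point

from .labeling import LabelSet
from .raster import Raster

log = logging.getLogger(__name__)


@dataclass
class SampleRecord:
    """One anchor's assembled model inputs and targets."""

    anchor_id: str
    x: float
    y: float
    image: np.ndarray        # (4, H, W) reflectance in [0, 1]
    climate: np.ndarray      # (B,) standardized covariates
    completeness: float      # (0, 1], sampling-effort weight
    labels: LabelSet

    def __post_init__(self) -> None:
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        if not np.all(np.isfinite(self.climate)):
            raise ValueError("climate vector must be finite")
        if not 0 < self.completeness <= 1:
            raise ValueError("completeness must be in (0, 1]")


@dataclass(frozen=True)
class ClimateNormalizer:
    """Per-band mean and (population) standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            raise ValueError("all standard deviations must be positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ClimateNormalizer":
        d = json.loads(text)
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float))


def scale_image(patch: np.ndarray) -> np.ndarray:
    """Scale integer pixel data into [0, 1] by the dtype maximum."""
    if np.issubdtype(patch.dtype, np.integer):
        return patch.astype(np.float32) / np.iinfo(patch.dtype).max
    return np.clip(patch.astype(np.float32), 0.0, 1.0)


def extract_image_patch(raster: Raster, x: float, y: float,
                        size_px: int = 256) -> np.ndarray | None:
    """Extract the ``size_px`` window whose center pixel contains (x, y).

    Returns ``None`` (a drop signal, not an error) when the point is
    outside the raster or the window does not fit inside it — anchors near
    the edge are dropped rather than padded, since padding would fabricate
    land cover.
    """
    if raster.n_bands < 4:
        raise ValueError("imagery raster must have >= 4 bands")
    rows, cols = raster.shape
    row, col = raster.transform.rowcol(x, y)
    row, col = int(row), int(col)
    if not (0 <= row < rows and 0 <= col < cols):
        return None
    half = size_px // 2
    r0, c0 = row - half, col - half
    if r0 < 0 or c0 < 0 or r0 + size_px > rows or c0 + size_px > cols:
        return None
    patch = raster.data[:, r0:r0 + size_px, c0:c0 + size_px]
    return scale_image(patch)


def fit_climate_normalizer(raster: Raster, mask=None) -> ClimateNormalizer:
    """Per-band mean/SD over all valid pixels, optionally inside ``mask``.

    SD uses the population (ddof=0) convention.  A band that is constant
    within the mask is fatal — it cannot be standardized.
    """
    b, rows, cols = raster.data.shape
    valid = np.ones((rows, cols), dtype=bool)
    if raster.nodata is not None:
        valid &= ~np.any(raster.data == raster.nodata, axis=0)
    if mask is not None:
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        xs, ys = raster.transform.xy(rr + 0.5, cc + 0.5)
        from shapely.prepared import prep
        prepared = prep(mask)
        inside = np.array([prepared.covers(Point(px, py))
                           for px, py in zip(xs.ravel(), ys.ravel())])
        valid &= inside.reshape(rows, cols)
    if not valid.any():
        raise ValueError("no valid pixels to fit the climate normalizer")
    vals = raster.data[:, valid].astype(float)
    mean = vals.mean(axis=1)
    std = vals.std(axis=1)
    if np.any(std == 0):
        bad = list(np.flatnonzero(std == 0))
        raise ValueError(f"constant climate band(s) {bad}: SD is zero")
    return ClimateNormalizer(mean, std)


def extract_climate_vector(raster: Raster, normalizer: ClimateNormalizer,
                           x: float, y: float) -> np.ndarray | None:
    """Standardized band values of the pixel containing (x, y).

    No interpolation: the half-open pixel cell owning the point wins.
    Returns ``None`` (drop signal) outside the raster or on nodata.
    """
    if not bool(raster.contains(x, y)):
        return None
    values = raster.sample(x, y).reshape(-1).astype(float)
    return normalizer.apply(values)


def assemble_samples(labels: Sequence[LabelSet], imagery: Raster,
                     climate: Raster, normalizer: ClimateNormalizer,
                     completeness: Mapping[str, float] | None = None,
                     patch_px: int = 256) -> list[SampleRecord]:
    """Inner-join labels with extractable inputs, ordered by anchor_id.

    Anchors whose image window does not fit or whose climate pixel is
    missing are dropped and logged.  When no completeness map is given,
    every anchor gets weight 1.0.
    """
    out = []
    dropped = 0
    for ls in sorted(labels, key=lambda l: l.anchor_id):
        image = extract_image_patch(imagery, ls.x, ls.y, patch_px)
        clim = extract_climate_vector(climate, normalizer, ls.x, ls.y)
        if image is None or clim is None:
            dropped += 1
            continue
        c = 1.0 if completeness is None else float(completeness[ls.anchor_id])
        out.append(SampleRecord(ls.anchor_id, ls.x, ls.y, image, clim, c, ls))
    if dropped:
        log.info("assemble_samples: dropped %d anchors missing inputs", dropped)
    if not out:
        raise ValueError("no anchors had complete inputs")
    return out
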