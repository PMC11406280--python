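"""Seeded virtual-ecosystem simulator.

Every pipeline stage is testable without downloads against worlds built
here.  A world emulates the structure of the real inputs:

* ``env`` — B spatially smooth environmental fields (the climate analog),
  standardized per band;
* ``landcover`` — a categorical fine-scale layer thresholded from an
  *independent*, weakly smoothed field: visible in imagery, invisible in
  climate.  This separation makes the fused-vs-single-modality model
  comparisons identifiable by construction;
* ``imagery`` — a 4-band uint8 texture raster at ``m`` pixels per cell;
  each land-cover class has a distinct 4-band signature plus per-pixel
  texture noise, so imagery carries information only through land cover;
* species niches — presence of species s at cell v iff
  ``sigmoid(w_s . env(v) + a_s[landcover(v)] + b_s) > u_s`` with u_s
  calibrated so prevalence lands in [0.02, 0.5].  Half the species have
  zero land-cover affinity (climate-determined), half have strong
  affinities (land-cover-driven);
* ``effort`` — a positive sampling-intensity field emulating the spatial
  observation bias of citizen science; occurrences are drawn from it with
  per-species detection probabilities, so recorded species lists are
  incomplete by construction.

Everything is reproducible bit-for-bit from the seed and size parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .mapping import PredictionMap
from .raster import GridTransform, Raster, write_raster

DEFAULT_ORIGIN = (500_000.0, 4_000_000.0)  # interior of UTM zone 10N
DEFAULT_CRS = "EPSG:32610"


@dataclass
class SyntheticWorld:
    env: np.ndarray            # (B, R, C) standardized smooth fields
    landcover: np.ndarray      # (R, C) int class labels
    imagery: np.ndarray        # (4, R*m, C*m) uint8
    weights: np.ndarray        # (S, B) env niche weights
    affinities: np.ndarray     # (S, K) land-cover affinities
    intercepts: np.ndarray     # (S,)
    thresholds: np.ndarray     # (S,) presence cutoffs u_s
    prob: np.ndarray           # (S, R, C) niche suitability sigmoid
    true_presence: np.ndarray  # (S, R, C) bool
    effort: np.ndarray         # (R, C) >= 0 sampling intensity
    class_signatures: np.ndarray  # (K, 4) imagery band means per class
    landcover_driven: np.ndarray  # (S,) bool
    seed: int
    cell_m: float = 256.0
    m: int = 8
    origin: tuple[float, float] = DEFAULT_ORIGIN
    crs: str = DEFAULT_CRS

    # -- grids -------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.prob.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.landcover.shape

    def cell_transform(self) -> GridTransform:
        x0, y0 = self.origin
        return GridTransform(x0, y0, self.cell_m, -self.cell_m)

    def climate_raster(self) -> Raster:
        names = [f"bio{i + 1:02d}" for i in range(self.env.shape[0])]
        return Raster(self.env.copy(), self.cell_transform(), self.crs,
                      band_names=names)

    def imagery_raster(self) -> Raster:
        x0, y0 = self.origin
        res = self.cell_m / self.m
        return Raster(self.imagery.copy(), GridTransform(x0, y0, res, -res),
                      self.crs, band_names=["red", "green", "blue", "infrared"])

    def boundary(self):
        x0, y0 = self.origin
        rows, cols = self.shape
        return box(x0, y0 - rows * self.cell_m, x0 + cols * self.cell_m, y0)

    def species_names(self) -> list[str]:
        return [f"sp{i:04d}" for i in range(self.n_species)]

    def probability_map(self) -> PredictionMap:
        """Niche suitability as a prediction-map stack (the change-metric
        oracle: what a perfect model would predict per cell)."""
        t = self.cell_transform()
        center = GridTransform(t.x0 + 0.5 * t.dx, t.y0 + 0.5 * t.dy, t.dx, t.dy)
        return PredictionMap(self.prob.copy(), center, self.crs,
                             self.species_names(), window_px=self.m,
                             stride_px=self.m)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (field - field.mean()) / field.std()


def _render_imagery(landcover: np.ndarray, signatures: np.ndarray, m: int,
                    texture_sd: float, rng: np.random.Generator) -> np.ndarray:
    rows, cols = landcover.shape
    up = np.kron(landcover, np.ones((m, m), dtype=int))
    img = signatures[up].transpose(2, 0, 1).astype(float)
    img += rng.normal(0.0, texture_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_world(seed: int, R: int = 64, C: int = 64, S: int = 32,
                   B: int = 19, m: int = 8, cell_m: float = 256.0,
                   n_landcover: int = 4, env_smooth_cells: float = 8.0,
                   landcover_smooth_cells: float = 1.5,
                   texture_sd: float = 12.0,
                   effort_smooth_cells: float = 6.0,
                   effort_concentration: float = 2.0,
                   n_active_env: int = 3,
                   ecotone_width_cells: float | None = None,
                   origin: tuple[float, float] = DEFAULT_ORIGIN,
                   crs: str = DEFAULT_CRS) -> SyntheticWorld:
    """Build a reproducible virtual ecosystem.

    ``ecotone_width_cells`` plants a sharp left-right transition: the first
    environmental band becomes a steep column-wise gradient and every
    species receives a strong (alternating-sign) weight on it, so true
    community turnover concentrates on the central column band.
    """
    if min(R, C, S, B, m) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    env = np.stack([_smooth_field(rng, (R, C), env_smooth_cells)
                    for _ in range(B)])
    if ecotone_width_cells is not None:
        gradient = np.tanh((np.arange(C) - (C - 1) / 2.0) / ecotone_width_cells)
        field = np.broadcast_to(gradient, (R, C)).astype(float)
        env[0] = (field - field.mean()) / field.std()

    lc_field = _smooth_field(rng, (R, C), landcover_smooth_cells)
    edges = np.quantile(lc_field, np.linspace(0, 1, n_landcover + 1)[1:-1])
    landcover = np.digitize(lc_field, edges)

    # class signatures: per band, evenly separated levels in random order
    levels = np.linspace(60.0, 200.0, n_landcover)
    signatures = np.stack([rng.permutation(levels) for _ in range(4)], axis=1)
    imagery = _render_imagery(landcover, signatures, m, texture_sd, rng)

    # niches: a few active env bands per species; land-cover affinities for
    # the second half of the species list
    weights = np.zeros((S, B))
    n_active = min(n_active_env, B)
    for s in range(S):
        bands = rng.choice(B, size=n_active, replace=False)
        weights[s, bands] = rng.normal(0.0, 1.5, size=n_active)
    if ecotone_width_cells is not None:
        weights[:, 0] = 4.0 * np.where(np.arange(S) % 2 == 0, 1.0, -1.0)
    landcover_driven = np.arange(S) >= S - S // 2
    affinities = np.zeros((S, n_landcover))
    affinities[landcover_driven] = rng.normal(
        0.0, 3.0, size=(int(landcover_driven.sum()), n_landcover))
    intercepts = np.zeros(S)

    score = np.einsum("sb,brc->src", weights, env) \
        + affinities[:, landcover] + intercepts[:, None, None]
    prob = 1.0 / (1.0 + np.exp(-score))
    thresholds = np.empty(S)
    presence = np.empty((S, R, C), dtype=bool)
    targets = rng.uniform(0.05, 0.35, size=S)
    for s in range(S):
        ok = False
        for attempt in range(8):
            u = float(np.quantile(prob[s], 1.0 - targets[s]))
            mask = prob[s] > u
            prevalence = mask.mean()
            if 0.02 <= prevalence <= 0.5 and mask.any():
                ok = True
                break
            targets[s] = float(np.clip(targets[s] * 1.5, 0.05, 0.45))
        if not ok:
            raise RuntimeError(f"prevalence calibration failed for species {s}")
        thresholds[s] = u
        presence[s] = mask

    effort = np.exp(effort_concentration
                    * _smooth_field(rng, (R, C), effort_smooth_cells))
    effort /= effort.mean()

    return SyntheticWorld(env=env, landcover=landcover, imagery=imagery,
                          weights=weights, affinities=affinities,
                          intercepts=intercepts, thresholds=thresholds,
                          prob=prob, true_presence=presence, effort=effort,
                          class_signatures=signatures,
                          landcover_driven=landcover_driven, seed=seed,
                          cell_m=cell_m, m=m, origin=origin, crs=crs)


def simulate_occurrences(world: SyntheticWorld, n_target: int,
                         detectability=0.5, seed: int = 0,
                         effort: np.ndarray | None = None) -> pd.DataFrame:
    """Draw spatially biased, incomplete occurrence records.

    ``n_target`` anchor locations are sampled proportional to the effort
    field (cells may repeat); at each anchor every truly present species is
    recorded independently with probability ``detectability`` (scalar or
    per-species).  Rows conform to the occurrence CSV schema.
    """
    if n_target == 0:
        return pd.DataFrame(columns=["record_id", "species", "x", "y", "date",
                                     "source", "coord_uncertainty_m"])
    effort = world.effort if effort is None else np.asarray(effort, float)
    if not (effort > 0).any():
        raise ValueError("effort field is nowhere positive")
    det = np.broadcast_to(np.asarray(detectability, float),
                          (world.n_species,))
    if det.min() <= 0 or det.max() > 1:
        raise ValueError("detectability must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows_n, cols_n = world.shape
    p = (effort / effort.sum()).ravel()
    cells = rng.choice(rows_n * cols_n, size=n_target, p=p)
    names = world.species_names()
    t = world.cell_transform()
    records = []
    for i, cell in enumerate(cells):
        r, c = divmod(int(cell), cols_n)
        x, y = t.xy(r + rng.uniform(0.05, 0.95), c + rng.uniform(0.05, 0.95))
        present = np.flatnonzero(world.true_presence[:, r, c])
        detected = present[rng.random(present.size) < det[present]]
        for s in detected:
            records.append((f"r{i:06d}s{s:04d}", names[s], float(x), float(y),
                            "2020-06-15", "synthetic", 10.0))
    return pd.DataFrame(records, columns=["record_id", "species", "x", "y",
                                          "date", "source",
                                          "coord_uncertainty_m"])


def taxonomy_frame(world: SyntheticWorld) -> pd.DataFrame:
    """Synthetic taxonomy: every 4 species share a genus, every 4 genera a
    family."""
    rows = []
    for i, name in enumerate(world.species_names()):
        rows.append((name, f"gen{i // 4:03d}", f"fam{i // 16:03d}"))
    return pd.DataFrame(rows, columns=["species", "genus", "family"])


def true_presence_map(world: SyntheticWorld, species: int) -> Raster:
    """Ground-truth presence raster for one species (evaluation oracle)."""
    if not 0 <= species < world.n_species:
        raise IndexError(f"species index {species} out of range")
    return Raster(world.true_presence[species].astype(np.uint8)[None],
                  world.cell_transform(), world.crs,
                  band_names=[world.species_names()[species]])


def disturb_landcover(world: SyntheticWorld, row0: int, row1: int,
                      col0: int, col1: int, seed: int = 0) -> SyntheticWorld:
    """Flip land-cover classes inside a cell rectangle and regenerate
    imagery, presence and suitability accordingly (a planted disturbance:
    climate is untouched, the ground surface changes)."""
    rng = np.random.default_rng(seed)
    landcover = world.landcover.copy()
    k = world.class_signatures.shape[0]
    landcover[row0:row1, col0:col1] = (landcover[row0:row1, col0:col1] + 1) % k
    imagery = _render_imagery(landcover, world.class_signatures, world.m,
                              12.0, rng)
    score = np.einsum("sb,brc->src", world.weights, world.env) \
        + world.affinities[:, landcover] + world.intercepts[:, None, None]
    prob = 1.0 / (1.0 + np.exp(-score))
    presence = prob > world.thresholds[:, None, None]
    return replace(world, landcover=landcover, imagery=imagery, prob=prob,
                   true_presence=presence)


def write_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Write imagery/climate/truth rasters, occurrences and taxonomy CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(directory / "imagery.tif", world.imagery_raster())
    write_raster(directory / "climate.tif", world.climate_raster())
    truth = Raster(world.true_presence.astype(np.uint8),
                   world.cell_transform(), world.crs,
                   band_names=world.species_names())
    write_raster(directory / "true_presence.tif", truth)
    taxonomy_frame(world).to_csv(directory / "taxonomy.csv", index=False)
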