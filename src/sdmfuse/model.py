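"""The three species-distribution model architectures.

* ``climate-mlp`` — a feed-forward network on the B bioclimatic covariates:
  B -> 1000 -> 1000 -> dropout(0.25) -> 2000 -> 2000 -> three parallel rank
  heads (species / genus / family), ReLU between hidden layers.
* ``image-only`` — a residual convolutional encoder over 4-band (RGB +
  infrared) patches: stem conv, then one stride-2 residual stage per depth
  level with doubling width, global average pooling, three rank heads.
* ``fused`` — the image encoder's pooled features concatenated with the
  climate MLP's penultimate activations, passed through one fully connected
  fusion layer, then the three rank heads; trained jointly end-to-end.

All heads emit logits; species presence probabilities are independent
sigmoids (multilabel — rows need not sum to 1).  Width/depth are fully
configurable so the same architecture trains at desk scale on 32x32
patches or at full scale on 256x256 ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .labeling import TaxonIndex
from .sampling import ClimateNormalizer


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference full-scale layout (1000/1000 then
    2000/2000 MLP neurons, 0.25 dropout); encoder width/depth and all layer
    sizes scale down for desk use.
    """

    n_species: int
    n_genera: int
    n_families: int
    in_channels: int = 4
    climate_dim: int = 19
    mlp_hidden: tuple[int, ...] = (1000, 1000, 2000, 2000)
    mlp_dropout: float = 0.25
    encoder_width: int = 64
    encoder_depth: int = 4
    fusion_dim: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_genera, self.n_families) < 1:
            raise ValueError("rank output counts must be >= 1")
        if min(self.in_channels, self.climate_dim, self.encoder_width,
               self.encoder_depth, self.fusion_dim, *self.mlp_hidden) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.mlp_dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def encoder_feature_dim(self) -> int:
        return self.encoder_width * 2 ** (self.encoder_depth - 1)

    @property
    def min_patch_px(self) -> int:
        """Smallest square input the encoder can downsample."""
        return 2 ** self.encoder_depth


@dataclass
class ModelOutputs:
    species_logits: np.ndarray  # (N, S)
    genus_logits: np.ndarray    # (N, G)
    family_logits: np.ndarray   # (N, F)


class _RankHeads:
    """Three parallel linear heads on a shared representation."""

    def __init__(self, feat_dim: int, config: ModelConfig,
                 rng: np.random.Generator):
        self.species = nn.Linear(feat_dim, config.n_species, rng)
        self.genus = nn.Linear(feat_dim, config.n_genera, rng)
        self.family = nn.Linear(feat_dim, config.n_families, rng)

    def params(self):
        return self.species.params() + self.genus.params() + self.family.params()

    def forward(self, feat: np.ndarray, train: bool) -> ModelOutputs:
        return ModelOutputs(self.species.forward(feat, train),
                            self.genus.forward(feat, train),
                            self.family.forward(feat, train))

    def backward(self, d_species, d_genus, d_family) -> np.ndarray:
        return (self.species.backward(d_species)
                + self.genus.backward(d_genus)
                + self.family.backward(d_family))


def _mlp_trunk(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    h = config.mlp_hidden
    if len(h) < 2:
        raise ValueError("mlp_hidden needs at least two layers")
    mid = len(h) // 2
    layers: list[nn.Layer] = []
    n_in = config.climate_dim
    for i, width in enumerate(h):
        layers.append(nn.Linear(n_in, width, rng))
        layers.append(nn.ReLU())
        if i == mid - 1:
            layers.append(nn.Dropout(config.mlp_dropout, rng))
        n_in = width
    return nn.Sequential(*layers)


def _encoder_trunk(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    w = config.encoder_width
    layers: list[nn.Layer] = [
        nn.Conv2d(config.in_channels, w, 3, 1, 1, rng),
        nn.BatchNorm(w), nn.ReLU()]
    c_in = w
    for i in range(config.encoder_depth):
        c_out = w * 2 ** i
        layers.append(nn.ResidualBlock(c_in, c_out, 2, rng))
        c_in = c_out
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


class _BaseModel:
    arch: str = ""
    inputs: str = ""  # "climate" | "image" | "both"

    def __init__(self, config: ModelConfig):
        self.config = config

    def params(self) -> list[nn.Param]:
        raise NotImplementedError

    def forward(self, images, climate, train: bool = False) -> ModelOutputs:
        raise NotImplementedError

    def backward(self, d_species, d_genus, d_family) -> None:
        raise NotImplementedError

    # -- state (parameters + batch-norm running statistics) ---------------
    def _layers(self):
        seen: list[nn.Layer] = []

        def walk(obj):
            if isinstance(obj, nn.Sequential):
                for sub in obj.layers:
                    walk(sub)
            elif isinstance(obj, nn.ResidualBlock):
                walk(obj.conv1), walk(obj.bn1), walk(obj.conv2), walk(obj.bn2)
                if obj.shortcut is not None:
                    walk(obj.shortcut)
            elif isinstance(obj, nn.Layer):
                seen.append(obj)

        for part in self._parts():
            walk(part)
        return seen

    def _parts(self):
        raise NotImplementedError

    def state(self) -> list[np.ndarray]:
        arrays = nn.snapshot(self.params())
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm):
                arrays += [layer.running_mean.copy(), layer.running_var.copy()]
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        n = len(self.params())
        nn.restore(self.params(), arrays[:n])
        rest = list(arrays[n:])
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = rest.pop(0)
                layer.running_var[...] = rest.pop(0)

    def _check_image(self, images: np.ndarray) -> None:
        if images.ndim != 4 or images.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected images (N, {self.config.in_channels}, H, W), "
                f"got {images.shape}")
        if min(images.shape[2], images.shape[3]) < self.config.min_patch_px:
            raise ValueError(
                f"patch too small for encoder depth {self.config.encoder_depth}: "
                f"needs >= {self.config.min_patch_px} px per side")


class ClimateMLP(_BaseModel):
    arch = "climate-mlp"
    inputs = "climate"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.trunk = _mlp_trunk(config, rng)
        self.heads = _RankHeads(config.mlp_hidden[-1], config, rng)

    def _parts(self):
        return [self.trunk, self.heads.species, self.heads.genus,
                self.heads.family]

    def params(self):
        return self.trunk.params() + self.heads.params()

    def forward(self, images, climate, train=False):
        feat = self.trunk.forward(np.asarray(climate, dtype=float), train)
        return self.heads.forward(feat, train)

    def backward(self, d_species, d_genus, d_family):
        self.trunk.backward(self.heads.backward(d_species, d_genus, d_family))


class ImageEncoderModel(_BaseModel):
    arch = "image-only"
    inputs = "image"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.trunk = _encoder_trunk(config, rng)
        self.heads = _RankHeads(config.encoder_feature_dim, config, rng)

    def _parts(self):
        return [self.trunk, self.heads.species, self.heads.genus,
                self.heads.family]

    def params(self):
        return self.trunk.params() + self.heads.params()

    def forward(self, images, climate, train=False):
        images = np.asarray(images, dtype=float)
        self._check_image(images)
        feat = self.trunk.forward(images, train)
        return self.heads.forward(feat, train)

    def backward(self, d_species, d_genus, d_family):
        self.trunk.backward(self.heads.backward(d_species, d_genus, d_family))


class FusedModel(_BaseModel):
    """Image encoder + climate MLP joined by one fusion layer."""

    arch = "fused"
    inputs = "both"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.encoder = _encoder_trunk(config, rng)
        self.mlp = _mlp_trunk(config, rng)
        concat_dim = config.encoder_feature_dim + config.mlp_hidden[-1]
        self.fusion = nn.Linear(concat_dim, config.fusion_dim, rng)
        self.fusion_relu = nn.ReLU()
        self.heads = _RankHeads(config.fusion_dim, config, rng)

    def _parts(self):
        return [self.encoder, self.mlp, self.fusion, self.fusion_relu,
                self.heads.species, self.heads.genus, self.heads.family]

    def params(self):
        return (self.encoder.params() + self.mlp.params()
                + self.fusion.params() + self.heads.params())

    def forward(self, images, climate, train=False):
        images = np.asarray(images, dtype=float)
        self._check_image(images)
        img_feat = self.encoder.forward(images, train)
        clim_feat = self.mlp.forward(np.asarray(climate, dtype=float), train)
        self._split = img_feat.shape[1]
        fused = self.fusion_relu.forward(
            self.fusion.forward(np.concatenate([img_feat, clim_feat], axis=1),
                                train), train)
        return self.heads.forward(fused, train)

    def backward(self, d_species, d_genus, d_family):
        d = self.heads.backward(d_species, d_genus, d_family)
        d = self.fusion.backward(self.fusion_relu.backward(d))
        self.encoder.backward(d[:, :self._split])
        self.mlp.backward(d[:, self._split:])


_ARCHS = {cls.arch: cls for cls in (ClimateMLP, ImageEncoderModel, FusedModel)}


def build_climate_mlp(config: ModelConfig) -> ClimateMLP:
    return ClimateMLP(config)


def build_image_encoder(config: ModelConfig) -> ImageEncoderModel:
    return ImageEncoderModel(config)


def build_fused_model(config: ModelConfig) -> FusedModel:
    return FusedModel(config)


def build_model(arch: str, config: ModelConfig) -> _BaseModel:
    try:
        return _ARCHS[arch](config)
    except KeyError:
        raise ValueError(f"unknown architecture {arch!r}; "
                         f"choose from {sorted(_ARCHS)}") from None


def predict_probabilities(model: _BaseModel,
                          samples,
                          batch_size: int = 256) -> np.ndarray:
    """Species presence probabilities, shape (N, S).

    Probabilities are independent sigmoids of the species logits; a row is
    a multilabel prediction and need not sum to 1.  ``samples`` may be a
    sequence of :class:`~sdmfuse.sampling.SampleRecord` or an
    ``(images, climate)`` array pair.
    """
    if isinstance(samples, tuple):
        images, climate = samples
    else:
        images = np.stack([s.image for s in samples])
        climate = np.stack([s.climate for s in samples])
    n = len(climate) if images is None else len(images)
    out = np.empty((n, model.config.n_species))
    for lo in range(0, n, batch_size):
        hi = min(n, lo + batch_size)
        img = None if images is None else images[lo:hi]
        outputs = model.forward(img, climate[lo:hi], train=False)
        out[lo:hi] = nn.sigmoid(outputs.species_logits)
    return out


def save_checkpoint(path: str | Path, model: _BaseModel,
                    taxon_index: TaxonIndex | None = None,
                    normalizer: ClimateNormalizer | None = None) -> None:
    """Weights + config (+ taxon index and climate normalizer) in one file."""
    path = Path(path)
    meta = {"arch": model.arch, "config": asdict(model.config)}
    if taxon_index is not None:
        meta["taxon_index"] = json.loads(taxon_index.to_json())
    if normalizer is not None:
        meta["normalizer"] = json.loads(normalizer.to_json())
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path):
    """Returns ``(model, taxon_index | None, normalizer | None)``."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg = meta["config"]
    cfg["mlp_hidden"] = tuple(cfg["mlp_hidden"])
    config = ModelConfig(**cfg)
    model = build_model(meta["arch"], config)
    model.load_state(arrays)
    index = (TaxonIndex.from_json(json.dumps(meta["taxon_index"]))
             if "taxon_index" in meta else None)
    norm = (ClimateNormalizer.from_json(json.dumps(meta["normalizer"]))
            if "normalizer" in meta else None)
    return model, index, norm
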