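"""Embryo phenotype classifier: architecture, augmentation, staged training.

The model graph is ``backbone -> CBAM -> global average pooling ->
dense(512, ReLU) -> dropout(0.5) -> dense(n_classes, softmax)``.

Training follows a three-phase transfer-learning schedule:

=====  ==========================  =======================  ========
phase  data                        backbone layers frozen   init LR
=====  ==========================  =======================  ========
1      external-style corpus       all                      1e-4
2      external-style corpus       first 1/3                1e-5
3      own-style corpus            none                     1e-5
=====  ==========================  =======================  ========

Every phase uses Adam, categorical cross-entropy, batch size 16, an epoch
cap of 100, and halves the learning rate (floor 1e-6) when validation loss
fails to improve for five consecutive epochs.  "Layers" for the freeze
fraction are the backbone's parameter-bearing layers counted from the input
end; the attention block and the dense head are new layers and stay
trainable in every phase.

Augmentation (training images only): the red channel is multiplied by 1.5
and clipped, emphasising blood-clot foci, followed by random rotation, zoom,
horizontal flipping and brightness jitter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .nn.attention import CBAM, AttentionConfig
from .nn.layers import (
    Conv2D,
    Dense,
    Dropout,
    FeatureScale,
    GlobalAveragePooling,
    MaxPool2D,
    ReLU,
)
from .nn.network import Network, TrainSettings, fit
from .phenotypes import CLASS_NAMES, N_CLASSES, PhenotypeClass
from .synthetic import LabeledImage


class ConfigurationError(ValueError):
    """Raised for invalid model/run configuration."""


_KNOWN_BACKBONES = ("tiny", "resnet50", "vgg16", "xception")

#: Channel widths of the tiny backbone's four conv(3x3)+ReLU+maxpool stages.
TINY_CHANNELS = (8, 16, 32, 64)
TINY_INPUT_SIZE = 64

#: Fixed gain applied to the pooled descriptor entering the dense head
#: (optimisation conditioning; see FeatureScale).
FEATURE_GAIN = 2000.0

#: First-layer colour-opponent/luminance filter weights (R, G, B per channel).
_OPPONENT_COMBOS = (
    (1, 1, 1),     # luminance
    (-1, -1, -1),  # darkness
    (2, -1, -1),   # red excess (blood foci)
    (-1, 2, -1),   # green excess
    (-1, -1, 2),   # blue excess (pericardial fluid)
    (1, 1, -2),    # yellow excess (yolk)
    (-1, -1, 0),   # red+green deficit (darkened yolk)
    (1, -1, 0),    # red-green opponent
)


def _opponent_stem(rng: np.random.Generator) -> Conv2D:
    """First convolution initialised as smoothed colour-opponent filters.

    A classical analytic initialisation: each output channel is a 3x3 box
    average of one fixed linear colour combination, giving the stem the
    generic colour/luminance selectivity that deeper stages can refine
    during fine-tuning.
    """
    conv = Conv2D(3, TINY_CHANNELS[0], 3, rng=rng, name="backbone/conv1")
    weight = np.zeros_like(conv.weight)
    box = np.ones((3, 3)) / 9.0
    for out_ch, combo in enumerate(_OPPONENT_COMBOS):
        for in_ch, w in enumerate(combo):
            weight[:, :, in_ch, out_ch] = w * box
    conv.weight = weight
    conv.dweight = np.zeros_like(weight)
    return conv


def _propagating_conv(in_ch: int, out_ch: int, rng: np.random.Generator, name: str) -> Conv2D:
    """Deeper backbone convolution: identity pass-through of the incoming
    channels plus damped random filters on the remaining outputs, so the
    stem's opponent statistics survive pooling while leaving capacity for
    learned texture features."""
    conv = Conv2D(in_ch, out_ch, 3, rng=rng, name=name)
    weight = conv.weight * 0.3
    for i in range(min(in_ch, out_ch)):
        weight[:, :, :, i] = 0.0
        weight[1, 1, i, i] = 1.0
    conv.weight = weight
    conv.dweight = np.zeros_like(weight)
    return conv


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    """Feature-extractor choice.

    ``tiny`` is a four-stage convolution/pooling stack trained from random
    initialisation, sized for desk-scale experiments; the published ImageNet
    backbones are recognised names but this build cannot construct them
    (their graphs and pretrained weights are not bundled).
    """

    name: Literal["tiny", "resnet50", "vgg16", "xception"] = "tiny"
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.name not in _KNOWN_BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; expected one of {_KNOWN_BACKBONES}"
            )
        if self.name == "tiny" and self.pretrained:
            raise ConfigurationError("the tiny backbone has no pretrained weights")

    @property
    def weighted_layer_count(self) -> int:
        if self.name == "tiny":
            return len(TINY_CHANNELS)
        raise ConfigurationError(f"backbone {self.name!r} is not available in this build")

    @property
    def input_size(self) -> int:
        if self.name == "tiny":
            return TINY_INPUT_SIZE
        return 299 if self.name == "xception" else 224


@dataclasses.dataclass(frozen=True)
class PhaseConfig:
    """Optimisation settings for one training phase."""

    phase_id: int
    data_source: Literal["external", "own"]
    frozen_fraction: float
    initial_learning_rate: float
    batch_size: int = 16
    max_epochs: int = 100
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_learning_rate: float = 1e-6

    def __post_init__(self) -> None:
        if self.phase_id not in (1, 2, 3):
            raise ConfigurationError("phase_id must be 1, 2 or 3")
        if not 0.0 <= self.frozen_fraction <= 1.0:
            raise ConfigurationError("frozen_fraction must lie in [0, 1]")
        if self.initial_learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("invalid optimisation settings")

    @classmethod
    def for_phase(cls, phase_id: int, **overrides) -> "PhaseConfig":
        defaults = {
            1: dict(data_source="external", frozen_fraction=1.0, initial_learning_rate=1e-4),
            2: dict(data_source="external", frozen_fraction=1.0 / 3.0, initial_learning_rate=1e-5),
            3: dict(data_source="own", frozen_fraction=0.0, initial_learning_rate=1e-5),
        }
        if phase_id not in defaults:
            raise ConfigurationError("phase_id must be 1, 2 or 3")
        kwargs = {**defaults[phase_id], **overrides}
        return cls(phase_id=phase_id, **kwargs)

    def train_settings(self) -> TrainSettings:
        return TrainSettings(
            learning_rate=self.initial_learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            min_learning_rate=self.min_learning_rate,
        )


def n_frozen_layers(n_layers: int, fraction: float) -> int:
    """Layers frozen from the input end: round(n * fraction) to nearest."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("frozen fraction must lie in [0, 1]")
    return int(n_layers * fraction + 0.5)


@dataclasses.dataclass
class EmbryoClassifier:
    """A (possibly trained) phenotype classifier.

    Wraps the network together with the class-index mapping and the
    preprocessing convention, so that prediction on raw uint8 images is
    self-contained.
    """

    network: Network
    backbone: BackboneSpec
    attention: AttentionConfig
    class_names: tuple[str, ...] = CLASS_NAMES
    preprocessing: str = "unit_scale"
    histories: dict[str, list[dict[str, float]]] = dataclasses.field(default_factory=dict)

    @property
    def input_size(self) -> int:
        return self.backbone.input_size

    @property
    def backbone_layers(self) -> list[Conv2D]:
        """Parameter-bearing backbone layers in topological order."""
        convs = [l for l in self.network.layers if isinstance(l, Conv2D)]
        return convs[: self.backbone.weighted_layer_count]

    @property
    def head_layers(self):
        backbone = set(map(id, self.backbone_layers))
        return [l for l in self.network.layers if l.params() and id(l) not in backbone]

    def set_frozen_fraction(self, fraction: float) -> None:
        """Freeze the first ``fraction`` of backbone layers; head stays trainable."""
        layers = self.backbone_layers
        k = n_frozen_layers(len(layers), fraction)
        for i, layer in enumerate(layers):
            layer.trainable = i >= k
        for layer in self.head_layers:
            layer.trainable = True

    def preprocess(self, pixels: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> float in [-1, 1], resized to the input size.

        Symmetric scaling (the convention several published backbones use)
        keeps the first convolution's responses zero-mean, which conditions
        training far better than raw [0, 1] intensities.  If the model's
        preprocessing convention includes the red-channel boost, it is
        applied here — uniformly at training and inference time, so there is
        no train/test intensity shift.
        """
        pixels = np.asarray(pixels)
        if "red_boost" in self.preprocessing:
            boosted = pixels.astype(float)
            boosted[..., 0] = np.clip(boosted[..., 0] * RED_BOOST_FACTOR, 0, 255)
            pixels = boosted
        x = np.asarray(pixels, dtype=float) / 255.0
        s = self.input_size
        if x.shape[1] != s or x.shape[2] != s:
            x = np.stack([resize(im, (s, s, 3), anti_aliasing=True) for im in x])
        return (x - 0.5) * 2.0

    def predict_proba(self, images: Sequence[LabeledImage] | np.ndarray) -> np.ndarray:
        if not isinstance(images, np.ndarray):
            images = np.stack([im.pixels for im in images])
        return self.network.predict_proba(self.preprocess(images))

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (NPZ) plus a JSON sidecar describing the model."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_dict())
        sidecar = {
            "backbone": dataclasses.asdict(self.backbone),
            "attention": dataclasses.asdict(self.attention),
            "class_names": list(self.class_names),
            "preprocessing": self.preprocessing,
            "histories": self.histories,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EmbryoClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = build_model(
            BackboneSpec(**sidecar["backbone"]),
            AttentionConfig(**sidecar["attention"]),
            n_classes=len(sidecar["class_names"]),
        )
        with np.load(path.with_suffix(".npz")) as data:
            model.network.load_state_dict({k: data[k] for k in data.files})
        model.class_names = tuple(sidecar["class_names"])
        model.histories = sidecar.get("histories", {})
        return model


def build_model(
    backbone: BackboneSpec,
    attention: AttentionConfig | None = None,
    n_classes: int = N_CLASSES,
    seed: int = 0,
    red_boost: bool = False,
) -> EmbryoClassifier:
    """Assemble backbone -> CBAM -> GAP -> dense-512 -> dropout-0.5 -> softmax.

    ``red_boost`` makes the red-channel boost part of the model's
    preprocessing convention (off by default; see the augmentation notes in
    the package documentation).
    """
    attention = attention or AttentionConfig()
    if backbone.name != "tiny":
        raise ConfigurationError(
            f"backbone {backbone.name!r} is not available in this build; use 'tiny'"
        )
    rng = np.random.default_rng(seed)
    layers = [_opponent_stem(rng), ReLU(), MaxPool2D()]
    in_ch = TINY_CHANNELS[0]
    for i, out_ch in enumerate(TINY_CHANNELS[1:], start=2):
        layers += [
            _propagating_conv(in_ch, out_ch, rng, name=f"backbone/conv{i}"),
            ReLU(),
            MaxPool2D(),
        ]
        in_ch = out_ch
    layers += [
        CBAM(in_ch, attention, rng=rng, name="cbam"),
        GlobalAveragePooling(),
        FeatureScale(FEATURE_GAIN),
        Dense(in_ch, 512, rng=rng, name="head/dense1"),
        ReLU(),
        Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31 - 1))),
        Dense(512, n_classes, rng=rng, name="head/logits"),
    ]
    # Zero-init the softmax layer: the model starts from the uniform
    # distribution instead of confident noise, which matters at the small
    # learning rates of the staged protocol.
    layers[-1].weight[...] = 0.0
    return EmbryoClassifier(
        network=Network(layers),
        backbone=backbone,
        attention=attention,
        preprocessing="red_boost_center_unit" if red_boost else "center_unit",
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeometricAugmentParams:
    """Random transform ranges (package defaults; tune via configuration)."""

    rotation_range: float = 20.0     # degrees, +/-
    zoom_range: float = 0.15         # fractional, +/-
    horizontal_flip: bool = True
    brightness_range: float = 0.2    # fractional, +/-

    def __post_init__(self) -> None:
        if self.rotation_range < 0 or self.zoom_range < 0 or self.brightness_range < 0:
            raise ConfigurationError("augmentation ranges must be non-negative")
        if self.zoom_range >= 1 or self.brightness_range >= 1:
            raise ConfigurationError("zoom/brightness ranges must be below 1")


RED_BOOST_FACTOR = 1.5


def augment_red_boost(img: LabeledImage, factor: float = RED_BOOST_FACTOR) -> LabeledImage:
    """Multiply the red channel by ``factor`` (clipped at 255); label kept."""
    if factor <= 0:
        raise ValueError("red-boost factor must be positive")
    pixels = img.pixels.astype(float)
    pixels[..., 0] = np.clip(pixels[..., 0] * factor, 0, 255)
    return LabeledImage(
        pixels=pixels.astype(np.uint8),
        label=img.label,
        provenance=f"{img.provenance} | red_boost x{factor}",
    )


def _random_affine(
    shape: tuple[int, int], params: GeometricAugmentParams, rng: np.random.Generator
) -> tuple[AffineTransform, bool, float]:
    angle = np.deg2rad(rng.uniform(-params.rotation_range, params.rotation_range))
    zoom = 1.0 + rng.uniform(-params.zoom_range, params.zoom_range)
    flip = bool(params.horizontal_flip and rng.random() < 0.5)
    brightness = 1.0 + rng.uniform(-params.brightness_range, params.brightness_range)
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, scale=(zoom, zoom))
        + AffineTransform(translation=center)
    )
    return tf, flip, brightness


def _apply_geometric(
    x: np.ndarray, params: GeometricAugmentParams, rng: np.random.Generator
) -> np.ndarray:
    """Transform one float image in [0, 1]; shape preserved."""
    tf, flip, brightness = _random_affine(x.shape[:2], params, rng)
    out = x
    identity_affine = (
        params.rotation_range == 0 and params.zoom_range == 0
    )
    if not identity_affine:
        out = warp(out, tf.inverse, mode="edge", order=1)
    if flip:
        out = out[:, ::-1, :]
    out = np.clip(out * brightness, 0.0, 1.0)
    return out


def augment_geometric(
    img: LabeledImage, params: GeometricAugmentParams, seed: int
) -> LabeledImage:
    """Random rotation/zoom/flip/brightness; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    out = _apply_geometric(img.pixels.astype(float) / 255.0, params, rng)
    return LabeledImage(
        pixels=np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8),
        label=img.label,
        provenance=f"{img.provenance} | geometric seed={seed}",
    )


def make_batch_augmenter(params: GeometricAugmentParams):
    """Adapter for the training loop: augments a preprocessed [-1, 1] batch.

    The geometric transforms are defined on [0, 1] intensities, so the batch
    is mapped back to that range, transformed, and re-centred.
    """

    def augment(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        unit = batch * 0.5 + 0.5
        out = np.stack([_apply_geometric(im, params, rng) for im in unit])
        return (out - 0.5) * 2.0

    return augment


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------

def split_train_val(
    data: Sequence[LabeledImage], seed: int, val_fraction: float = 0.2
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Stratified, disjoint, exhaustive 8:2 split (deterministic per seed)."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    by_class: dict[PhenotypeClass, list[int]] = {}
    for i, img in enumerate(data):
        by_class.setdefault(img.label, []).append(i)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in sorted(by_class):
        idx = np.array(by_class[cls])
        if len(idx) < 5:
            raise ValueError(
                f"class {cls.name} has {len(idx)} images; at least 5 required for stratification"
            )
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.extend(idx[:n_val].tolist())
        train_idx.extend(idx[n_val:].tolist())
    return [data[i] for i in sorted(train_idx)], [data[i] for i in sorted(val_idx)]


def _prepare_arrays(
    model: EmbryoClassifier,
    data: Sequence[LabeledImage],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    train, val = split_train_val(data, seed=seed)
    x_train = model.preprocess(np.stack([im.pixels for im in train]))
    y_train = np.array([int(im.label) for im in train])
    x_val = model.preprocess(np.stack([im.pixels for im in val]))
    y_val = np.array([int(im.label) for im in val])
    return x_train, y_train, x_val, y_val


def run_phase(
    model: EmbryoClassifier,
    data: Sequence[LabeledImage],
    cfg: PhaseConfig,
    seed: int = 0,
    augment: GeometricAugmentParams | None = None,
) -> list[dict[str, float]]:
    """Train one phase in place; returns the per-epoch history.

    Exactly the first ``frozen_fraction`` of backbone weighted layers are
    excluded from updates; random geometric augmentation is applied to
    training batches only (the red boost, when enabled, lives in the model's
    preprocessing convention).
    """
    if not data:
        raise ValueError("training data must be non-empty")
    model.set_frozen_fraction(cfg.frozen_fraction)
    augment = augment if augment is not None else GeometricAugmentParams()
    x_train, y_train, x_val, y_val = _prepare_arrays(model, data, seed)
    rng = np.random.default_rng(seed + 1)
    history = fit(
        model.network,
        x_train,
        y_train,
        x_val,
        y_val,
        cfg.train_settings(),
        rng=rng,
        augment_fn=make_batch_augmenter(augment),
    )
    model.histories[f"phase{cfg.phase_id}"] = history
    return history


def _check_corpus(name: str, data: Sequence[LabeledImage]) -> None:
    present = {img.label for img in data}
    missing = set(PhenotypeClass) - present
    if missing:
        names = ", ".join(m.name for m in sorted(missing))
        raise ValueError(f"{name} corpus is missing classes: {names}")


def train_three_phase(
    backbone: BackboneSpec,
    corpus_external_style: Sequence[LabeledImage],
    corpus_own_style: Sequence[LabeledImage],
    seed: int = 0,
    attention: AttentionConfig | None = None,
    phase_overrides: dict | None = None,
    augment: GeometricAugmentParams | None = None,
    red_boost: bool = False,
) -> EmbryoClassifier:
    """Run the full protocol: phases 1-2 on the external-style corpus, phase 3
    on the own-style corpus.  ``phase_overrides`` (e.g. ``{"max_epochs": 15}``)
    apply to every phase."""
    _check_corpus("external-style", corpus_external_style)
    _check_corpus("own-style", corpus_own_style)
    model = build_model(backbone, attention, seed=seed, red_boost=red_boost)
    overrides = phase_overrides or {}
    for phase_id in (1, 2, 3):
        cfg = PhaseConfig.for_phase(phase_id, **overrides)
        data = corpus_external_style if cfg.data_source == "external" else corpus_own_style
        run_phase(model, data, cfg, seed=seed + phase_id, augment=augment)
    return model
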