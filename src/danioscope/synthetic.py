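"""Synthetic embryo images and dose-response tables with known ground truth.

The renderer draws a stylised lateral view of a zebrafish embryo on a light,
noisy background and superimposes the diagnostic feature of each phenotype:

* ``DEAD`` — an opaque, dark, granular coagulated mass filling the body
  outline, with no eye primordia;
* ``EDEMA`` — a pale fluid-filled pericardial bulge adjacent to the heart
  region;
* ``BLOOD_STASIS`` — small, strongly red clot foci inside the body (red
  channel well above green and blue);
* ``NECROSED_YOLK_SAC`` — a darkened, granular yolk ball;
* ``NORMAL`` — an intact elongated body with eyes and a light yolk.

The images are not photorealistic; they reproduce the pixel-level statistics
the classifier relies on (colour of clots, interior opacity, bulge area,
yolk darkness) so that the full training/evaluation loop is testable with a
known answer.  Mortality tables are simulated from a log10-dose probit model
so the LC50 estimator can be validated against simulation ground truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .phenotypes import PhenotypeClass

#: Yolk-darkness value at and above which a render counts as necrosed.
NECROSIS_DARKNESS_THRESHOLD = 0.5

#: Clot pixels must exceed max(green, blue) by at least this margin so that a
#: threshold-and-label detector can re-find them (fixture constant, not a
#: biological claim).
CLOT_RED_MARGIN = 40

_BACKGROUND_LEVEL = 225.0
_BODY_COLOR = np.array([200.0, 185.0, 160.0])
_YOLK_COLOR = np.array([225.0, 200.0, 140.0])
_DEAD_COLOR = np.array([85.0, 75.0, 70.0])
_EYE_COLOR = np.array([60.0, 50.0, 45.0])
_EDEMA_COLOR = np.array([205.0, 215.0, 240.0])
_EDEMA_RIM_COLOR = np.array([110.0, 115.0, 130.0])


@dataclasses.dataclass(frozen=True)
class EmbryoRenderSpec:
    """Parameters of one synthetic embryo render.

    The feature parameters are tied to the phenotype: clots only occur for
    blood stasis, a pericardial bulge only for edema, and a yolk darkness at
    or above :data:`NECROSIS_DARKNESS_THRESHOLD` only for yolk-sac necrosis.
    """

    phenotype: PhenotypeClass
    image_size: int = 224
    body_axis_angle: float = 0.0
    yolk_darkness: float = 0.0
    edema_bulge_scale: float = 0.0
    clot_count: int = 0
    clot_intensity: float = 200.0
    background_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if not 0.0 <= self.yolk_darkness <= 1.0:
            raise ValueError("yolk_darkness must lie in [0, 1]")
        if self.edema_bulge_scale < 0 or self.clot_count < 0:
            raise ValueError("edema_bulge_scale and clot_count must be non-negative")
        p = self.phenotype
        if (self.clot_count > 0) != (p is PhenotypeClass.BLOOD_STASIS):
            raise ValueError("clot_count must be positive iff phenotype is BLOOD_STASIS")
        if (self.edema_bulge_scale > 0) != (p is PhenotypeClass.EDEMA):
            raise ValueError("edema_bulge_scale must be positive iff phenotype is EDEMA")
        necrotic = self.yolk_darkness >= NECROSIS_DARKNESS_THRESHOLD
        if necrotic != (p is PhenotypeClass.NECROSED_YOLK_SAC):
            raise ValueError(
                "yolk_darkness must be >= "
                f"{NECROSIS_DARKNESS_THRESHOLD} iff phenotype is NECROSED_YOLK_SAC"
            )
        if p is PhenotypeClass.BLOOD_STASIS and self.clot_intensity < 100:
            raise ValueError("clot_intensity must be >= 100 for detectable clots")


@dataclasses.dataclass
class LabeledImage:
    """An RGB uint8 raster plus its single phenotype decision class."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: PhenotypeClass
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        self.label = PhenotypeClass(self.label)


def _axes(size: int, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates along/perpendicular to the body axis, origin at centre."""
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xx -= half
    yy -= half
    th = np.deg2rad(angle_deg)
    u = xx * np.cos(th) + yy * np.sin(th)       # along the body axis
    v = -xx * np.sin(th) + yy * np.cos(th)      # perpendicular
    return u, v


def _ellipse(u: np.ndarray, v: np.ndarray, cu: float, cv: float, a: float, b: float) -> np.ndarray:
    return ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2 <= 1.0


def generate_embryo_image(spec: EmbryoRenderSpec) -> LabeledImage:
    """Render one labelled synthetic embryo image.

    Deterministic: the raster is a pure function of the spec (including its
    seed).
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    canvas = np.full((s, s, 3), _BACKGROUND_LEVEL)
    canvas += rng.normal(0.0, spec.background_noise_sd, size=canvas.shape)

    u, v = _axes(s, spec.body_axis_angle)
    trunk = _ellipse(u, v, 0.0, 0.0, 0.36 * s, 0.15 * s)
    head = _ellipse(u, v, 0.28 * s, 0.0, 0.13 * s, 0.12 * s)
    body = trunk | head
    yolk = _ellipse(u, v, -0.06 * s, 0.05 * s, 0.12 * s, 0.10 * s)

    texture = rng.normal(0.0, 6.0, size=(s, s, 1))

    if spec.phenotype is PhenotypeClass.DEAD:
        # Opaque coagulated interior, strongly granular, no eyes.
        granules = rng.normal(0.0, 18.0, size=(s, s, 1))
        canvas[body] = _DEAD_COLOR + granules[body]
    else:
        canvas[body] = _BODY_COLOR + texture[body]
        yolk_color = _YOLK_COLOR.copy()
        if spec.yolk_darkness > 0:
            yolk_color = yolk_color * (1.0 - 0.75 * spec.yolk_darkness)
        canvas[yolk] = yolk_color + texture[yolk]
        if spec.phenotype is PhenotypeClass.NECROSED_YOLK_SAC:
            granules = rng.normal(0.0, 22.0, size=(s, s, 1))
            canvas[yolk] += granules[yolk]
        # Two eye primordia in the head.
        for dv in (-0.05 * s, 0.05 * s):
            eye = _ellipse(u, v, 0.30 * s, dv, max(1.5, 0.025 * s), max(1.5, 0.025 * s))
            canvas[eye] = _EYE_COLOR

    if spec.phenotype is PhenotypeClass.EDEMA:
        # Fluid-filled pericardial sac below the head/heart region: a pale
        # bluish interior bounded by a visible membrane rim.
        sc = spec.edema_bulge_scale
        a_b, b_b = 0.14 * s * sc, 0.11 * s * sc
        d2 = ((u - 0.16 * s) / a_b) ** 2 + ((v - 0.16 * s) / b_b) ** 2
        bulge = d2 <= 1.0
        rim = (d2 <= 1.0) & (d2 >= 0.72)
        fill = bulge & ~rim & ~body
        canvas[fill] = _EDEMA_COLOR + texture[fill]
        canvas[rim & ~body] = _EDEMA_RIM_COLOR

    if spec.phenotype is PhenotypeClass.BLOOD_STASIS:
        _draw_clots(canvas, rng, spec, u, v, body_halfaxes=(0.33 * s, 0.12 * s))

    pixels = np.clip(canvas, 0, 255).astype(np.uint8)
    prov = (
        f"synthetic render phenotype={spec.phenotype.name} size={s} "
        f"angle={spec.body_axis_angle:.1f} seed={spec.seed}"
    )
    return LabeledImage(pixels=pixels, label=spec.phenotype, provenance=prov)


def _draw_clots(
    canvas: np.ndarray,
    rng: np.random.Generator,
    spec: EmbryoRenderSpec,
    u: np.ndarray,
    v: np.ndarray,
    body_halfaxes: tuple[float, float],
) -> None:
    """Place well-separated red clot foci inside the trunk."""
    s = spec.image_size
    a, b = body_halfaxes
    clot_color = np.array([spec.clot_intensity, 40.0, 45.0])
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < spec.clot_count and attempts < 1000:
        attempts += 1
        cu = rng.uniform(-a * 0.85, a * 0.85)
        cv = rng.uniform(-b * 0.7, b * 0.7)
        r = rng.uniform(max(1.6, 0.012 * s), max(2.4, 0.02 * s))
        if any((cu - pu) ** 2 + (cv - pv) ** 2 < (r + pr + 2.0) ** 2 for pu, pv, pr in placed):
            continue
        placed.append((cu, cv, r))
    if len(placed) < spec.clot_count:  # pragma: no cover - generous retry budget
        raise RuntimeError("could not place the requested number of clots")
    for cu, cv, r in placed:
        mask = _ellipse(u, v, cu, cv, r, r)
        canvas[mask] = clot_color


def default_render_spec(
    phenotype: PhenotypeClass, rng: np.random.Generator, image_size: int = 224
) -> EmbryoRenderSpec:
    """Draw per-image rendering parameters from the study's nominal ranges."""
    common = dict(
        phenotype=phenotype,
        image_size=image_size,
        body_axis_angle=float(rng.uniform(0.0, 180.0)),
        background_noise_sd=float(rng.uniform(6.0, 10.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if phenotype is PhenotypeClass.BLOOD_STASIS:
        return EmbryoRenderSpec(
            clot_count=int(rng.integers(2, 6)),
            clot_intensity=float(rng.uniform(180.0, 230.0)),
            yolk_darkness=float(rng.uniform(0.0, 0.15)),
            **common,
        )
    if phenotype is PhenotypeClass.EDEMA:
        return EmbryoRenderSpec(
            edema_bulge_scale=float(rng.uniform(0.8, 1.3)),
            yolk_darkness=float(rng.uniform(0.0, 0.15)),
            **common,
        )
    if phenotype is PhenotypeClass.NECROSED_YOLK_SAC:
        return EmbryoRenderSpec(yolk_darkness=float(rng.uniform(0.6, 0.9)), **common)
    if phenotype is PhenotypeClass.DEAD:
        return EmbryoRenderSpec(**common)
    return EmbryoRenderSpec(yolk_darkness=float(rng.uniform(0.0, 0.15)), **common)


def generate_dataset(
    class_counts: Mapping[PhenotypeClass, int],
    image_size: int = 224,
    seed: int = 0,
) -> list[LabeledImage]:
    """Generate ``class_counts[c]`` images per class, reproducibly.

    Per-image render parameters (orientation, feature strength, per-image
    seed) are derived from the single master seed, so two calls with the
    same arguments return identical collections.
    """
    for cls, n in class_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {cls}")
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    for cls in PhenotypeClass:  # fixed class order for reproducibility
        n = int(class_counts.get(cls, 0))
        for _ in range(n):
            spec = default_render_spec(cls, rng, image_size=image_size)
            images.append(generate_embryo_image(spec))
    return images


def write_image_dataset(images: Iterable[LabeledImage], root: str | Path) -> list[Path]:
    """Write images as PNG under ``<root>/<class_name>/<index>.png``."""
    root = Path(root)
    paths: list[Path] = []
    counters = {cls: 0 for cls in PhenotypeClass}
    for img in images:
        sub = root / img.label.name.lower()
        sub.mkdir(parents=True, exist_ok=True)
        path = sub / f"{counters[img.label]:05d}.png"
        Image.fromarray(img.pixels).save(path)
        counters[img.label] += 1
        paths.append(path)
    return paths


def read_image_dataset(root: str | Path) -> list[LabeledImage]:
    """Read a ``<root>/<class_name>/*.png`` directory tree."""
    root = Path(root)
    images: list[LabeledImage] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        label = PhenotypeClass.from_name(sub.name)
        for path in sorted(sub.glob("*.png")):
            pixels = np.asarray(Image.open(path).convert("RGB"))
            images.append(LabeledImage(pixels=pixels, label=label, provenance=str(path)))
    if not images:
        raise ValueError(f"no class sub-directories with PNG images under {root}")
    return images


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DoseResponseTable:
    """Mortality counts per exposure concentration (mg/mL)."""

    concentration: np.ndarray
    n_exposed: np.ndarray
    n_dead: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        n = np.asarray(self.n_exposed, dtype=int)
        d = np.asarray(self.n_dead, dtype=int)
        if not (c.shape == n.shape == d.shape) or c.ndim != 1:
            raise ValueError("columns must be equal-length 1-D arrays")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be unique")
        if np.any(n <= 0) or np.any(d < 0) or np.any(d > n):
            raise ValueError("need 0 <= n_dead <= n_exposed and n_exposed > 0")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "n_exposed", n)
        object.__setattr__(self, "n_dead", d)

    @property
    def mortality_fraction(self) -> np.ndarray:
        return self.n_dead / self.n_exposed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentration,
                "n_exposed": self.n_exposed,
                "n_dead": self.n_dead,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseTable":
        df = pd.read_csv(path)
        return cls(
            concentration=df["concentration"].to_numpy(),
            n_exposed=df["n_exposed"].to_numpy(),
            n_dead=df["n_dead"].to_numpy(),
        )


def probit_mortality_curve(
    concentration: np.ndarray | float, lc50: float, slope: float
) -> np.ndarray | float:
    """Expected mortality fraction Phi(slope * (log10 c - log10 LC50))."""
    from scipy.stats import norm

    c = np.asarray(concentration, dtype=float)
    return norm.cdf(slope * (np.log10(c) - np.log10(lc50)))


def generate_dose_response(
    lc50_true: float,
    slope_true: float,
    concentrations: Sequence[float],
    n_per_dose: int,
    seed: int = 0,
) -> DoseResponseTable:
    """Simulate Bernoulli mortality from a log10-dose probit model.

    At each concentration ``c`` the number dead is drawn as
    ``Binomial(n_per_dose, Phi(slope * (log10 c - log10 LC50)))``.
    """
    if lc50_true <= 0 or slope_true <= 0:
        raise ValueError("lc50_true and slope_true must be positive")
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be at least 1")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = np.random.default_rng(seed)
    p = probit_mortality_curve(conc, lc50_true, slope_true)
    n_dead = rng.binomial(n_per_dose, p)
    return DoseResponseTable(
        concentration=conc,
        n_exposed=np.full(conc.shape, n_per_dose, dtype=int),
        n_dead=n_dead,
    )
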