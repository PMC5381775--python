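"""Synthetic stained-colony generator with exact ground truth.

Emulates micrographs of circular stem-cell colonies after dual chromogen
staining: three color clusters arranged near the RGB gray diagonal
(red-shifted adipogenic, blue-shifted osteogenic, near-white negative)
and a radial differentiation layout with an adipogenic core, osteogenic
belt and undifferentiated rim against the confining wall. Every simulated
image comes with the exact per-pixel ground-truth label map and the
confinement geometry, so classifier and profiler can be validated without
any microscope data.

Randomness uses numpy's PCG64 generator seeded explicitly; a given seed
fully determines image, labels and geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import StainClass
from .errors import ConfigurationError
from .profiler import ConfinementGeometry

#: Default class color means: red-shifted, blue-shifted and near-white
#: clusters along the gray diagonal of RGB space.
DEFAULT_MEANS: dict[StainClass, tuple[float, float, float]] = {
    StainClass.ADIPOGENIC: (180.0, 60.0, 60.0),
    StainClass.OSTEOGENIC: (60.0, 60.0, 180.0),
    StainClass.NEGATIVE: (225.0, 225.0, 225.0),
}

#: Default isotropic color noise SD (8-bit intensity units).
DEFAULT_NOISE_SD = 10.0


@dataclass
class ColorModel:
    """Per-class Gaussian color model in RGB space.

    ``sds`` may give a per-class isotropic SD; classes without an entry
    use the simulation-wide noise SD. The area outside the confinement is
    unstained surface and defaults to the NEGATIVE class model.
    """

    means: dict[StainClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEANS)
    )
    sds: dict[StainClass, float] = field(default_factory=dict)
    background_mean: tuple[float, float, float] | None = None
    background_sd: float | None = None

    def mean_of(self, cls: StainClass) -> np.ndarray:
        return np.asarray(self.means[cls], dtype=np.float64)

    def sd_of(self, cls: StainClass, default: float) -> float:
        return float(self.sds.get(cls, default))

    @property
    def background(self) -> np.ndarray:
        if self.background_mean is not None:
            return np.asarray(self.background_mean, dtype=np.float64)
        return self.mean_of(StainClass.NEGATIVE)


@dataclass
class RadialLayout:
    """Radial class layout: adipogenic core, osteogenic belt, negative rim.

    ``three_zone_step`` assigns classes deterministically by zone;
    ``logistic_blend`` turns the two zone boundaries into smooth logistic
    transitions of width ``blend_width_um``, giving per-radius class
    probabilities. Radii default to 0.5 x and 0.85 x the confinement
    radius when left unset.
    """

    kind: str = "three_zone_step"
    r_adipo_um: float | None = None
    r_osteo_um: float | None = None
    blend_width_um: float = 10.0

    def resolve(self, radius_um: float) -> tuple[float, float]:
        r_a = 0.5 * radius_um if self.r_adipo_um is None else self.r_adipo_um
        r_o = 0.85 * radius_um if self.r_osteo_um is None else self.r_osteo_um
        if not (0 < r_a <= r_o <= radius_um + 1e-9):
            raise ConfigurationError(
                f"zone radii must satisfy 0 < r_adipo <= r_osteo <= radius "
                f"(got {r_a}, {r_o}, radius {radius_um})"
            )
        return r_a, r_o

    def class_probabilities(self, radii_um: np.ndarray, radius_um: float) -> np.ndarray:
        """(N, 3) class probabilities at each radius, class-code order."""
        r_a, r_o = self.resolve(radius_um)
        r = np.asarray(radii_um, dtype=np.float64)
        p = np.zeros((r.size, 3))
        if self.kind == "three_zone_step":
            p[r < r_a, 0] = 1.0
            p[(r >= r_a) & (r < r_o), 1] = 1.0
            p[r >= r_o, 2] = 1.0
        elif self.kind == "logistic_blend":
            w = self.blend_width_um
            core = 1.0 / (1.0 + np.exp((r - r_a) / w))
            rim = 1.0 / (1.0 + np.exp(-(r - r_o) / w))
            p[:, 0] = core
            p[:, 2] = (1.0 - core) * rim
            p[:, 1] = 1.0 - p[:, 0] - p[:, 2]
        else:
            raise ConfigurationError(f"unknown radial layout kind {self.kind!r}")
        return p


@dataclass
class ColonySimParams:
    """Full parameter set of one simulated confinement image."""

    seed: int
    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    diameter_um: float = 200.0
    color_model: ColorModel = field(default_factory=ColorModel)
    layout: RadialLayout = field(default_factory=RadialLayout)
    noise_sd: float = DEFAULT_NOISE_SD
    speckle_count: int = 0
    speckle_radius_px: float = 2.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ConfigurationError("image size must be at least 1x1")
        if self.pixel_size_um <= 0 or self.diameter_um <= 0:
            raise ConfigurationError("pixel size and diameter must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be >= 0")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "image_size": list(self.image_size),
            "pixel_size_um": self.pixel_size_um,
            "diameter_um": self.diameter_um,
            "means": {c.name.lower(): list(self.color_model.means[c]) for c in StainClass},
            "noise_sd": self.noise_sd,
            "layout": {
                "kind": self.layout.kind,
                "r_adipo_um": self.layout.r_adipo_um,
                "r_osteo_um": self.layout.r_osteo_um,
                "blend_width_um": self.layout.blend_width_um,
            },
            "speckle_count": self.speckle_count,
            "speckle_radius_px": self.speckle_radius_px,
            "rng": "numpy PCG64",
        }


def simulate_colony(
    params: ColonySimParams,
) -> tuple[np.ndarray, np.ndarray, ConfinementGeometry]:
    """Simulate one confinement micrograph.

    For each in-circle pixel a class is drawn from the radial layout at
    that pixel's radius, then a color from the class's Gaussian color
    model; outside pixels take the background model and the NEGATIVE
    label. Returns ``(image, labels, geometry)`` — (H, W, 3) uint8,
    (H, W) class codes, and the circle geometry. Bitwise reproducible
    per seed.

    Draw order (fixed for reproducibility): class uniforms for all
    pixels, then speckle positions, then one color-noise normal per
    pixel and channel.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    radius_um = params.diameter_um / 2.0
    geometry = ConfinementGeometry(cx, cy, radius_um / params.pixel_size_um, params.pixel_size_um)

    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    dist_um = (np.hypot(cols - cx, rows - cy) * params.pixel_size_um).ravel()
    inside = dist_um < radius_um

    probs = params.layout.class_probabilities(dist_um, radius_um)
    u = rng.random(h * w)
    cum = np.cumsum(probs, axis=1)
    labels = np.full(h * w, int(StainClass.NEGATIVE), dtype=np.int64)
    drawn = 1 + np.sum(u[:, None] >= cum, axis=1)  # class code 1..3
    labels[inside] = np.minimum(drawn[inside], 3)

    if params.speckle_count > 0:
        _add_speckles(labels.reshape(h, w), params, geometry, rng)

    cm = params.color_model
    means = np.empty((h * w, 3))
    sds = np.empty(h * w)
    for cls in StainClass:
        sel = inside & (labels == int(cls))
        means[sel] = cm.mean_of(cls)
        sds[sel] = cm.sd_of(cls, params.noise_sd)
    means[~inside] = cm.background
    sds[~inside] = cm.background_sd if cm.background_sd is not None else cm.sd_of(
        StainClass.NEGATIVE, params.noise_sd
    )

    noise = rng.standard_normal((h * w, 3))
    colors = np.clip(np.rint(means + noise * sds[:, None]), 0, 255).astype(np.uint8)
    return colors.reshape(h, w, 3), labels.reshape(h, w), geometry


def _add_speckles(
    labels2d: np.ndarray,
    params: ColonySimParams,
    geometry: ConfinementGeometry,
    rng: np.random.Generator,
) -> None:
    """Stamp small adipogenic disks (lipid-droplet-like speckles) in-circle."""
    h, w = labels2d.shape
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    for _ in range(params.speckle_count):
        ang = rng.random() * 2 * np.pi
        rad = np.sqrt(rng.random()) * geometry.radius_px
        sy = geometry.center_y + rad * np.sin(ang)
        sx = geometry.center_x + rad * np.cos(ang)
        disk = np.hypot(cols - sx, rows - sy) <= params.speckle_radius_px
        inside = (
            np.hypot(cols - geometry.center_x, rows - geometry.center_y) < geometry.radius_px
        )
        labels2d[disk & inside] = int(StainClass.ADIPOGENIC)


def simulate_training_crops(
    color_model: ColorModel | None = None,
    crop_size: int | tuple[int, int] = 100,
    n_per_class: int = 1,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    shading_factor: float | None = None,
    shading_fraction: float = 0.5,
) -> list[tuple[np.ndarray, StainClass]]:
    """Generate pure-class reference crops for classifier training.

    One crop per requested item, colors sampled from the class color
    model; ``crop_size`` is a side length or an (H, W) pair.
    ``shading_factor`` < 1 darkens the first ``shading_fraction`` of each
    crop's rows multiplicatively, emulating the dark areas deliberately
    present in real reference micrographs.
    """
    shape = (crop_size, crop_size) if isinstance(crop_size, int) else tuple(crop_size)
    if shape[0] < 1 or shape[1] < 1:
        raise ConfigurationError("crop size must be >= 1")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    cm = color_model if color_model is not None else ColorModel()
    rng = np.random.default_rng(seed)
    crops: list[tuple[np.ndarray, StainClass]] = []
    shade_rows = int(round(shading_fraction * shape[0])) if shading_factor is not None else 0
    for cls in StainClass:
        for _ in range(n_per_class):
            mean = cm.mean_of(cls)
            sd = cm.sd_of(cls, noise_sd)
            colors = mean + rng.standard_normal((*shape, 3)) * sd
            if shade_rows:
                colors[:shade_rows] *= shading_factor
            crops.append((np.clip(np.rint(colors), 0, 255).astype(np.uint8), cls))
    return crops


__all__ = [
    "DEFAULT_MEANS",
    "DEFAULT_NOISE_SD",
    "ColorModel",
    "RadialLayout",
    "ColonySimParams",
    "simulate_colony",
    "simulate_training_crops",
]
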