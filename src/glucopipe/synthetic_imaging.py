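"""Seeded synthetic generator for colorimetric glucose well images.

The GOD/POD assay stains the outlet well of the microfluidic device with a
pink quinonimine complex whose absorbance is proportional to glucose
concentration (Beer-Lambert).  This module renders labeled 8-bit RGB well
images with the statistical structure of a factorial smartphone capture
campaign: 16 concentration classes x 2 lighting conditions x 3 room
locations x 3 camera profiles x 5 replicates = 1440 images.

Color model
-----------
Transmitted channel intensity follows per-channel Beer-Lambert attenuation
of a white-film background::

    I_k(c) = background_k * 10 ** (-absorptivity_k * path_scale * c)

with the green channel absorbed most strongly (a pink product transmits red,
absorbs green).  Lighting, room location and camera white balance act as
multiplicative gains; sensor noise is additive Gaussian, clamped to [0, 255].

Each rendered well is ringed by a dark rim, the cut channel contour of the
polyvinyl film device.  The rim anchors the dark end of every image's
histogram, which is what lets the downstream per-image percentile contrast
stretch cancel illumination gain without erasing the concentration signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: The assay's standard concentration series, mg/dL.
CONCENTRATIONS: tuple[int, ...] = tuple(range(50, 201, 10))

#: Background color of the blank well on the white polyvinyl film.  Kept
#: below 255/max_gain so the brightest condition (location x lighting x
#: white balance up to ~1.13) never clips highlights: smartphone auto
#: exposure holds the white film inside the sensor's dynamic range, and a
#: clipped film would break the illumination-cancelling contrast stretch.
FILM_RGB: tuple[int, int, int] = (220, 220, 220)

#: Color of the dark rim (cut channel contour) around the well.
RIM_RGB: tuple[int, int, int] = (30, 30, 30)

#: Photometric model of the two lighting conditions: overall gain and
#: per-channel tint.  Natural daylight is slightly dimmer and warmer than
#: the fluorescent-lit condition.
LIGHTING_MODEL: dict[str, tuple[float, tuple[float, float, float]]] = {
    "natural": (0.9, (1.03, 1.0, 0.95)),
    "artificial": (1.0, (1.0, 1.0, 1.0)),
}

#: Brightness multiplier of each of the three room locations (+/- 10 %).
LOCATION_GAIN: dict[int, float] = {1: 0.9, 2: 1.0, 3: 1.1}


@dataclass(frozen=True)
class ConcentrationClass:
    """One of the 16 glucose levels, both class label and numeric target.

    ``value`` is the concentration in mg/dL and must lie on the standard
    series 50, 60, ..., 200; ``index`` is the zero-based class index
    ``(value - 50) // 10``.
    """

    value: int

    def __post_init__(self) -> None:
        if self.value not in CONCENTRATIONS:
            raise ValueError(
                f"concentration {self.value} mg/dL is not on the standard "
                f"series {CONCENTRATIONS[0]}..{CONCENTRATIONS[-1]} step 10"
            )

    @property
    def index(self) -> int:
        return (self.value - 50) // 10

    @classmethod
    def from_index(cls, index: int) -> "ConcentrationClass":
        if not 0 <= index < len(CONCENTRATIONS):
            raise ValueError(f"class index {index} out of range 0..15")
        return cls(CONCENTRATIONS[index])


@dataclass(frozen=True)
class AssayColorModel:
    """Per-channel Beer-Lambert attenuation of the quinonimine complex.

    ``absorptivity`` has units 1/(mg/dL); the green coefficient must be the
    largest (pink product).  The default green absorptivity 0.004 maximizes
    the 50-200 mg/dL green-channel separation achievable under Beer-Lambert
    attenuation of an 8-bit background.
    """

    background_rgb: tuple[int, int, int] = (225, 221, 219)
    absorptivity: tuple[float, float, float] = (0.0005, 0.004, 0.0015)
    path_scale: float = 1.0

    def __post_init__(self) -> None:
        a_r, a_g, a_b = self.absorptivity
        if min(self.absorptivity) < 0:
            raise ValueError("absorptivity coefficients must be >= 0")
        if a_g < a_r or a_g < a_b:
            raise ValueError(
                "green absorptivity must dominate (pink complex absorbs green most)"
            )
        if self.path_scale <= 0:
            raise ValueError("path_scale must be positive")


@dataclass(frozen=True)
class CameraProfile:
    """Optics and sensor model of one smartphone camera."""

    name: str
    sensor_resolution: tuple[int, int]  # (H, W) pixels
    focal_length_mm: float
    aperture: float  # f-number
    white_balance_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 3.0  # additive noise scale, intensity units

    def __post_init__(self) -> None:
        if min(self.white_balance_gains) <= 0:
            raise ValueError("white balance gains must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.sensor_resolution) <= 0:
            raise ValueError("sensor resolution must be positive")


#: The three phone cameras of the capture campaign.
DEFAULT_CAMERAS: tuple[CameraProfile, ...] = (
    CameraProfile("iphone-xr", (3024, 4032), 4.0, 1.8, (1.0, 1.0, 1.0), 3.0),
    CameraProfile("moto-g62-5g", (2296, 4080), 4.0, 1.8, (1.02, 1.0, 0.97), 3.0),
    CameraProfile("pixel-6a", (2268, 4032), 4.0, 1.7, (0.98, 1.0, 1.03), 3.0),
)


@dataclass(frozen=True)
class CaptureCondition:
    """Lighting/location/camera/replicate coordinates of one image."""

    lighting: str
    location: int
    camera: CameraProfile
    replicate: int

    def __post_init__(self) -> None:
        if self.lighting not in LIGHTING_MODEL:
            raise ValueError(f"unknown lighting {self.lighting!r}")
        if self.location not in LOCATION_GAIN:
            raise ValueError(f"location must be 1..3, got {self.location}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")

    @property
    def illumination_gain(self) -> float:
        return LIGHTING_MODEL[self.lighting][0] * LOCATION_GAIN[self.location]

    @property
    def tint(self) -> tuple[float, float, float]:
        return LIGHTING_MODEL[self.lighting][1]

    @property
    def channel_gains(self) -> np.ndarray:
        """Combined per-channel multiplier: illumination x tint x white balance."""
        return self.illumination_gain * np.asarray(self.tint) * np.asarray(
            self.camera.white_balance_gains
        )


@dataclass(frozen=True)
class RawImage:
    """An 8-bit RGB capture with its label and provenance."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: ConcentrationClass | None = None
    condition: CaptureCondition | None = None

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {p.shape}")
        if p.shape[0] < 32 or p.shape[1] < 32:
            raise ValueError("image must be at least 32x32")
        if p.dtype != np.uint8:
            raise ValueError("pixels must be uint8")


def concentration_to_rgb(
    c: ConcentrationClass | int, model: AssayColorModel
) -> tuple[int, int, int]:
    """Noise-free well color of a glucose concentration under Beer-Lambert.

    Per channel k: ``round(background_k * 10**(-absorptivity_k * path_scale
    * c))``, clamped to [0, 255].  Monotone non-increasing in concentration
    on every channel.
    """
    value = c.value if isinstance(c, ConcentrationClass) else float(c)
    if value < 0:
        raise ValueError("concentration must be non-negative")
    bg = np.asarray(model.background_rgb, dtype=float)
    a = np.asarray(model.absorptivity, dtype=float)
    transmittance = 10.0 ** (-a * model.path_scale * value)
    channels = np.clip(np.round(bg * transmittance), 0, 255).astype(int)
    return int(channels[0]), int(channels[1]), int(channels[2])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; the 8-bit pipeline contract is
    # round-half-away-from-zero (values here are non-negative).
    return np.floor(x + 0.5)


def _well_masks(
    size: tuple[int, int], shape: str, radius_frac: float, rim_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (well, rim) masks for a centered disc or square well."""
    h, w = size
    r = radius_frac * min(h, w)
    r_out = r + rim_frac * min(h, w)
    if 2 * r_out > min(h, w):
        raise ValueError(
            f"well of radius {r:.1f}+rim {r_out - r:.1f} does not fit in {h}x{w}"
        )
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if shape == "disc":
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        well = d2 <= r**2
        rim = (d2 > r**2) & (d2 <= r_out**2)
    elif shape == "square":
        d = np.maximum(np.abs(yy - cy), np.abs(xx - cx))
        well = d <= r
        rim = (d > r) & (d <= r_out)
    else:
        raise ValueError(f"well shape must be 'disc' or 'square', got {shape!r}")
    return well, rim


def render_well_image(
    rgb: tuple[int, int, int],
    condition: CaptureCondition,
    size: tuple[int, int] = (400, 400),
    seed: int = 0,
    *,
    well_shape: str = "disc",
    well_radius_frac: float = 0.28,
    rim_width_frac: float = 0.05,
    noise_sigma: float | None = None,
) -> RawImage:
    """Render one well capture: colored well, dark rim, white film background.

    The scene (well color, rim, film) is scaled per channel by the
    condition's combined gains, then seeded Gaussian noise of scale
    ``noise_sigma`` (default: the camera profile's) is added, and the result
    is rounded and clamped to [0, 255].  Identical arguments and seed give a
    bit-identical image.
    """
    h, w = size
    if h > condition.camera.sensor_resolution[0] or w > condition.camera.sensor_resolution[1]:
        raise ValueError("requested size exceeds the camera's sensor resolution")
    well, rim = _well_masks(size, well_shape, well_radius_frac, rim_width_frac)

    scene = np.empty((h, w, 3), dtype=float)
    scene[:] = FILM_RGB
    scene[rim] = RIM_RGB
    scene[well] = rgb
    scene *= condition.channel_gains

    sigma = condition.camera.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        scene = scene + rng.normal(0.0, sigma, scene.shape)
    pixels = np.clip(_round_half_away(scene), 0, 255).astype(np.uint8)
    return RawImage(pixels=pixels, condition=condition)


@dataclass
class GeneratorConfig:
    """Factorial design of a synthetic capture campaign.

    Defaults reproduce the full campaign: 16 concentrations x 2 lightings x
    3 locations x 3 cameras x 5 replicates = 1440 images at 400x400.
    ``noise_sigma``, if set, overrides every camera's sensor noise (e.g. 0
    for noise-free renders).
    """

    concentrations: Sequence[int] = CONCENTRATIONS
    lightings: Sequence[str] = ("natural", "artificial")
    locations: Sequence[int] = (1, 2, 3)
    cameras: Sequence[CameraProfile] = DEFAULT_CAMERAS
    replicates: int = 5
    image_size: tuple[int, int] = (400, 400)
    well_shape: str = "disc"
    master_seed: int = 0
    color_model: AssayColorModel = field(default_factory=AssayColorModel)
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        for name in ("concentrations", "lightings", "locations", "cameras"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor {name!r} must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def image_count(self) -> int:
        return (
            len(self.concentrations)
            * len(self.lightings)
            * len(self.locations)
            * len(self.cameras)
            * self.replicates
        )


def _derive_seed(
    master_seed: int, c_idx: int, l_idx: int, loc: int, cam_idx: int, rep: int
) -> int:
    """Deterministic per-image seed from the master seed and factorial cell."""
    ss = np.random.SeedSequence((master_seed, c_idx, l_idx, loc, cam_idx, rep))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the full factorial image set and return its manifest.

    Creates one PNG per factorial cell under ``out_dir/<concentration>/``,
    plus ``manifest.csv`` with columns path, concentration, lighting,
    location, camera, replicate, seed.  Regenerating with the same config
    yields byte-identical images and manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    for c_idx, value in enumerate(config.concentrations):
        label = ConcentrationClass(int(value))
        class_dir = out_dir / str(label.value)
        class_dir.mkdir(exist_ok=True)
        rgb = concentration_to_rgb(label, config.color_model)
        for l_idx, lighting in enumerate(config.lightings):
            for loc in config.locations:
                for cam_idx, camera in enumerate(config.cameras):
                    condition = CaptureCondition(lighting, int(loc), camera, 1)
                    for rep in range(1, config.replicates + 1):
                        condition = dataclasses.replace(condition, replicate=rep)
                        seed = _derive_seed(
                            config.master_seed, c_idx, l_idx, int(loc), cam_idx, rep
                        )
                        img = render_well_image(
                            rgb,
                            condition,
                            size=config.image_size,
                            seed=seed,
                            well_shape=config.well_shape,
                            noise_sigma=config.noise_sigma,
                        )
                        fname = f"{lighting}_loc{loc}_{camera.name}_r{rep}.png"
                        path = class_dir / fname
                        Image.fromarray(img.pixels, mode="RGB").save(path)
                        records.append(
                            {
                                "path": str(path.relative_to(out_dir)),
                                "concentration": label.value,
                                "lighting": lighting,
                                "location": int(loc),
                                "camera": camera.name,
                                "replicate": rep,
                                "seed": seed,
                            }
                        )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
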