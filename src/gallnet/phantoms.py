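"""Synthetic gallbladder-ultrasound phantom generator.

Produces deterministic 128x128 grayscale phantoms for the nine disease
classes so the full pipeline (loading, training, evaluation, explanation)
is exercisable without any clinical data.  Each phantom is an anatomy
layer — mid-gray tissue, a dark anechoic lumen, an echogenic wall, and a
class-specific motif — multiplied by a speckle field with the
exponential-like intensity statistics of a low-pass-filtered squared
Gaussian process (the standard first-order approximation of fully
developed ultrasound speckle).

Class motifs follow the sonographic signatures of the conditions:

* gallstones — bright intraluminal foci with vertical acoustic shadows;
* abdomen and retroperitoneum — a lumen-free organ field with layered
  fascia-like bands;
* cholecystitis — moderately thickened bright wall with a dark
  pericholecystic rim;
* membranous and gangrenous cholecystitis — irregular wall with thin
  intraluminal membrane strands;
* perforation — a contiguous angular gap in the wall with an adjacent
  fluid collection;
* polyps and cholesterol crystals — small wall-attached echogenic blobs
  without shadowing;
* adenomyomatosis — markedly thickened wall containing small anechoic
  intramural pockets with bright comet-tail streaks;
* carcinoma — a heterogeneous irregular-margin mass filling much of the
  lumen;
* gallbladder wall thickening — an extreme, radially striated wall.

The geometric parameters (lumen axes, wall thickness, focus counts and
radii) are drawn per image from the ranges in each
:class:`PhantomClassSpec`, so phantoms vary within a class while the
class signature stays fixed.  ``(class, seed)`` fully determines an
image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import CLASS_NAMES
from .data_io import ImageRecord

__all__ = [
    "PhantomClassSpec",
    "PhantomConfig",
    "PHANTOM_CLASSES",
    "speckle_field",
    "generate_phantom",
    "generate_dataset",
]


@dataclass(frozen=True)
class PhantomClassSpec:
    """Structural parameters for one synthetic appearance class."""

    name: str
    has_lumen: bool = True
    lumen_axes: tuple[float, float, float, float] = (0.22, 0.30, 0.14, 0.20)
    #: wall thickness range as a fraction of the image extent
    wall_thickness: tuple[float, float] = (0.020, 0.032)
    #: (count range, radius range (fraction), brightness, shadow opacity)
    stones: tuple[tuple[int, int], tuple[float, float], float, float] | None = None
    #: (count range, radius range (fraction))
    polyps: tuple[tuple[int, int], tuple[float, float]] | None = None
    texture_heterogeneity: float = 0.05
    perforation_gap: bool = False
    membranes: bool = False
    mass: bool = False
    intramural_pockets: bool = False
    wall_striation: bool = False
    pericholecystic_rim: bool = False


PHANTOM_CLASSES: dict[str, PhantomClassSpec] = {spec.name: spec for spec in (
    PhantomClassSpec(
        "gallstones",
        stones=((2, 3), (0.036, 0.056), 0.95, 0.8)),
    PhantomClassSpec(
        "abdomen_and_retroperitoneum",
        has_lumen=False, texture_heterogeneity=0.10),
    PhantomClassSpec(
        "cholecystitis",
        wall_thickness=(0.048, 0.062), pericholecystic_rim=True),
    PhantomClassSpec(
        "membranous_and_gangrenous_cholecystitis",
        wall_thickness=(0.035, 0.055), membranes=True,
        texture_heterogeneity=0.08),
    PhantomClassSpec(
        "perforation",
        wall_thickness=(0.025, 0.040), perforation_gap=True),
    PhantomClassSpec(
        "polyps_and_cholesterol_crystals",
        polyps=((3, 5), (0.022, 0.036))),
    PhantomClassSpec(
        "adenomyomatosis",
        wall_thickness=(0.060, 0.085), intramural_pockets=True),
    PhantomClassSpec(
        "carcinoma",
        wall_thickness=(0.028, 0.045), mass=True,
        texture_heterogeneity=0.08),
    PhantomClassSpec(
        "gallbladder_wall_thickening",
        wall_thickness=(0.105, 0.135), wall_striation=True),
)}


@dataclass(frozen=True)
class PhantomConfig:
    """Global phantom parameters."""

    extent: int = 128
    speckle_sigma: float = 1.1      # grain size of the speckle, in pixels
    speckle_strength: float = 0.25  # multiplicative modulation depth
    background_mean: float = 0.45
    master_seed: int = 0
    #: probability of adding a distractor stone-like focus to classes that
    #: are clinically confusable with gallstones (off by default)
    confusability: float = 0.0

    def __post_init__(self):
        if self.extent <= 0 or self.extent % 64 != 0:
            raise ValueError("extent must be a positive multiple of 64")


def speckle_field(extent: int, sigma: float = 1.1, strength: float = 0.25,
                  seed: int = 0) -> np.ndarray:
    """Positive multiplicative speckle grid with mean 1.

    A Gaussian white field is low-pass filtered and squared, giving the
    exponential-like single-point intensity statistics of fully developed
    speckle; the result is normalized to unit mean and blended toward 1
    by ``strength``.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    g = gaussian_filter(rng.standard_normal((extent, extent)), sigma)
    s = g ** 2
    s /= s.mean()
    out = 1.0 + strength * (s - 1.0)
    return np.maximum(out, 1e-3)


def _smooth_noise(rng: np.random.Generator, extent: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((extent, extent)), sigma)
    return f / (np.abs(f).max() + 1e-12)


def _angular_profile(rng: np.random.Generator, theta: np.ndarray,
                     depth: float, harmonics: int = 4) -> np.ndarray:
    """1 + depth * random low-order Fourier modulation of an angle field."""
    out = np.ones_like(theta)
    for k in range(1, harmonics + 1):
        amp = rng.uniform(0, depth / harmonics)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(k * theta + phase)
    return out


class _Scene:
    """Working state for one phantom: anatomy layer + attenuation mask."""

    def __init__(self, extent: int, rng: np.random.Generator,
                 config: PhantomConfig, spec: PhantomClassSpec):
        self.e = extent
        self.rng = rng
        self.config = config
        self.spec = spec
        yy, xx = np.mgrid[0:extent, 0:extent]
        self.yy = yy
        self.xx = xx
        base = config.background_mean * np.ones((extent, extent))
        base += 0.5 * spec.texture_heterogeneity * _smooth_noise(rng, extent, 6.0)
        base += 0.3 * spec.texture_heterogeneity * _smooth_noise(rng, extent, 2.5)
        self.img = base
        self.atten = np.ones((extent, extent))
        # geometry introspection for tests / ROI statistics
        self.stones: list[tuple[float, float, float]] = []
        self.geo: dict | None = None


def _disk(scene: _Scene, cy: float, cx: float, r: float) -> np.ndarray:
    return (scene.yy - cy) ** 2 + (scene.xx - cx) ** 2 < r ** 2


def _add_stone(scene: _Scene, cy: float, cx: float, r: float,
               brightness: float, shadow_opacity: float) -> None:
    mask = _disk(scene, cy, cx, r)
    scene.img[mask] = brightness
    shadow = (np.abs(scene.xx - cx) < 0.9 * r) & (scene.yy > cy + 0.4 * r)
    scene.atten[shadow] *= (1.0 - shadow_opacity)
    scene.stones.append((cy, cx, r))


def _paint_abdomen(scene: _Scene) -> None:
    """Organ field without a lumen: layered echotexture and fascia lines."""
    e, rng = scene.e, scene.rng
    n_bands = rng.integers(3, 6)
    for _ in range(n_bands):
        y0 = rng.uniform(0.1, 0.9) * e
        width = rng.uniform(0.02, 0.05) * e
        gain = rng.uniform(0.15, 0.30)
        scene.img += gain * np.exp(-0.5 * ((scene.yy - y0) / width) ** 2)
    # one bright curved interface (diaphragm / fascia)
    y0 = rng.uniform(0.25, 0.6) * e
    curve = y0 + 0.08 * e * np.sin(np.pi * scene.xx / e + rng.uniform(0, np.pi))
    scene.img += 0.35 * np.exp(-0.5 * ((scene.yy - curve) / (0.012 * e)) ** 2)


def _paint_gallbladder(scene: _Scene) -> dict:
    """Lumen + wall; returns the geometry handles the motifs need."""
    e, rng, spec = scene.e, scene.rng, scene.spec
    cy = e * rng.uniform(0.46, 0.54)
    cx = e * rng.uniform(0.46, 0.54)
    a_lo, a_hi, b_lo, b_hi = spec.lumen_axes
    a = e * rng.uniform(a_lo, a_hi)   # horizontal semi-axis
    b = e * rng.uniform(b_lo, b_hi)   # vertical semi-axis
    rot = rng.uniform(-0.2, 0.2)
    cos_r, sin_r = np.cos(rot), np.sin(rot)
    xr = (scene.xx - cx) * cos_r + (scene.yy - cy) * sin_r
    yr = -(scene.xx - cx) * sin_r + (scene.yy - cy) * cos_r
    r = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    theta = np.arctan2(yr / b, xr / a)

    tw = rng.uniform(*spec.wall_thickness) * e
    tw_r = tw / min(a, b)  # thickness in normalized-radius units
    wall_profile = _angular_profile(rng, theta,
                                    0.35 if spec.membranes else 0.12)
    outer = 1.0 + tw_r * wall_profile

    lumen = r < 1.0
    wall = (r >= 1.0) & (r < outer)
    scene.img[lumen] = rng.uniform(0.04, 0.09)
    wall_level = rng.uniform(0.85, 0.95) if spec.pericholecystic_rim \
        else rng.uniform(0.72, 0.82)
    scene.img[wall] = wall_level
    if spec.wall_striation:
        # layered wall: bright-dark-bright radial banding
        frac = np.zeros_like(r)
        frac[wall] = (r[wall] - 1.0) / (outer[wall] - 1.0)
        band = 0.45 * np.cos(2 * np.pi * frac * 2.0)
        scene.img[wall] = np.clip(wall_level - 0.18 + band[wall] * 0.5, 0.2, 0.95)
    if spec.pericholecystic_rim:
        rim = (r >= outer) & (r < outer + 0.45 * tw_r)
        scene.img[rim] = rng.uniform(0.16, 0.24)
    return {"cy": cy, "cx": cx, "a": a, "b": b, "r": r, "theta": theta,
            "outer": outer, "lumen": lumen, "wall": wall, "tw": tw,
            "tw_r": tw_r, "rot": rot, "wall_level": wall_level}


def _apply_motif(scene: _Scene, geo: dict | None) -> None:
    e, rng, spec = scene.e, scene.rng, scene.spec
    if spec.stones is not None:
        (n_lo, n_hi), (r_lo, r_hi), bright, opacity = spec.stones
        n_stones = rng.integers(n_lo, n_hi + 1)
        for _ in range(n_stones):
            sr = rng.uniform(r_lo, r_hi) * e
            # dependent (gravity) position: lower part of the lumen
            sx = geo["cx"] + rng.uniform(-0.45, 0.45) * geo["a"]
            sy = geo["cy"] + rng.uniform(0.25, 0.55) * geo["b"]
            _add_stone(scene, sy, sx, sr, bright, opacity)
    if spec.polyps is not None:
        (n_lo, n_hi), (r_lo, r_hi) = spec.polyps
        n_polyps = rng.integers(n_lo, n_hi + 1)
        for _ in range(n_polyps):
            pr = rng.uniform(r_lo, r_hi) * e
            ang = rng.uniform(0, 2 * np.pi)
            # attach to the inner wall, protruding well into the dark
            # lumen so the blob contrasts against it
            px = geo["cx"] + 0.80 * geo["a"] * np.cos(ang) * np.cos(geo["rot"]) \
                - 0.80 * geo["b"] * np.sin(ang) * np.sin(geo["rot"])
            py = geo["cy"] + 0.80 * geo["a"] * np.cos(ang) * np.sin(geo["rot"]) \
                + 0.80 * geo["b"] * np.sin(ang) * np.cos(geo["rot"])
            scene.img[_disk(scene, py, px, pr)] = rng.uniform(0.8, 0.92)
    if spec.perforation_gap:
        gap_width = rng.uniform(np.deg2rad(60), np.deg2rad(100))
        gap_center = rng.uniform(-np.pi, np.pi)
        dist = np.angle(np.exp(1j * (geo["theta"] - gap_center)))
        gap = geo["wall"] & (np.abs(dist) < gap_width / 2)
        scene.img[gap] = scene.config.background_mean  # wall breach
        # extraluminal fluid collection just outside the gap
        fx = geo["cx"] + 1.25 * geo["a"] * np.cos(gap_center)
        fy = geo["cy"] + 1.25 * geo["b"] * np.sin(gap_center)
        scene.img[_disk(scene, fy, fx, rng.uniform(0.08, 0.12) * e)] = \
            rng.uniform(0.05, 0.10)
    if spec.membranes:
        n_strands = rng.integers(2, 4)
        for _ in range(n_strands):
            t = np.linspace(-0.85, 0.85, 4 * e)
            amp = rng.uniform(0.15, 0.45)
            phase = rng.uniform(0, 2 * np.pi)
            mx = geo["cx"] + t * geo["a"]
            my = geo["cy"] + amp * geo["b"] * np.sin(2.5 * t + phase)
            ix = np.clip(np.round(mx).astype(int), 0, e - 1)
            iy = np.clip(np.round(my).astype(int), 0, e - 1)
            inside = geo["r"][iy, ix] < 0.95
            scene.img[iy[inside], ix[inside]] = 0.7
            scene.img[np.clip(iy[inside] + 1, 0, e - 1), ix[inside]] = 0.6
    if spec.mass:
        mcx = geo["cx"] + rng.uniform(-0.25, 0.25) * geo["a"]
        mcy = geo["cy"] + rng.uniform(-0.25, 0.25) * geo["b"]
        mr = rng.uniform(0.55, 0.8) * min(geo["a"], geo["b"])
        ang = np.arctan2(scene.yy - mcy, scene.xx - mcx)
        radius = mr * _angular_profile(rng, ang, 0.5)
        mass_mask = ((scene.yy - mcy) ** 2 + (scene.xx - mcx) ** 2
                     < radius ** 2) & (geo["r"] < 1.05)
        texture = 0.5 + 0.15 * _smooth_noise(rng, e, 2.0)
        scene.img[mass_mask] = texture[mass_mask]
    if spec.intramural_pockets:
        n_pockets = rng.integers(4, 7)
        for _ in range(n_pockets):
            ang = rng.uniform(0, 2 * np.pi)
            rad = 1.0 + 0.5 * geo["tw_r"]
            px = geo["cx"] + rad * geo["a"] * np.cos(ang) * np.cos(geo["rot"]) \
                - rad * geo["b"] * np.sin(ang) * np.sin(geo["rot"])
            py = geo["cy"] + rad * geo["a"] * np.cos(ang) * np.sin(geo["rot"]) \
                + rad * geo["b"] * np.sin(ang) * np.cos(geo["rot"])
            pr = rng.uniform(0.35, 0.6) * geo["tw"]
            scene.img[_disk(scene, py, px, pr)] = rng.uniform(0.05, 0.12)
            # comet-tail reverberation: short bright streak below the pocket
            tail = (np.abs(scene.xx - px) < 1.2) & \
                (scene.yy > py) & (scene.yy < py + 0.1 * e)
            scene.img[tail] = np.maximum(scene.img[tail], 0.8)
    if scene.config.confusability > 0 and spec.name in (
            "abdomen_and_retroperitoneum", "perforation", "adenomyomatosis"):
        if rng.random() < scene.config.confusability:
            sx = rng.uniform(0.3, 0.7) * e
            sy = rng.uniform(0.35, 0.65) * e
            _add_stone(scene, sy, sx, rng.uniform(0.025, 0.045) * e, 0.9, 0.6)


def generate_phantom(class_name: str, seed: int,
                     config: PhantomConfig | None = None,
                     with_scene: bool = False):
    """Render one phantom; ``(class_name, seed)`` fully determines the
    pixels for a given config.

    With ``with_scene=True`` also returns the internal :class:`_Scene`
    (pre-speckle anatomy, attenuation mask, stone and lumen geometry) for
    region-of-interest statistics."""
    if config is None:
        config = PhantomConfig()
    if class_name not in PHANTOM_CLASSES:
        raise KeyError(f"unknown phantom class {class_name!r}; "
                       f"registered: {sorted(PHANTOM_CLASSES)}")
    spec = PHANTOM_CLASSES[class_name]
    class_index = CLASS_NAMES.index(class_name)
    rng = np.random.default_rng(np.random.SeedSequence([seed, class_index]))
    scene = _Scene(config.extent, rng, config, spec)
    if spec.has_lumen:
        geo = _paint_gallbladder(scene)
    else:
        _paint_abdomen(scene)
        geo = None
    scene.geo = geo
    _apply_motif(scene, geo)
    speckle_seed = int(rng.integers(0, 2 ** 31))
    speckle = speckle_field(config.extent, config.speckle_sigma,
                            config.speckle_strength, speckle_seed)
    img = scene.img * scene.atten * speckle
    record = ImageRecord(path=None, label=class_name,
                         pixels=np.clip(img, 0.0, 1.0).astype(np.float32))
    return (record, scene) if with_scene else record


def generate_dataset(n_per_class: int, master_seed: int,
                     out_dir: str | Path,
                     config: PhantomConfig | None = None) -> Path:
    """Write ``n_per_class`` phantoms per class as 8-bit PNGs in a
    class-per-subdirectory layout plus a ``manifest.csv``; fully
    deterministic (byte-identical files) per master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    rows = []
    for ci, name in enumerate(CLASS_NAMES):
        class_dir = out_dir / name
        class_dir.mkdir(exist_ok=True)
        for j in range(n_per_class):
            seed = int(np.random.SeedSequence(
                [master_seed, ci, j]).generate_state(1)[0] % (2 ** 31))
            rec = generate_phantom(name, seed, config)
            arr = np.round(rec.pixels * 255.0).astype(np.uint8)
            path = class_dir / f"{name}_{j:04d}.png"
            Image.fromarray(arr, mode="L").save(path)
            rows.append({"class": name, "file": str(path.relative_to(out_dir)),
                         "seed": seed})
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["class", "file", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return out_dir


def phantom_records(n_per_class: int, master_seed: int,
                    config: PhantomConfig | None = None) -> list[ImageRecord]:
    """In-memory equivalent of :func:`generate_dataset` (no files written);
    used by tests and quick experiments.  Records get synthetic paths so
    they can participate in path-based splitting."""
    records = []
    for ci, name in enumerate(CLASS_NAMES):
        for j in range(n_per_class):
            seed = int(np.random.SeedSequence(
                [master_seed, ci, j]).generate_state(1)[0] % (2 ** 31))
            rec = generate_phantom(name, seed, config)
            rec.path = Path(f"synthetic://{name}/{j:04d}")
            records.append(rec)
    return records
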