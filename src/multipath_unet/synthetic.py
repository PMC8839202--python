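"""Synthetic plate and cell scenes with exact ground truth.

The generator emulates the phenomenology of agar-plate photographs — a
circular plate on a dark surround, low-frequency background texture,
disk-like colonies of varying radius and contrast with a smooth intensity
falloff, and non-colony artifacts (text-like glyph strokes, a specular
highlight) that appear in the image but never in the mask — plus irregular
elongated cell-like shapes for the cell-scene variant.  Every scene carries
an exact binary mask and a known object count, so segmentation and counting
can be validated without any external data.  The generator makes no claim of
matching the statistics of real laboratory plates; it is a controlled test
stand with known ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.special import expit


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``intensity_contrast`` is the peak colony intensity offset relative to
    the background (positive fraction of the dynamic range);
    ``background_texture_scale`` the amplitude of the smooth background
    texture.  ``dark_objects`` renders colonies darker than the background
    instead of lighter.
    """

    height: int = 128
    width: int = 128
    n_colonies: int = 8
    radius_range: tuple[float, float] = (4.0, 10.0)
    intensity_contrast: float = 0.6
    background_texture_scale: float = 0.05
    text_glyphs: bool = False
    specular_highlight: bool = False
    dark_objects: bool = False
    allow_overlap: bool = False
    channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16x16")
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be nonnegative")
        rmin, rmax = self.radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("invalid radius_range")
        if rmax * 2 >= min(self.height, self.width):
            raise ValueError("colonies do not fit within the image bounds")
        if not 0.0 < self.intensity_contrast <= 1.0:
            raise ValueError("intensity_contrast must be in (0,1]")
        if self.background_texture_scale < 0:
            raise ValueError("background_texture_scale must be nonnegative")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene: 8-bit image, binary mask, and exact ground truth."""

    image: np.ndarray          # uint8, (H,W) or (H,W,3)
    mask: np.ndarray           # uint8 {0,1}, (H,W)
    true_count: int
    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]


class PlacementError(RuntimeError):
    """Raised when disjoint object placement fails (scene too crowded)."""


def _place_objects(spec: SceneSpec, rng: np.random.Generator,
                   margin_scale: float = 1.0):
    """Rejection-sample object centers/radii inside the plate region."""
    h, w = spec.height, spec.width
    cy, cx = h / 2.0, w / 2.0
    plate_r = 0.48 * min(h, w)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 300 * max(spec.n_colonies, 1)
    while len(centers) < spec.n_colonies:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_colonies} disjoint objects after "
                f"{max_attempts} attempts")
        attempts += 1
        r = rng.uniform(*spec.radius_range) * margin_scale
        ang = rng.uniform(0, 2 * np.pi)
        rad = (plate_r - r - 2) * np.sqrt(rng.uniform())
        y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        if not spec.allow_overlap:
            ok = all(np.hypot(y - yc, x - xc) > r + rc + 2.0
                     for (yc, xc), rc in zip(centers, radii))
            if not ok:
                continue
        centers.append((y, x))
        radii.append(r)
    return centers, radii


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    plate_r = 0.48 * min(h, w)
    dist = np.hypot(yy - h / 2.0, xx - w / 2.0)
    plate = expit(-(dist - plate_r) / 1.5)  # soft plate edge
    bg = 0.15 + 0.40 * plate
    if spec.background_texture_scale > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                        sigma=min(h, w) / 16.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        bg = bg + spec.background_texture_scale * noise * plate
    return bg


def _stamp_artifacts(img: np.ndarray, spec: SceneSpec,
                     rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.text_glyphs:
        # a few thin dark strokes, like marker notes on the dish
        for _ in range(rng.integers(2, 5)):
            y0 = rng.uniform(0.2 * h, 0.8 * h)
            x0 = rng.uniform(0.2 * w, 0.8 * w)
            ang = rng.uniform(0, np.pi)
            length = rng.uniform(0.05, 0.15) * min(h, w)
            ts = np.linspace(-length / 2, length / 2, int(2 * length) + 2)
            ys = np.clip(y0 + ts * np.sin(ang), 0, h - 1).astype(int)
            xs = np.clip(x0 + ts * np.cos(ang), 0, w - 1).astype(int)
            stroke = np.zeros((h, w))
            stroke[ys, xs] = 1.0
            stroke = ndimage.gaussian_filter(stroke, sigma=0.7)
            img = img - 0.35 * stroke / max(stroke.max(), 1e-12)
    if spec.specular_highlight:
        yy, xx = np.mgrid[0:h, 0:w]
        yc = rng.uniform(0.25 * h, 0.75 * h)
        xc = rng.uniform(0.25 * w, 0.75 * w)
        sig = 0.12 * min(h, w)
        img = img + 0.30 * np.exp(-((yy - yc) ** 2 + (xx - xc) ** 2)
                                  / (2 * sig ** 2))
    return img


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent per-stage generators (placement, shapes, background,
    artifacts) so toggling artifact flags never perturbs the other stages."""
    return tuple(np.random.default_rng(s)
                 for s in np.random.SeedSequence(seed).spawn(4))


def _render(spec: SceneSpec, centers, radii, elong=None) -> SyntheticScene:
    h, w = spec.height, spec.width
    _, _, bg_rng, art_rng = _streams(spec.seed)
    img = _background(spec, bg_rng)
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    sign = -1.0 if spec.dark_objects else 1.0
    for i, ((yc, xc), r) in enumerate(zip(centers, radii)):
        if elong is None:
            dist = np.hypot(yy - yc, xx - xc) / r
        else:
            a, b, ang, wob, phase = elong[i]
            dy, dx = yy - yc, xx - xc
            u = dx * np.cos(ang) + dy * np.sin(ang)
            v = -dx * np.sin(ang) + dy * np.cos(ang)
            theta = np.arctan2(v / b, u / a)
            wobble = 1.0 + wob * np.sin(3 * theta + phase)
            dist = np.hypot(u / a, v / b) / wobble
        mask[dist <= 1.0] = 1
        # smooth radial falloff: flat core, soft shoulder at the rim
        profile = expit(-(dist - 0.85) * 8.0)
        img = img + sign * spec.intensity_contrast * 0.5 * profile
    img = _stamp_artifacts(img, spec, art_rng)
    img = np.clip(img, 0.0, 1.0)
    img8 = np.round(img * 255.0).astype(np.uint8)
    if spec.channels == 3:
        tint = np.array([1.0, 0.95, 0.85])
        img8 = np.clip(np.round(img[..., None] * tint * 255.0), 0,
                       255).astype(np.uint8)
    return SyntheticScene(image=img8, mask=mask,
                          true_count=len(centers),
                          centers=tuple((float(y), float(x))
                                        for y, x in centers),
                          radii=tuple(float(r) for r in radii))


def generate_cfu_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a plate scene with disk-shaped colonies.

    Deterministic under ``spec.seed``; when ``allow_overlap`` is false the
    colonies are pairwise disjoint so the mask's 8-connected component count
    equals ``n_colonies`` exactly.
    """
    place_rng = _streams(spec.seed)[0]
    centers, radii = _place_objects(spec, place_rng)
    return _render(spec, centers, radii)


def generate_cell_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene of irregular, elongated cell-like shapes.

    Shapes are rotated ellipses with a low-order angular wobble of the
    radius, emulating bent or irregular cells; ground-truth guarantees are
    the same as for plate scenes.
    """
    place_rng, shape_rng = _streams(spec.seed)[:2]
    # the wobbled ellipse stays within its nominal radius r (a = r/1.3 and
    # the wobble factor tops out at 1.2), so disjoint placement still holds
    centers, radii = _place_objects(spec, place_rng)
    elong = []
    for r in radii:
        aspect = shape_rng.uniform(1.5, 3.0)
        a = r / 1.3
        b = a / aspect
        elong.append((a * 1.0, b, shape_rng.uniform(0, np.pi),
                      shape_rng.uniform(0.05, 0.2),
                      shape_rng.uniform(0, 2 * np.pi)))
    return _render(spec, centers, radii, elong=elong)


def generate_dataset(n_images: int, template: SceneSpec, seed: int,
                     out_dir=None, kind: str = "cfu",
                     count_range: tuple[int, int] | None = None):
    """Generate a set of scenes with per-image derived seeds.

    Returns the list of scenes; when ``out_dir`` is given, also writes
    ``images/*.png``, ``masks/*.png`` and a ``counts.csv`` manifest in a
    layout the preprocessing loader understands.
    """
    if n_images < 1:
        raise ValueError("n_images must be positive")
    make = {"cfu": generate_cfu_scene, "cell": generate_cell_scene}[kind]
    children = np.random.SeedSequence(seed).spawn(n_images)
    scenes = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = replace(template, seed=child_seed)
        if count_range is not None:
            n_rng = np.random.default_rng(child_seed + 1)
            spec = replace(spec, n_colonies=int(
                n_rng.integers(count_range[0], count_range[1] + 1)))
        scenes.append(make(spec))
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        with open(out / "counts.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "true_count"])
            for i, scene in enumerate(scenes):
                stem = f"scene_{i:04d}"
                iio.imwrite(out / "images" / f"{stem}.png", scene.image)
                iio.imwrite(out / "masks" / f"{stem}.png",
                            (scene.mask * 255).astype(np.uint8))
                writer.writerow([stem, scene.true_count])
    return scenes
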