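"""Image loading and input normalization.

Inputs are rescaled to a fixed square size (512 by default) with Gaussian
anti-aliasing when shrinking, then standardized to per-image z-scores using
one mean and standard deviation over all pixels and channels.  Masks are
resized with nearest-neighbor interpolation so they stay strictly binary.
All steps are deterministic.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

#: guard against zero division for constant images
ZSCORE_EPS = 1e-8


def load_pair(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load an image/mask pair from PNG or TIFF files.

    Returns the image as an integer array (H,W) or (H,W,3) — 8-bit per
    channel, or 16-bit single channel — and the mask binarized to {0,1}
    (any nonzero label counts as foreground).  Raises on missing files,
    unsupported bit depth or channel count, and dimension mismatch.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(p)
    image = np.asarray(iio.imread(image_path))
    mask = np.asarray(iio.imread(mask_path))
    if image.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth {image.dtype} for {image_path}")
    if image.ndim == 3 and image.shape[2] == 4:  # tolerate opaque RGBA PNGs
        image = image[..., :3]
    if image.ndim not in (2, 3) or (image.ndim == 3 and image.shape[2] != 3):
        raise ValueError(f"unsupported channel layout {image.shape}")
    if image.ndim == 3 and image.dtype == np.uint16:
        raise ValueError("16-bit input must be single-channel")
    if mask.ndim == 3:
        mask = mask[..., 0]
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask {mask.shape} does not match image "
                         f"{image.shape[:2]}")
    return image, (mask != 0).astype(np.uint8)


def resize_with_gaussian_smoothing(image: np.ndarray,
                                   target: int = 512) -> np.ndarray:
    """Rescale to target x target with Gaussian anti-aliasing when shrinking.

    The blur sigma is s/3 per axis, where s is that axis' shrink factor;
    upscaled axes get no blur.  Channels are resized identically; bilinear
    interpolation.  Non-square inputs are resized anisotropically.
    """
    if target < 8:
        raise ValueError("target must be >= 8")
    img = np.asarray(image, dtype=float)
    if img.ndim not in (2, 3) or (img.ndim == 3 and img.shape[2] not in (1, 3)):
        raise ValueError(f"unsupported channel layout {img.shape}")
    h, w = img.shape[:2]
    sigmas = [max(h / target, 1.0) / 3.0 if h > target else 0.0,
              max(w / target, 1.0) / 3.0 if w > target else 0.0]
    out_shape = (target, target) + img.shape[2:]
    if img.ndim == 3:
        sigmas.append(0.0)
    anti_alias = any(s > 0 for s in sigmas)
    return _sk_resize(img, out_shape, order=1, mode="reflect",
                      anti_aliasing=anti_alias,
                      anti_aliasing_sigma=sigmas if anti_alias else None,
                      preserve_range=True)


def resize_mask(mask: np.ndarray, target: int = 512) -> np.ndarray:
    """Nearest-neighbor mask resize; preserves binarity exactly."""
    m = np.asarray(mask)
    out = _sk_resize(m.astype(float), (target, target), order=0,
                     anti_aliasing=False, preserve_range=True)
    return out.astype(m.dtype)


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Per-image z-scores with one mean/std over all pixels and channels.

    Uses the population standard deviation; a constant image maps to zeros
    through the epsilon guard.  Output layout is (channel, row, column).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    z = (img - img.mean()) / (img.std() + ZSCORE_EPS)
    if z.ndim == 2:
        return z[None]
    return np.moveaxis(z, -1, 0)


def prepare_image(image: np.ndarray, target: int = 512) -> np.ndarray:
    """Full input pipeline: smoothed rescale followed by z-scoring."""
    return zscore_normalize(resize_with_gaussian_smoothing(image, target))


def load_dataset(data_dir, target: int | None = None):
    """Load an images/ + masks/ directory pair (matching stems).

    Returns ``(X, Y, ids)`` where X is (N,C,H,W) z-scored float64, Y is
    (N,H,W) uint8, and ids the sorted file stems.  When ``target`` is given,
    images and masks are resized to target x target first.
    """
    data_dir = Path(data_dir)
    image_files = sorted((data_dir / "images").iterdir())
    xs, ys, ids = [], [], []
    for img_path in image_files:
        mask_path = data_dir / "masks" / img_path.name
        if not mask_path.exists():
            candidates = list((data_dir / "masks").glob(img_path.stem + ".*"))
            if not candidates:
                raise FileNotFoundError(f"no mask for {img_path.name}")
            mask_path = candidates[0]
        image, mask = load_pair(img_path, mask_path)
        if target is not None:
            image = resize_with_gaussian_smoothing(image, target)
            mask = resize_mask(mask, target)
        xs.append(zscore_normalize(image))
        ys.append(mask)
        ids.append(img_path.stem)
    return np.stack(xs), np.stack(ys), ids
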