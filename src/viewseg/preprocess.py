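"""Resizing, normalisation and geometric augmentation.

Geometric transforms act in a centre-origin coordinate frame with ``x``
pointing right and ``y`` pointing up; a transform maps input coordinates to
output coordinates as ``x' = A x + t`` and the image is resampled with the
inverse map (bilinear for images, constant zero fill outside the frame).

By default the random transforms are applied only in the view-classifier
training stream; segmentation training uses resize + normalise alone, with
geometric augmentation available behind ``enabled_for``.  When enabled for
segmentation, image and mask must be warped with the identical transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "AugmentConfig",
    "resize",
    "apply_affine",
    "rotate",
    "random_rotation",
    "random_affine",
    "normalize",
    "denormalize",
    "classifier_augment",
]


@dataclass
class AugmentConfig:
    """Augmentation and normalisation settings.

    Angles in degrees, translations as fractions of the image size,
    scales as multiplicative factors.
    """

    theta_max: float = 10.0
    affine_degrees: float = 5.0
    affine_translate: tuple[float, float] = (0.05, 0.05)
    affine_scale: tuple[float, float] = (0.95, 1.05)
    affine_shear: float = 5.0
    target_size: int = 512
    enabled_for: tuple[str, ...] = ("classifier",)
    mean: float = 0.5
    std: float = 0.5

    def __post_init__(self) -> None:
        if self.theta_max < 0:
            raise ValueError("theta_max must be non-negative")
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")


def resize(image, mask=None, target_size: int = 512):
    """Resize to ``target_size`` square: bilinear for the image,
    nearest-neighbour for the mask (so it stays binary)."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    shape = (target_size, target_size) + img.shape[2:]
    out = _sk_resize(img, shape, order=1, preserve_range=True,
                     anti_aliasing=img.shape[0] > target_size).astype(np.float32)
    if mask is None:
        return out
    m = np.asarray(mask)
    mout = _sk_resize(m.astype(np.float64), (target_size, target_size),
                      order=0, preserve_range=True, anti_aliasing=False)
    return out, (mout > 0.5).astype(np.uint8)


def _xy_to_rc(H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset of the map from (row, col) to centre-origin (x, y-up)."""
    M = np.array([[0.0, 1.0], [-1.0, 0.0]])  # x = col - cc ; y = rc - row
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    t = np.array([-cc, cr])
    return M, t


def apply_affine(image, A, t=(0.0, 0.0), order: int = 1):
    """Warp ``image`` by ``x' = A x + t`` about the image centre.

    ``A`` is 2x2 in (x, y-up) coordinates; ``t`` is in pixels.  Pixels
    mapped from outside the frame are filled with 0.  ``order=0`` gives
    nearest-neighbour resampling (for masks).
    """
    img = np.asarray(image, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine matrix is singular")
    H, W = img.shape[:2]
    M, c = _xy_to_rc(H, W)
    # rc_in = M^-1 (A^-1 ((M rc_out + c) - t) - c)
    Minv, Ainv = np.linalg.inv(M), np.linalg.inv(A)
    B = Minv @ Ainv @ M
    off = Minv @ (Ainv @ (c - t) - c)

    def warp2d(plane):
        return ndimage.affine_transform(plane, B, offset=off, order=order,
                                        mode="constant", cval=0.0,
                                        prefilter=False)

    if img.ndim == 2:
        out = warp2d(img)
    else:
        out = np.stack([warp2d(img[..., k]) for k in range(img.shape[2])],
                       axis=2)
    return out.astype(np.float32)


def rotate(image, theta_deg: float, order: int = 1):
    """Rotate by ``theta_deg`` (counter-clockwise, y-up convention) about
    the image centre using the standard 2-D rotation matrix."""
    th = np.deg2rad(theta_deg)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return apply_affine(image, A, order=order)


def random_rotation(image, rng: np.random.Generator, theta_max: float = 10.0):
    """Rotate by an angle drawn uniformly from [-theta_max, +theta_max]."""
    if theta_max < 0:
        raise ValueError("theta_max must be non-negative")
    theta = rng.uniform(-theta_max, theta_max)
    return rotate(image, theta)


def sample_affine(rng: np.random.Generator, cfg: AugmentConfig, size: int):
    """Draw (A, t) for a random rotation/scale/shear/translation."""
    th = np.deg2rad(rng.uniform(-cfg.affine_degrees, cfg.affine_degrees))
    sh = np.deg2rad(rng.uniform(-cfg.affine_shear, cfg.affine_shear))
    sc = rng.uniform(*cfg.affine_scale)
    tx = rng.uniform(-cfg.affine_translate[0], cfg.affine_translate[0]) * size
    ty = rng.uniform(-cfg.affine_translate[1], cfg.affine_translate[1]) * size
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    Sh = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
    A = R @ Sh @ (sc * np.eye(2))
    return A, np.array([tx, ty])


def random_affine(image, rng: np.random.Generator, cfg: AugmentConfig):
    """Apply a random affine transform (rotation, translation, scale, shear)."""
    A, t = sample_affine(rng, cfg, size=image.shape[0])
    return apply_affine(image, A, t)


def normalize(image, mean: float = 0.5, std: float = 0.5):
    """Per-channel standardisation ``(value - mean) / std``."""
    if std == 0:
        raise ValueError("std must be non-zero")
    return ((np.asarray(image, dtype=np.float32) - mean) / std).astype(
        np.float32)


def denormalize(image, mean: float = 0.5, std: float = 0.5):
    return np.asarray(image, dtype=np.float32) * std + mean


def classifier_augment(image, rng: np.random.Generator, cfg: AugmentConfig):
    """The classifier training stream: random rotation then random affine.

    Normalisation is applied separately by the batch builder.
    """
    out = random_rotation(image, rng, cfg.theta_max)
    out = random_affine(out, rng, cfg)
    return out


def paired_augment(image, mask, rng: np.random.Generator, cfg: AugmentConfig):
    """Identical random rotation + affine applied to an image/mask pair.

    The two transforms are composed into a single warp so the pair is
    resampled once; the mask uses nearest-neighbour resampling and stays
    binary.
    """
    theta = np.deg2rad(rng.uniform(-cfg.theta_max, cfg.theta_max))
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    A2, t = sample_affine(rng, cfg, size=image.shape[0])
    A = A2 @ R
    img = apply_affine(image, A, t, order=1)
    m = apply_affine(np.asarray(mask, dtype=np.float64), A, t, order=0)
    return img, (m > 0.5).astype(np.uint8)
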