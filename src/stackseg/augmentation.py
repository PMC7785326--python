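"""Training-time augmentation and validation-time standardization.

Geometric transforms (dihedral, flip, rotation, skew, perspective /
symmetric warp, jitter) are composed into a single projective warp and
applied with IDENTICAL parameters and identical (bilinear) resampling to
the image channels and to the mask; the mask stays continuous through the
whole pipeline and is thresholded at 0.5 exactly once at the end, which
guarantees binarity and makes image/mask synchronization exact: feeding a
binary image through geometric-only augmentation and binarizing it
reproduces the transformed mask pixel for pixel.

Photometric transforms (brightness, contrast) touch image channels only.
Out-of-frame regions are zero-filled (zero-padding avoids twin-cell
artifacts when a rotated frame would otherwise wrap or reflect a second
copy of the labeled cell into view).  Jitter is interpreted as a small
random translation.  The pipeline ends with a square crop and a resize to
``target_size``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, SimilarityTransform, resize, warp

from .stack_io import MaskLabel


@dataclass(frozen=True)
class AugmentParams:
    """Augmentation magnitudes; mild defaults that keep cells realistic."""

    brightness: float = 0.10        # additive, U(-b, +b)
    contrast: float = 0.15          # multiplicative, U(1-c, 1+c)
    rotation_deg: float = 180.0
    skew: float = 0.1               # shear in tan units
    warp_magnitude: float = 0.2     # perspective corner displacement fraction
    jitter_px: int = 4
    enable_dihedral: bool = True
    enable_rotation: bool = True
    enable_skew: bool = True
    enable_perspective: bool = True
    enable_photometric: bool = True
    enable_jitter: bool = True
    target_size: int = 400

    def __post_init__(self):
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        for name in ("brightness", "contrast", "rotation_deg", "skew",
                     "warp_magnitude"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def geometric_only(self) -> "AugmentParams":
        from dataclasses import replace
        return replace(self, enable_photometric=False)


def _check_shapes(sub: np.ndarray, mask: np.ndarray) -> None:
    if sub.ndim != 3:
        raise ValueError(f"subimage must be (C, H, W), got shape {sub.shape}")
    if sub.shape[1:] != mask.shape:
        raise ValueError(
            f"image {sub.shape[1:]} and mask {mask.shape} shapes differ")


def _dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Apply element k of the dihedral group D4 to the trailing 2 axes."""
    rot, flip = k % 4, k // 4
    out = np.rot90(arr, rot, axes=(-2, -1))
    if flip:
        out = np.flip(out, axis=-1)
    return out


def _build_warp(shape: tuple[int, int], params: AugmentParams,
                rng: np.random.Generator) -> ProjectiveTransform | None:
    H, W = shape
    used = False
    tform = SimilarityTransform()
    center = np.array([W / 2.0, H / 2.0])
    if params.enable_rotation and params.rotation_deg > 0:
        ang = math.radians(rng.uniform(-params.rotation_deg, params.rotation_deg))
        tform = (SimilarityTransform(translation=-center)
                 + SimilarityTransform(rotation=ang)
                 + SimilarityTransform(translation=center))
        used = True
    mat = tform.params
    if params.enable_skew and params.skew > 0:
        sh = rng.uniform(-params.skew, params.skew)
        shear = np.array([[1.0, sh, -sh * center[1]],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]])
        mat = shear @ mat
        used = True
    if params.enable_jitter and params.jitter_px > 0:
        dx = float(rng.integers(-params.jitter_px, params.jitter_px + 1))
        dy = float(rng.integers(-params.jitter_px, params.jitter_px + 1))
        trans = np.array([[1.0, 0.0, dx], [0.0, 1.0, dy], [0.0, 0.0, 1.0]])
        mat = trans @ mat
        used = True
    if params.enable_perspective and params.warp_magnitude > 0:
        # random projective distortion: jitter the four corners
        d = params.warp_magnitude
        src = np.array([[0, 0], [W, 0], [W, H], [0, H]], dtype=float)
        dst = src + rng.uniform(-d, d, size=(4, 2)) * np.array([W, H]) * 0.25
        if hasattr(ProjectiveTransform, "from_estimate"):
            persp = ProjectiveTransform.from_estimate(src, dst)
            ok = bool(persp)
        else:  # older scikit-image
            persp = ProjectiveTransform()
            ok = persp.estimate(src, dst)
        if ok:
            mat = persp.params @ mat
            used = True
    if not used:
        return None
    return ProjectiveTransform(matrix=mat)


def _apply_warp(arr: np.ndarray, tform: ProjectiveTransform) -> np.ndarray:
    """Warp one 2-D array, bilinear, zero-filled outside the frame."""
    return warp(arr.astype(np.float64), tform.inverse, order=1, cval=0.0,
                mode="constant", preserve_range=True)


def _square_crop_resize(arr: np.ndarray, target: int, *,
                        offset: tuple[int, int] | None = None) -> np.ndarray:
    """Center (or offset) square crop followed by bilinear resize."""
    H, W = arr.shape
    side = min(H, W)
    if offset is None:
        r0, c0 = (H - side) // 2, (W - side) // 2
    else:
        r0, c0 = offset
    crop = arr[r0:r0 + side, c0:c0 + side]
    if side == target:
        return crop.astype(np.float64)
    return resize(crop.astype(np.float64), (target, target), order=1,
                  mode="constant", cval=0.0, anti_aliasing=False,
                  preserve_range=True)


def augment_pair(sub: np.ndarray, mask: MaskLabel | np.ndarray,
                 params: AugmentParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, MaskLabel]:
    """Augment an image stack and its mask with synchronized geometry.

    Returns ``(sub', MaskLabel)`` with ``sub'`` of shape
    ``(C, target_size, target_size)`` clipped to [0, 1].
    """
    mask_arr = mask.pixels if isinstance(mask, MaskLabel) else np.asarray(mask)
    sub = np.asarray(sub, dtype=np.float64)
    _check_shapes(sub, mask_arr)
    channels = [sub[c] for c in range(sub.shape[0])]
    m = mask_arr.astype(np.float64)

    if params.enable_dihedral:
        k = int(rng.integers(8))
        channels = [_dihedral(ch, k) for ch in channels]
        m = _dihedral(m, k)

    tform = _build_warp(m.shape, params, rng)
    if tform is not None:
        channels = [_apply_warp(ch, tform) for ch in channels]
        m = _apply_warp(m, tform)

    if params.enable_photometric:
        b = rng.uniform(-params.brightness, params.brightness)
        c = rng.uniform(1.0 - params.contrast, 1.0 + params.contrast)
        channels = [(ch - 0.5) * c + 0.5 + b for ch in channels]

    channels = [_square_crop_resize(ch, params.target_size) for ch in channels]
    m = _square_crop_resize(m, params.target_size)

    out = np.clip(np.stack(channels), 0.0, 1.0).astype(np.float32)
    return out, MaskLabel((m > 0.5).astype(np.uint8))


def validation_transform(sub: np.ndarray, mask: MaskLabel | np.ndarray,
                         target_size: int) -> tuple[np.ndarray, MaskLabel]:
    """Deterministic center square crop + resize; no randomness at all."""
    mask_arr = mask.pixels if isinstance(mask, MaskLabel) else np.asarray(mask)
    sub = np.asarray(sub, dtype=np.float64)
    _check_shapes(sub, mask_arr)
    if sub.shape[1] == sub.shape[2] == target_size:
        return (sub.astype(np.float32),
                MaskLabel(mask_arr.astype(np.uint8)))
    channels = [_square_crop_resize(sub[c], target_size)
                for c in range(sub.shape[0])]
    m = _square_crop_resize(mask_arr.astype(np.float64), target_size)
    out = np.clip(np.stack(channels), 0.0, 1.0).astype(np.float32)
    return out, MaskLabel((m > 0.5).astype(np.uint8))
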