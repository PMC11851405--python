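"""Intensity normalization, patch cropping and seeded augmentation.

Normalization follows common BraTS practice: per-modality z-score over the
nonzero (foreground) support, background left at zero.  Geometric
augmentations (rotation, isotropic scaling, elastic deformation) are applied
with one transform to both image and labels — linear interpolation for the
image, nearest-neighbor for labels — so the pairing is preserved; gamma
correction touches the image only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .io_brats import LabelVolume, ModalityVolume

__all__ = ["AugmentParams", "zscore_normalize", "random_crop", "augment",
           "pad_to_shape"]


def zscore_normalize(mv: ModalityVolume, tol: float = 1e-5) -> ModalityVolume:
    """Per-modality z-score over the nonzero support; background stays 0.

    If a channel has no zero voxels the support is the whole channel.
    Raises DegenerateInputError for a constant foreground channel.
    """
    out = np.zeros_like(mv.data)
    for c in range(mv.data.shape[0]):
        chan = mv.data[c]
        fg = chan != 0
        if not fg.any():
            raise DegenerateInputError(f"channel {c} is identically zero")
        vals = chan[fg]
        sd = vals.std()
        if sd < tol:
            raise DegenerateInputError(
                f"channel {c} has (near-)constant foreground intensity")
        out[c][fg] = (vals - vals.mean()) / sd
    return ModalityVolume(out, mv.spacing)


def pad_to_shape(arr: np.ndarray, target: tuple[int, int, int],
                 value: float = 0.0) -> np.ndarray:
    """Symmetric zero-padding of the trailing three axes up to `target`."""
    spatial = arr.shape[-3:]
    pads = []
    for s, t in zip(spatial, target):
        extra = max(t - s, 0)
        pads.append((extra // 2, extra - extra // 2))
    full = [(0, 0)] * (arr.ndim - 3) + pads
    if any(p != (0, 0) for p in full):
        arr = np.pad(arr, full, constant_values=value)
    return arr


def random_crop(mv: ModalityVolume, lv: LabelVolume, size: tuple[int, int, int],
                seed: int | np.random.Generator) -> tuple[ModalityVolume, LabelVolume]:
    """Crop an identical window from image and labels, uniformly over valid
    corners.  Volumes smaller than `size` are zero-padded symmetrically first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = tuple(int(s) for s in size)
    data = pad_to_shape(mv.data, size)
    labels = pad_to_shape(lv.labels, size)
    spatial = data.shape[1:]
    corner = tuple(int(rng.integers(0, s - t + 1)) for s, t in zip(spatial, size))
    sl = tuple(slice(c, c + t) for c, t in zip(corner, size))
    return (ModalityVolume(data[(slice(None),) + sl], mv.spacing),
            LabelVolume(labels[sl], lv.spacing))


@dataclass
class AugmentParams:
    """Ranges for the random augmentations; each is applied with prob. `p_each`."""

    rotation_deg: float = 15.0          # uniform per-axis rotation in ±range
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_spacing: float = 32.0       # control-point spacing of the field (voxels)
    elastic_sd: float = 4.0             # displacement standard deviation (voxels)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    p_each: float = 0.5


def _rotate_pair(img: np.ndarray, lab: np.ndarray, angles: tuple[float, float, float]):
    """Rotate about each array axis in turn; exact np.rot90 for multiples of 90°."""
    planes = [(1, 2), (0, 2), (0, 1)]       # label-volume axis pairs
    for axis, angle in enumerate(angles):
        if angle == 0.0:
            continue
        plane = planes[axis]
        if angle % 90 == 0:
            k = int(angle // 90) % 4
            img = np.rot90(img, k=k, axes=(plane[0] + 1, plane[1] + 1))
            lab = np.rot90(lab, k=k, axes=plane)
            continue
        img = np.stack([
            ndimage.rotate(ch, angle, axes=plane, reshape=False, order=1,
                           mode="constant", cval=0.0) for ch in img])
        lab = ndimage.rotate(lab, angle, axes=plane, reshape=False, order=0,
                             mode="constant", cval=0)
    return img, np.ascontiguousarray(lab)


def _scale_pair(img: np.ndarray, lab: np.ndarray, scale: float):
    """Isotropic zoom about the volume center, output shape unchanged."""
    if scale == 1.0:
        return img, lab
    shape = np.array(lab.shape, dtype=float)
    center = (shape - 1) / 2.0
    matrix = np.eye(3) / scale
    offset = center - matrix @ center
    img = np.stack([
        ndimage.affine_transform(ch, matrix, offset=offset, order=1,
                                 mode="constant", cval=0.0) for ch in img])
    lab = ndimage.affine_transform(lab, matrix, offset=offset, order=0,
                                   mode="constant", cval=0)
    return img, lab


def _elastic_pair(img: np.ndarray, lab: np.ndarray, spacing: float, sd: float,
                  rng: np.random.Generator):
    """Smooth random displacement field from coarse control points."""
    shape = lab.shape
    coarse = tuple(max(int(np.ceil(s / spacing)) + 1, 2) for s in shape)
    disp = []
    for _ in range(3):
        field = rng.normal(0.0, sd, coarse)
        zoom = [s / c for s, c in zip(shape, coarse)]
        disp.append(ndimage.zoom(field, zoom, order=3))
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    coords = [g + d for g, d in zip(grids, disp)]
    img = np.stack([
        ndimage.map_coordinates(ch, coords, order=1, mode="constant", cval=0.0)
        for ch in img])
    lab = ndimage.map_coordinates(lab, coords, order=0, mode="constant", cval=0)
    return img, lab


def _gamma(img: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma correction per channel on the min-max normalized range."""
    if gamma == 1.0:
        return img
    out = np.empty_like(img)
    for c in range(img.shape[0]):
        ch = img[c]
        lo, hi = ch.min(), ch.max()
        if hi - lo < 1e-8:
            out[c] = ch
            continue
        unit = (ch - lo) / (hi - lo)
        out[c] = unit ** gamma * (hi - lo) + lo
    return out


def augment(mv: ModalityVolume, lv: LabelVolume, params: AugmentParams,
            seed: int | np.random.Generator) -> tuple[ModalityVolume, LabelVolume]:
    """Apply the seeded random augmentations to an image/label pair.

    The random stream is consumed in a fixed order (rotation, scale, elastic,
    gamma) regardless of which transforms fire, so a seed fully determines
    the output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = mv.data.astype(np.float32).copy()
    lab = lv.labels.copy()

    do_rot = rng.random() < params.p_each
    angles = tuple(rng.uniform(-params.rotation_deg, params.rotation_deg, 3))
    do_scale = rng.random() < params.p_each
    scale = float(rng.uniform(*params.scale_range))
    do_elastic = rng.random() < params.p_each
    elastic_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
    do_gamma = rng.random() < params.p_each
    gamma = float(rng.uniform(*params.gamma_range))

    if do_rot and params.rotation_deg != 0:
        img, lab = _rotate_pair(img, lab, angles)
    if do_scale:
        img, lab = _scale_pair(img, lab, scale)
    if do_elastic and params.elastic_sd > 0:
        img, lab = _elastic_pair(img, lab, params.elastic_spacing,
                                 params.elastic_sd, elastic_rng)
    if do_gamma:
        img = _gamma(img, gamma)

    return (ModalityVolume(img.astype(np.float32), mv.spacing),
            LabelVolume(lab.astype(lv.labels.dtype), lv.spacing))


def rotate90(mv: ModalityVolume, lv: LabelVolume, axis: int, k: int = 1):
    """Exact 90°-step rotation of an image/label pair about one array axis."""
    planes = [(1, 2), (0, 2), (0, 1)]
    plane = planes[axis]
    img = np.rot90(mv.data, k=k, axes=(plane[0] + 1, plane[1] + 1)).copy()
    lab = np.rot90(lv.labels, k=k, axes=plane).copy()
    return ModalityVolume(img, mv.spacing), LabelVolume(lab, lv.spacing)
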