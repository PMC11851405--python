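"""NIfTI case I/O and label conversions for BraTS-convention volumes.

A *case* is a directory ``<case>/<case>_{t1,t2,t1ce,flair,seg}.nii.gz`` of
four co-registered modalities plus an optional integer segmentation with
labels 0 (background), 1 (necrosis / non-enhancing core, NCR/NET),
2 (edema, ED) and 4 (enhancing tumor, ET).  Evaluation regions are the
nested unions: whole tumor WT = {1,2,4}, tumor core TC = {1,4}, enhancing
tumor ET = {4}.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InconsistentCaseError, InvalidLabelError, MissingInputError

#: file-name suffixes, in the fixed channel order T1, T2, T1c, Flair
MODALITY_SUFFIXES = ("t1", "t2", "t1ce", "flair")
MODALITY_NAMES = ("T1", "T2", "T1c", "Flair")
VALID_LABELS = frozenset({0, 1, 2, 4})
#: training-class order: background, NCR/NET, ED, ET
CLASS_ORDER = (0, 1, 2, 4)


@dataclass
class ModalityVolume:
    """Four co-registered modality channels with a shared voxel spacing.

    data: float32 array of shape (4, D, H, W), channel order T1/T2/T1c/Flair.
    spacing: mm per voxel along (D, H, W).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITY_SUFFIXES):
            raise InconsistentCaseError(
                f"expected (4, D, H, W) modality stack, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InconsistentCaseError("modality intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InconsistentCaseError(f"invalid spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class LabelVolume:
    """Integer subregion labels on the BraTS convention {0, 1, 2, 4}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise InvalidLabelError("labels must be integers")
            self.labels = self.labels.astype(np.int16)
        if self.labels.ndim != 3:
            raise InvalidLabelError(f"expected rank-3 labels, got {self.labels.shape}")
        present = set(np.unique(self.labels).tolist())
        bad = present - VALID_LABELS
        if bad:
            raise InvalidLabelError(f"label values outside {{0,1,2,4}}: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class RegionMasks:
    """Nested BraTS evaluation regions (boolean, shape D×H×W)."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"wt": self.wt, "tc": self.tc, "et": self.et}


# ----------------------------------------------------------------- NIfTI I/O
def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(path: Path | str, array: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(array), _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path: Path | str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def _case_file(case_dir: Path, suffix: str) -> Path:
    name = case_dir.name
    for ext in (".nii.gz", ".nii"):
        p = case_dir / f"{name}_{suffix}{ext}"
        if p.exists():
            return p
    raise MissingInputError(f"missing {suffix} volume for case {name} in {case_dir}")


def read_case(case_dir: Path | str) -> tuple[ModalityVolume, LabelVolume | None]:
    """Read one BraTS-layout case; the segmentation file is optional."""
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise MissingInputError(f"case directory {case_dir} does not exist")
    channels, spacings = [], []
    for suffix in MODALITY_SUFFIXES:
        arr, spacing = load_nifti(_case_file(case_dir, suffix))
        channels.append(np.asarray(arr, dtype=np.float32))
        spacings.append(spacing)
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise InconsistentCaseError(f"modality shapes disagree: {sorted(shapes)}")
    if len({tuple(np.round(s, 5)) for s in spacings}) != 1:
        raise InconsistentCaseError(f"modality spacings disagree: {spacings}")
    mv = ModalityVolume(np.stack(channels, axis=0), spacings[0])

    lv = None
    try:
        seg_path = _case_file(case_dir, "seg")
    except MissingInputError:
        seg_path = None
    if seg_path is not None:
        seg, seg_spacing = load_nifti(seg_path)
        if seg.shape != mv.shape:
            raise InconsistentCaseError(
                f"segmentation shape {seg.shape} != modality shape {mv.shape}")
        lv = LabelVolume(np.asarray(seg), seg_spacing)
    return mv, lv


def write_case(out_dir: Path | str, case_name: str, mv: ModalityVolume,
               lv: LabelVolume | None = None) -> Path:
    """Write a case in BraTS layout; returns the case directory."""
    case_dir = Path(out_dir) / case_name
    case_dir.mkdir(parents=True, exist_ok=True)
    for i, suffix in enumerate(MODALITY_SUFFIXES):
        save_nifti(case_dir / f"{case_name}_{suffix}.nii.gz", mv.data[i], mv.spacing)
    if lv is not None:
        save_nifti(case_dir / f"{case_name}_seg.nii.gz",
                   lv.labels.astype(np.uint8), lv.spacing)
    return case_dir


# ---------------------------------------------------------- label conversions
def labels_to_onehot(lv: LabelVolume, class_order: tuple = CLASS_ORDER) -> np.ndarray:
    """One-hot training target of shape (len(class_order), D, H, W).

    `class_order` must be a permutation of (0, 1, 2, 4); channels sum to one
    at every voxel.
    """
    if sorted(class_order) != sorted(CLASS_ORDER):
        raise InvalidLabelError(f"class_order must permute {CLASS_ORDER}")
    onehot = np.stack([(lv.labels == c) for c in class_order]).astype(np.float32)
    return onehot


def group_onehot(lv: LabelVolume, groups: tuple[tuple[int, ...], ...]) -> np.ndarray:
    """One-hot target for grouped label classes (used for SMN supervision).

    `groups` is an exhaustive partition of {0,1,2,4}; channel c indicates
    membership of any label in groups[c].
    """
    flat = [l for g in groups for l in g]
    if sorted(flat) != sorted(CLASS_ORDER):
        raise InvalidLabelError(f"groups must partition {CLASS_ORDER}: {groups}")
    return np.stack([np.isin(lv.labels, g) for g in groups]).astype(np.float32)


def labels_to_regions(lv: LabelVolume) -> RegionMasks:
    """Map labels to the nested WT/TC/ET evaluation regions."""
    lab = lv.labels
    return RegionMasks(
        wt=np.isin(lab, (1, 2, 4)),
        tc=np.isin(lab, (1, 4)),
        et=lab == 4,
    )
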