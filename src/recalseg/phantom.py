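"""Seeded synthetic multimodal tumor phantoms.

Phantoms emulate the anatomy and contrast a segmentation network is trained
on: three concentric axis-aligned ellipsoids give the nested subregions
(necrotic core NCR/NET inside an enhancing rim ET inside an edema shell ED),
and per-modality mean intensities reproduce the qualitative MRI contrasts —
tumor hypointense on T1, edema hyperintense on T2/Flair, enhancing rim
bright against the necrotic core on T1c.  Additive Gaussian noise is the
only stochastic element and is drawn from one generator in a fixed order
(one block per modality, in channel order), so a spec plus seed is fully
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidSpecError
from .io_brats import (LabelVolume, ModalityVolume, MODALITY_NAMES, write_case)

#: tissue classes used by the intensity table
TISSUES = ("background", "ED", "ET", "NCR/NET")

#: default mean intensities (arbitrary units) per modality and tissue class;
#: only the orderings are contractual: T1 tumor < background, T2/Flair
#: ED > background, T1c ET > NCR/NET.
DEFAULT_INTENSITIES: dict[tuple[str, str], float] = {
    ("T1", "background"): 100.0, ("T1", "ED"): 70.0,
    ("T1", "ET"): 60.0, ("T1", "NCR/NET"): 50.0,
    ("T2", "background"): 100.0, ("T2", "ED"): 180.0,
    ("T2", "ET"): 140.0, ("T2", "NCR/NET"): 120.0,
    ("T1c", "background"): 100.0, ("T1c", "ED"): 110.0,
    ("T1c", "ET"): 190.0, ("T1c", "NCR/NET"): 70.0,
    ("Flair", "background"): 100.0, ("Flair", "ED"): 190.0,
    ("Flair", "ET"): 150.0, ("Flair", "NCR/NET"): 130.0,
}

#: label codes per tissue (BraTS convention)
_TISSUE_LABEL = {"background": 0, "NCR/NET": 1, "ED": 2, "ET": 4}


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic case.

    The three radius triples define concentric ellipsoids around
    ``wt_center`` (voxel coordinates): the necrotic core fills the innermost
    ellipsoid (et_radii), the enhancing rim the shell out to tc_radii, and
    edema the shell out to wt_radii.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wt_center: tuple[float, float, float] | None = None
    wt_radii: tuple[float, float, float] = (12.0, 12.0, 12.0)
    tc_radii: tuple[float, float, float] = (8.0, 8.0, 8.0)
    et_radii: tuple[float, float, float] = (4.0, 4.0, 4.0)
    intensity_table: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise InvalidSpecError(f"invalid shape {self.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError(f"spacing must be positive: {self.spacing}")
        if self.wt_center is None:
            self.wt_center = tuple((s - 1) / 2.0 for s in self.shape)
        self.wt_center = tuple(float(c) for c in self.wt_center)
        for name in ("wt_radii", "tc_radii", "et_radii"):
            r = tuple(float(v) for v in getattr(self, name))
            if len(r) != 3 or any(v <= 0 for v in r):
                raise InvalidSpecError(f"{name} must be 3 positive reals: {r}")
            setattr(self, name, r)
        if not (all(e < t for e, t in zip(self.et_radii, self.tc_radii))
                and all(t < w for t, w in zip(self.tc_radii, self.wt_radii))):
            raise InvalidSpecError(
                "radii must nest strictly: et_radii < tc_radii < wt_radii")
        for lo, hi, r, c in zip((0, 0, 0), self.shape, self.wt_radii, self.wt_center):
            if c - r < lo - 0.5 or c + r > hi - 0.5:
                raise InvalidSpecError(
                    f"whole-tumor ellipsoid (center {self.wt_center}, radii "
                    f"{self.wt_radii}) exceeds volume bounds {self.shape}")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        missing = [(m, t) for m in MODALITY_NAMES for t in TISSUES
                   if (m, t) not in self.intensity_table]
        if missing:
            raise InvalidSpecError(f"intensity_table missing entries: {missing}")


def spec_for_shape(shape: tuple[int, int, int], **kwargs) -> PhantomSpec:
    """A spec whose ellipsoid radii scale with the volume (3/8, 1/4 and 1/8
    of each axis), so any reasonable shape yields a valid nested phantom."""
    shape = tuple(int(s) for s in shape)
    return PhantomSpec(
        shape=shape,
        wt_radii=tuple(0.375 * s for s in shape),
        tc_radii=tuple(0.25 * s for s in shape),
        et_radii=tuple(0.125 * s for s in shape),
        **kwargs,
    )


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def phantom_labels(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label array from the three nested ellipsoids."""
    wt = _ellipsoid_mask(spec.shape, spec.wt_center, spec.wt_radii)
    tc = _ellipsoid_mask(spec.shape, spec.wt_center, spec.tc_radii)
    core = _ellipsoid_mask(spec.shape, spec.wt_center, spec.et_radii)
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[wt] = _TISSUE_LABEL["ED"]            # edema shell
    labels[tc] = _TISSUE_LABEL["ET"]            # enhancing rim
    labels[core] = _TISSUE_LABEL["NCR/NET"]     # necrotic core
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[ModalityVolume, LabelVolume]:
    """Render a four-modality phantom plus ground truth from `spec`.

    Identical spec and seed produce bit-identical output.
    """
    labels = phantom_labels(spec)
    rng = np.random.default_rng(spec.seed)
    label_of = {t: _TISSUE_LABEL[t] for t in TISSUES}
    channels = []
    for modality in MODALITY_NAMES:
        img = np.zeros(spec.shape, dtype=np.float32)
        for tissue in TISSUES:
            img[labels == label_of[tissue]] = spec.intensity_table[(modality, tissue)]
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)
        channels.append(img)
    mv = ModalityVolume(np.stack(channels), spec.spacing)
    lv = LabelVolume(labels, spec.spacing)
    return mv, lv


def write_phantom_dataset(out_dir: Path | str, n_cases: int,
                          base_spec: PhantomSpec | None = None,
                          seed: int = 0) -> list[Path]:
    """Write `n_cases` phantoms in BraTS case layout, seeds derived from `seed`.

    Case geometry is jittered slightly (center and radii) so cases differ
    beyond the noise realization.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n_cases):
        # one common radius factor preserves the strict nesting; small center
        # jitter keeps the whole-tumor ellipsoid inside the volume
        factor = rng.uniform(0.9, 1.02)
        shift = rng.uniform(-1.0, 1.0, size=3)
        spec = PhantomSpec(
            shape=base.shape, spacing=base.spacing,
            wt_center=tuple(c + d for c, d in zip(base.wt_center, shift)),
            wt_radii=tuple(r * factor for r in base.wt_radii),
            tc_radii=tuple(r * factor for r in base.tc_radii),
            et_radii=tuple(r * factor for r in base.et_radii),
            intensity_table=base.intensity_table,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        mv, lv = generate_phantom(spec)
        paths.append(write_case(out_dir, f"phantom_{i:03d}", mv, lv))
    return paths
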