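"""The Dual Recalibration Module (DRM).

The DRM fuses the multi-modality decoder feature with the same-scale
single-modality decoder features at each resolution level.  It has two
stages:

* **Spatial recalibration (SR).**  Each branch's channels are compressed to
  a single map by a 1x1x1 convolution; the per-branch maps are stacked and
  softmax-normalized across branches at every voxel, and each branch is
  multiplied by its weight map.  The weights therefore sum to one per voxel
  — a per-voxel soft arbitration between the branches.

* **Channel recalibration (CR).**  Global average pooling reduces every
  branch to an R-vector; the vectors are concatenated and three independent
  branch-specific fully-connected heads followed by a sigmoid produce
  per-channel weights in (0, 1), which scale the branch's channels
  (squeeze-excitation across branches).

The fused output is the elementwise sum of the recalibrated branches.  By
default CR consumes the SR outputs (sequential composition); a flag
computes both stages' weights from the raw inputs and applies them
multiplicatively (parallel composition).  Ablation modes skip either stage,
or replace the DRM by plain 1x1x1 convolutional fusion ("none").

Single-modality features whose width differs from the target R are first
mapped by a learned 1x1x1 projection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidShapeError
from .nn import Conv3d, Linear, Module, Tensor, concat, softmax

__all__ = ["DRM_MODES", "SpatialWeights", "ChannelWeights", "DualRecalibration"]

DRM_MODES = ("full", "sr_only", "cr_only", "none")


@dataclass
class SpatialWeights:
    """Per-branch voxel weight maps (batch, O, P, Q); sum to 1 per voxel."""

    weights: dict[str, np.ndarray]


@dataclass
class ChannelWeights:
    """Per-branch channel weight vectors (batch, R); entries in (0, 1)."""

    weights: dict[str, np.ndarray]


def _check_same_shape(blocks: dict[str, Tensor]) -> None:
    shapes = {b: t.shape for b, t in blocks.items()}
    if len(set(shapes.values())) != 1:
        raise InvalidShapeError(f"branch feature shapes differ: {shapes}")


class DualRecalibration(Module):
    """One DRM site fusing the MMN branch with 1-2 SMN branches.

    Parameters
    ----------
    width : channel count R of the multi-modality feature at this scale.
    smn_widths : mapping branch name ("t1c", "flair") -> incoming SMN width.
    mode : one of `DRM_MODES`; selects the ablation variant.
    composition : "sequential" (CR consumes SR outputs, default) or
        "parallel" (both weightings computed from the raw inputs).
    """

    def __init__(self, width: int, smn_widths: dict[str, int], mode: str = "full",
                 composition: str = "sequential",
                 rng: np.random.Generator | None = None):
        if mode not in DRM_MODES:
            raise InvalidConfigError(f"drm mode must be one of {DRM_MODES}: {mode!r}")
        if composition not in ("sequential", "parallel"):
            raise InvalidConfigError(f"unknown composition {composition!r}")
        if not smn_widths:
            raise InvalidConfigError("DRM needs at least one SMN branch")
        rng = rng or np.random.default_rng()
        self.width = width
        self.mode = mode
        self.composition = composition
        self.branches = ("mmn",) + tuple(smn_widths)
        self.project = {b: Conv3d(w, width, kernel_size=1, padding=0, rng=rng)
                        for b, w in smn_widths.items()}
        k = len(self.branches)
        self.sr_compress = {b: Conv3d(width, 1, kernel_size=1, padding=0, rng=rng)
                            for b in self.branches}
        self.cr_fc = {b: Linear(k * width, width, rng=rng) for b in self.branches}
        self.fuse_conv = Conv3d(k * width, width, kernel_size=1, padding=0, rng=rng)

    # ------------------------------------------------------------ operations
    def project_channels(self, branch: str, f_smn: Tensor) -> Tensor:
        """Map an SMN feature to the target width R by 1x1x1 convolution."""
        return self.project[branch](f_smn)

    def spatial_recalibrate(self, blocks: dict[str, Tensor]
                            ) -> tuple[dict[str, Tensor], SpatialWeights]:
        """Per-voxel softmax arbitration across branches."""
        _check_same_shape(blocks)
        logits = concat([self.sr_compress[b](blocks[b]) for b in self.branches],
                        axis=1)                       # (B, k, O, P, Q)
        w = softmax(logits, axis=1)
        out = {b: blocks[b] * w[:, i:i + 1]
               for i, b in enumerate(self.branches)}
        weights = SpatialWeights({b: w.data[:, i] for i, b in enumerate(self.branches)})
        return out, weights

    def _channel_weight_tensors(self, blocks: dict[str, Tensor]) -> dict[str, Tensor]:
        gaps = [blocks[b].mean(axis=(2, 3, 4)) for b in self.branches]  # (B, R)
        pooled = concat(gaps, axis=1)                                    # (B, kR)
        return {b: self.cr_fc[b](pooled).sigmoid() for b in self.branches}

    def channel_recalibrate(self, blocks: dict[str, Tensor],
                            weight_source: dict[str, Tensor] | None = None
                            ) -> tuple[dict[str, Tensor], ChannelWeights]:
        """Squeeze-excitation channel reweighting across branches.

        Weights are computed from `weight_source` if given (the parallel
        composition), otherwise from `blocks` themselves.
        """
        _check_same_shape(blocks)
        us = self._channel_weight_tensors(weight_source or blocks)
        batch = next(iter(blocks.values())).shape[0]
        out = {b: blocks[b] * us[b].reshape(batch, self.width, 1, 1, 1)
               for b in self.branches}
        return out, ChannelWeights({b: us[b].data for b in self.branches})

    # ----------------------------------------------------------------- fusion
    def forward_with_weights(self, f_mmn: Tensor, smn_feats: dict[str, Tensor]
                             ) -> tuple[Tensor, SpatialWeights | None,
                                        ChannelWeights | None]:
        expected = set(self.branches) - {"mmn"}
        if set(smn_feats) != expected:
            raise InvalidConfigError(
                f"expected SMN branches {sorted(expected)}, got {sorted(smn_feats)}")
        blocks = {"mmn": f_mmn}
        for b, f in smn_feats.items():
            blocks[b] = self.project_channels(b, f)
        _check_same_shape(blocks)

        if self.mode == "none":
            fused = self.fuse_conv(concat([blocks[b] for b in self.branches], axis=1))
            return fused, None, None
        sw = cw = None
        if self.mode in ("full", "sr_only"):
            sr_out, sw = self.spatial_recalibrate(blocks)
        if self.mode == "sr_only":
            out = sr_out
        elif self.mode == "cr_only":
            out, cw = self.channel_recalibrate(blocks)
        elif self.composition == "sequential":
            out, cw = self.channel_recalibrate(sr_out)
        else:  # parallel: CR weights from the raw inputs, applied on SR outputs
            out, cw = self.channel_recalibrate(sr_out, weight_source=blocks)
        fused = out[self.branches[0]]
        for b in self.branches[1:]:
            fused = fused + out[b]
        return fused, sw, cw

    def forward(self, f_mmn: Tensor, smn_feats: dict[str, Tensor]) -> Tensor:
        return self.forward_with_weights(f_mmn, smn_feats)[0]
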