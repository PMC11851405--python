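"""3D U-Net backbones: the four-channel multi-modality network (MMN) and the
narrower single-modality networks (SMNs).

Both share one topology: a four-level encoder (two 3x3x3 conv blocks per
level, each conv + instance norm + ReLU, downsampling by stride-2
convolution) and a symmetric decoder (trilinear upsampling + convolution,
skip concatenation, two conv blocks), with a 1x1x1 logit head at full
resolution.  Channel widths default to (32, 64, 128, 256); SMNs scale them
by `smn_width_factor` to keep their memory footprint small.  The decoder
features at each of the four scales — bottleneck outward — are exposed so
the dual recalibration module can fuse the branches scale by scale.

The two SMNs supervise modality-specific class groupings.  The default
("flair_merged") assignment gives the Flair network {background, ED, ET+NCR/NET}
(edema is what Flair shows best) and the T1c network
{background+ED, ET, NCR/NET} (T1c contrasts the enhancing rim against the
necrotic core); the alternative "t1c_merged" assignment swaps the two
readings, and "all_labels" supervises both SMNs on all four classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidShapeError
from .nn import Conv3d, InstanceNorm3d, Module, Tensor, concat, upsample_trilinear2x

__all__ = ["NetConfig", "UNet3D", "build_mmn", "build_smn", "SMN_TARGET_GROUPS",
           "smn_groups"]

#: label groupings per SMN under the two readings of the target assignment,
#: plus the all-labels ablation variant.  Each grouping is an exhaustive
#: partition of the labels {0, 1, 2, 4}.
SMN_TARGET_GROUPS: dict[str, dict[str, tuple[tuple[int, ...], ...]]] = {
    "flair_merged": {
        "t1c": ((0, 2), (4,), (1,)),      # other / ET / NCR-NET
        "flair": ((0,), (2,), (1, 4)),    # background / ED / tumor core
    },
    "t1c_merged": {
        "t1c": ((0,), (2,), (1, 4)),
        "flair": ((0, 2), (4,), (1,)),
    },
    "all_labels": {
        "t1c": ((0,), (1,), (2,), (4,)),
        "flair": ((0,), (1,), (2,), (4,)),
    },
}


def smn_groups(assignment: str, branch: str) -> tuple[tuple[int, ...], ...]:
    try:
        return SMN_TARGET_GROUPS[assignment][branch]
    except KeyError:
        raise InvalidConfigError(
            f"unknown SMN target assignment {assignment!r} / branch {branch!r}")


@dataclass
class NetConfig:
    """Topology configuration for one backbone network."""

    in_channels: int = 4
    class_count: int = 4
    widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    norm_kind: str = "instance"           # "instance" or "none"
    smn_width_factor: float = 0.5

    def __post_init__(self):
        self.widths = tuple(int(w) for w in self.widths)
        if len(self.widths) != 4 or any(b <= a for a, b in zip(self.widths, self.widths[1:])):
            raise InvalidConfigError(f"widths must be 4 strictly increasing ints: {self.widths}")
        if self.class_count < 2:
            raise InvalidConfigError("class_count must be >= 2")
        if self.norm_kind not in ("instance", "none"):
            raise InvalidConfigError(f"unknown norm_kind {self.norm_kind!r}")

    def smn_widths(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(w * self.smn_width_factor))) for w in self.widths)


class ConvBlock(Module):
    """3x3x3 convolution + normalization + ReLU."""

    def __init__(self, cin: int, cout: int, norm_kind: str, rng):
        self.conv = Conv3d(cin, cout, kernel_size=3, rng=rng)
        self.norm = InstanceNorm3d(cout) if norm_kind == "instance" else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.relu()


class UNet3D(Module):
    """Encoder-decoder with skip connections and per-scale feature access.

    Decoder features are indexed by scale 0..3 where 3 is the bottleneck
    (widths[3] channels at 1/8 resolution) and 0 the full-resolution level.
    """

    n_levels = 4

    def __init__(self, in_channels: int, class_count: int,
                 widths: tuple[int, int, int, int], norm_kind: str = "instance",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.widths = tuple(widths)
        self.class_count = class_count
        w = self.widths
        # the stride-2 down convolutions already map w[l] -> w[l+1], so every
        # encoder block keeps its level's width (level 0 ingests the image)
        self.enc_blocks = []
        for level in range(self.n_levels):
            cin = in_channels if level == 0 else w[level]
            self.enc_blocks.append([ConvBlock(cin, w[level], norm_kind, rng),
                                    ConvBlock(w[level], w[level], norm_kind, rng)])
        self.down = [Conv3d(w[i], w[i + 1], kernel_size=3, stride=2, rng=rng)
                     for i in range(self.n_levels - 1)]
        # decoder: upsample conv w[l+1]->w[l], then two blocks on concat
        self.up = [Conv3d(w[i + 1], w[i], kernel_size=3, rng=rng)
                   for i in range(self.n_levels - 1)]
        self.dec_blocks = [[ConvBlock(2 * w[i], w[i], norm_kind, rng),
                            ConvBlock(w[i], w[i], norm_kind, rng)]
                           for i in range(self.n_levels - 1)]
        self.head = Conv3d(w[0], class_count, kernel_size=1, padding=0, rng=rng)

    # ------------------------------------------------------------- structure
    def decoder_widths(self) -> tuple[int, ...]:
        """Channel widths of the decoder features from bottleneck upward."""
        return tuple(reversed(self.widths))

    def _check_shape(self, x: Tensor) -> None:
        spatial = x.shape[2:]
        factor = 2 ** (self.n_levels - 1)
        if any(s % factor != 0 or s < factor for s in spatial):
            raise InvalidShapeError(
                f"spatial shape {spatial} must be divisible by {factor} "
                f"for {self.n_levels - 1} downsamplings")

    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Returns (skips at levels 0..2, bottleneck at level 3)."""
        self._check_shape(x)
        skips = []
        for level in range(self.n_levels):
            for block in self.enc_blocks[level]:
                x = block(x)
            if level < self.n_levels - 1:
                skips.append(x)
                x = self.down[level](x).relu()
        return skips, x

    def decode_level(self, level: int, f: Tensor, skip: Tensor) -> Tensor:
        """One decoder step: upsample the level+1 feature, merge the skip."""
        x = self.up[level](upsample_trilinear2x(f))
        x = concat([x, skip], axis=1)
        for block in self.dec_blocks[level]:
            x = block(x)
        return x

    def forward(self, x: Tensor, feature_hook=None) -> tuple[Tensor, list[Tensor]]:
        """Full pass.  Returns (logits, decoder features bottleneck-first).

        `feature_hook(scale, feature) -> feature` may replace each decoder
        feature before it flows onward (the DRM fusion site).
        """
        skips, f = self.encode(x)
        features = []
        if feature_hook is not None:
            f = feature_hook(3, f)
        features.append(f)
        for level in range(self.n_levels - 2, -1, -1):
            f = self.decode_level(level, f, skips[level])
            if feature_hook is not None:
                f = feature_hook(level, f)
            features.append(f)
        logits = self.head(f)
        return logits, features


def build_mmn(cfg: NetConfig, rng: np.random.Generator | None = None) -> UNet3D:
    """The four-channel multi-modality network."""
    return UNet3D(cfg.in_channels, cfg.class_count, cfg.widths,
                  norm_kind=cfg.norm_kind, rng=rng)


def build_smn(cfg: NetConfig, target_groups: tuple[tuple[int, ...], ...],
              rng: np.random.Generator | None = None) -> UNet3D:
    """A single-modality network with width-scaled channels.

    `target_groups` is the label partition the SMN is supervised on; its
    length sets the logit channel count.
    """
    return UNet3D(1, len(target_groups), cfg.smn_widths(),
                  norm_kind=cfg.norm_kind, rng=rng)
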