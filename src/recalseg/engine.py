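"""Training, inference and ablation orchestration.

The combined model runs the four-channel multi-modality U-Net and the
single-modality T1c/Flair U-Nets in parallel; at each of the four decoder
scales a Dual Recalibration Module fuses the same-scale features and the
fused block replaces the multi-modality decoder feature.  All active
networks are optimized jointly on the lambda-weighted total loss.

Inference is sliding-window: overlapping patches are forwarded, class
probabilities averaged, and the argmax decoded back to BraTS labels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .backbone import NetConfig, UNet3D, build_mmn, build_smn, smn_groups
from .drm import DRM_MODES, DualRecalibration
from .errors import InvalidConfigError, RecalsegError
from .io_brats import (CLASS_ORDER, LabelVolume, ModalityVolume, group_onehot,
                       labels_to_onehot, read_case)
from .losses import compound_loss, loss_terms, total_loss
from .metrics import MetricReport, evaluate_labels
from .nn import Module, Tensor, build_optimizer, softmax
from .preprocess import AugmentParams, augment, pad_to_shape, random_crop, zscore_normalize

__all__ = ["TrainConfig", "RecalibrationModel", "TrainResult", "train", "predict",
           "run_ablation", "ABLATION_VARIANTS", "save_checkpoint",
           "load_checkpoint"]

#: modality channel index feeding each SMN branch (T1, T2, T1c, Flair)
SMN_CHANNEL = {"t1c": 2, "flair": 3}

SMN_SETS = ("both", "t1c_only", "flair_only", "none", "all_labels")


@dataclass
class TrainConfig:
    """Hyperparameters and architecture switches for one run.

    Defaults follow the reference training recipe (Adam, lr 1e-4, weight
    decay 2e-5, batch 4, 100 epochs, 96x128x128 patches, 300 patches per
    epoch); `desk_scale()` gives a small-profile variant for CPU-sized runs.
    """

    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 2e-5
    optimizer: str = "adam"
    patch_size: tuple[int, int, int] = (96, 128, 128)
    patches_per_epoch: int = 300
    lam: float = 0.5
    drm_mode: str = "full"
    drm_composition: str = "sequential"
    smn_set: str = "both"
    smn_targets: str = "flair_merged"
    widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    smn_width_factor: float = 0.5
    val_fraction: float = 0.1
    do_augment: bool = True
    augment_params: AugmentParams = field(default_factory=AugmentParams)
    normalize: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise InvalidConfigError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.drm_mode not in DRM_MODES:
            raise InvalidConfigError(f"drm_mode must be one of {DRM_MODES}")
        if self.smn_set not in SMN_SETS:
            raise InvalidConfigError(f"smn_set must be one of {SMN_SETS}")
        if min(self.epochs, self.batch_size, self.patches_per_epoch) < 1:
            raise InvalidConfigError("epochs/batch_size/patches_per_epoch must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise InvalidConfigError("invalid optimizer hyperparameters")
        self.patch_size = tuple(int(p) for p in self.patch_size)
        self.widths = tuple(int(w) for w in self.widths)

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Small CPU profile: 32^3 patches, batch 2, widths (8, 16, 32, 64)."""
        base = dict(patch_size=(32, 32, 32), batch_size=2,
                    widths=(8, 16, 32, 64), patches_per_epoch=8, epochs=2)
        base.update(overrides)
        return cls(**base)

    # branch bookkeeping -----------------------------------------------------
    def active_branches(self) -> tuple[str, ...]:
        return {"both": ("t1c", "flair"), "all_labels": ("t1c", "flair"),
                "t1c_only": ("t1c",), "flair_only": ("flair",),
                "none": ()}[self.smn_set]

    def target_assignment(self) -> str:
        return "all_labels" if self.smn_set == "all_labels" else self.smn_targets

    def net_config(self) -> NetConfig:
        return NetConfig(in_channels=4, class_count=len(CLASS_ORDER),
                         widths=self.widths,
                         smn_width_factor=self.smn_width_factor)


class RecalibrationModel(Module):
    """MMN + active SMNs + one DRM per decoder scale."""

    def __init__(self, cfg: TrainConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        net_cfg = cfg.net_config()
        self.mmn = build_mmn(net_cfg, rng=rng)
        self.branches = cfg.active_branches()
        self.smn_groups = {b: smn_groups(cfg.target_assignment(), b)
                           for b in self.branches}
        self.smns = {b: build_smn(net_cfg, self.smn_groups[b], rng=rng)
                     for b in self.branches}
        if self.branches:
            smn_widths_per_scale = list(reversed(net_cfg.smn_widths()))
            mmn_widths_per_scale = self.mmn.decoder_widths()
            self.drms = [DualRecalibration(
                width=mmn_widths_per_scale[i],
                smn_widths={b: smn_widths_per_scale[i] for b in self.branches},
                mode=cfg.drm_mode, composition=cfg.drm_composition, rng=rng)
                for i in range(UNet3D.n_levels)]
        else:
            self.drms = []

    def forward(self, x: Tensor) -> tuple[Tensor, dict[str, Tensor]]:
        """Returns (MMN logits, per-branch SMN logits)."""
        smn_logits: dict[str, Tensor] = {}
        smn_feats: dict[str, list[Tensor]] = {}
        for b in self.branches:
            xb = x[:, SMN_CHANNEL[b]:SMN_CHANNEL[b] + 1]
            logits_b, feats_b = self.smns[b](xb)
            smn_logits[b] = logits_b
            smn_feats[b] = feats_b          # bottleneck-first: scales 3,2,1,0

        if self.branches:
            def hook(scale: int, f: Tensor) -> Tensor:
                idx = UNet3D.n_levels - 1 - scale
                return self.drms[idx](f, {b: smn_feats[b][idx]
                                          for b in self.branches})
        else:
            hook = None
        logits, _ = self.mmn(x, feature_hook=hook)
        return logits, smn_logits


@dataclass
class TrainResult:
    model: RecalibrationModel
    config: TrainConfig
    history: list[dict]

    @property
    def final_loss(self) -> float:
        return self.history[-1]["train_loss"]


def _load_cases(cases) -> list[tuple[ModalityVolume, LabelVolume]]:
    loaded = []
    for case in cases:
        if isinstance(case, (str, Path)):
            mv, lv = read_case(case)
        else:
            mv, lv = case
        if lv is None:
            raise InvalidConfigError(f"case {case} has no labels; cannot train")
        loaded.append((mv, lv))
    return loaded


def _step_losses(model: RecalibrationModel, batch_img: np.ndarray,
                 batch_lab: list[LabelVolume], cfg: TrainConfig):
    """Forward a batch and return (total Tensor, LossTerms)."""
    x = Tensor(batch_img)
    mmn_logits, smn_logits = model(x)
    mmn_target = np.stack([labels_to_onehot(lv) for lv in batch_lab])
    l_mmn = compound_loss(mmn_logits, mmn_target)
    smn_losses = {}
    for b, logits_b in smn_logits.items():
        target_b = np.stack([group_onehot(lv, model.smn_groups[b])
                             for lv in batch_lab])
        smn_losses[b] = compound_loss(logits_b, target_b)
    if not smn_losses:
        total = l_mmn
        terms = loss_terms(l_mmn.item(), 0.0, 0.0, 1.0)
    else:
        l_t1c = smn_losses.get("t1c", Tensor(0.0))
        l_flair = smn_losses.get("flair", Tensor(0.0))
        total = total_loss(l_mmn, l_t1c, l_flair, cfg.lam)
        terms = loss_terms(l_mmn.item(), l_t1c.item(), l_flair.item(), cfg.lam)
    return total, terms


def train(cases, cfg: TrainConfig, out_dir: Path | str | None = None,
          progress: bool = False) -> TrainResult:
    """Joint training of all active networks on labeled cases.

    Each epoch samples `patches_per_epoch` random (augmented) patches,
    groups them into batches, and updates all parameters on the total loss.
    With `out_dir`, per-epoch losses go to ``history.jsonl`` and parameters
    to ``checkpoints/epoch_NNN.npz``.
    """
    data = _load_cases(cases)
    if cfg.normalize:
        data = [(zscore_normalize(mv), lv) for mv, lv in data]
    rng = np.random.default_rng(cfg.seed)

    n_val = int(round(cfg.val_fraction * len(data)))
    order = rng.permutation(len(data))
    val_idx = set(order[:n_val].tolist())
    train_data = [d for i, d in enumerate(data) if i not in val_idx]
    val_data = [d for i, d in enumerate(data) if i in val_idx]
    if not train_data:
        raise InvalidConfigError("validation split left no training cases")

    model = RecalibrationModel(cfg, rng=np.random.default_rng(cfg.seed))
    opt = build_optimizer(cfg.optimizer, model.parameters(),
                          lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "checkpoints").mkdir(parents=True, exist_ok=True)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        epoch_losses, epoch_terms = [], []
        n_batches = max(1, cfg.patches_per_epoch // cfg.batch_size)
        for _ in range(n_batches):
            imgs, labs = [], []
            for _ in range(cfg.batch_size):
                mv, lv = train_data[rng.integers(len(train_data))]
                mv_p, lv_p = random_crop(mv, lv, cfg.patch_size, rng)
                if cfg.do_augment:
                    mv_p, lv_p = augment(mv_p, lv_p, cfg.augment_params, rng)
                imgs.append(mv_p.data)
                labs.append(lv_p)
            total, terms = _step_losses(model, np.stack(imgs), labs, cfg)
            if not np.isfinite(total.item()):
                raise RecalsegError(
                    f"non-finite loss at epoch {epoch}: {terms.as_dict()}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(total.item())
            epoch_terms.append(terms)

        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "l_mmn": float(np.mean([t.l_mmn for t in epoch_terms])),
            "l_smn_t1c": float(np.mean([t.l_smn_t1c for t in epoch_terms])),
            "l_smn_flair": float(np.mean([t.l_smn_flair for t in epoch_terms])),
        }
        if val_data:
            val_losses = []
            for mv, lv in val_data:
                mv_p, lv_p = random_crop(mv, lv, cfg.patch_size, rng)
                v_total, _ = _step_losses(model, mv_p.data[None], [lv_p], cfg)
                val_losses.append(v_total.item())
            record["val_loss"] = float(np.mean(val_losses))
        history.append(record)
        if progress:
            print(f"epoch {epoch:3d}  train {record['train_loss']:.4f}"
                  + (f"  val {record['val_loss']:.4f}" if val_data else ""))
        if out_path is not None:
            with open(out_path / "history.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
            save_checkpoint(out_path / "checkpoints" / f"epoch_{epoch:03d}.npz",
                            model)
    return TrainResult(model=model, config=cfg, history=history)


# -------------------------------------------------------------- checkpointing
def save_checkpoint(path: Path | str, model: RecalibrationModel) -> None:
    np.savez(str(path), **model.state_dict())


def load_checkpoint(path: Path | str, cfg: TrainConfig) -> RecalibrationModel:
    model = RecalibrationModel(cfg)
    with np.load(str(path)) as data:
        try:
            model.load_state_dict({k: data[k] for k in data.files})
        except (KeyError, ValueError) as exc:
            raise InvalidConfigError(
                f"checkpoint {path} incompatible with config: {exc}") from exc
    return model


# ------------------------------------------------------------------ inference
def predict(mv: ModalityVolume, model: RecalibrationModel,
            cfg: TrainConfig | None = None) -> LabelVolume:
    """Sliding-window inference with overlap-averaged class probabilities."""
    cfg = cfg or model.cfg
    img = zscore_normalize(mv).data if cfg.normalize else mv.data.copy()
    orig_shape = img.shape[1:]
    patch = cfg.patch_size
    img = pad_to_shape(img, patch)
    shape = img.shape[1:]

    n_classes = len(CLASS_ORDER)
    probs = np.zeros((n_classes,) + shape, dtype=np.float32)
    counts = np.zeros(shape, dtype=np.float32)

    starts = []
    for s, p in zip(shape, patch):
        stride = max(p // 2, 1)
        axis_starts = list(range(0, max(s - p, 0) + 1, stride))
        if axis_starts[-1] != s - p:
            axis_starts.append(s - p)
        starts.append(sorted(set(axis_starts)))

    for d0 in starts[0]:
        for h0 in starts[1]:
            for w0 in starts[2]:
                sl = (slice(d0, d0 + patch[0]), slice(h0, h0 + patch[1]),
                      slice(w0, w0 + patch[2]))
                window = img[(slice(None),) + sl][None]
                logits, _ = model(Tensor(window))
                p = softmax(logits, axis=1).data[0]
                probs[(slice(None),) + sl] += p
                counts[sl] += 1.0

    probs /= np.maximum(counts, 1.0)
    class_idx = probs.argmax(axis=0)
    labels = np.asarray(CLASS_ORDER, dtype=np.int16)[class_idx]
    # crop symmetric padding back to the original shape
    offs = [(s - o) // 2 for s, o in zip(labels.shape, orig_shape)]
    sl = tuple(slice(o, o + n) for o, n in zip(offs, orig_shape))
    return LabelVolume(labels[sl], mv.spacing)


# ------------------------------------------------------------------ ablations
#: §-style ablation variants -> (smn_set, drm_mode)
ABLATION_VARIANTS: dict[str, dict] = {
    "mm_only": {"smn_set": "none", "drm_mode": "full"},
    "mm_flair": {"smn_set": "flair_only", "drm_mode": "full"},
    "mm_t1c": {"smn_set": "t1c_only", "drm_mode": "full"},
    "mm_smn_all_labels": {"smn_set": "all_labels", "drm_mode": "full"},
    "no_drm": {"smn_set": "both", "drm_mode": "none"},
    "sr_only": {"smn_set": "both", "drm_mode": "sr_only"},
    "cr_only": {"smn_set": "both", "drm_mode": "cr_only"},
    "full": {"smn_set": "both", "drm_mode": "full"},
}


def variant_config(variant: str, cfg: TrainConfig) -> TrainConfig:
    if variant not in ABLATION_VARIANTS:
        raise InvalidConfigError(
            f"unknown ablation variant {variant!r}; "
            f"expected one of {sorted(ABLATION_VARIANTS)}")
    return replace(cfg, **ABLATION_VARIANTS[variant])


def run_ablation(variants, cases, cfg: TrainConfig,
                 progress: bool = False) -> dict[str, dict]:
    """Train and evaluate each variant; held-out cases give the metrics.

    Returns variant -> {"mean": flat mean metrics, "cases": per-case
    MetricReports, "history": loss history}.
    """
    data = _load_cases(cases)
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(data))))
    order = rng.permutation(len(data))
    val_idx = set(order[:n_val].tolist())
    train_cases = [d for i, d in enumerate(data) if i not in val_idx]
    test_cases = [d for i, d in enumerate(data) if i in val_idx]

    results: dict[str, dict] = {}
    for variant in variants:
        vcfg = replace(variant_config(variant, cfg), val_fraction=0.0)
        res = train(train_cases, vcfg, progress=progress)
        reports: list[MetricReport] = []
        for mv, lv in test_cases:
            pred = predict(mv, res.model, vcfg)
            reports.append(evaluate_labels(pred, lv))
        mean = {k: float(np.mean([r.flat()[k] for r in reports]))
                for k in reports[0].flat()}
        results[variant] = {"mean": mean, "cases": reports,
                            "history": res.history}
        if progress:
            print(f"{variant}: " + ", ".join(f"{k}={v:.3f}"
                                             for k, v in mean.items()))
    return results


def ablation_table(results: dict[str, dict]) -> str:
    """Render ablation results as a region-by-metric CSV table."""
    metrics = ("dice", "ppv", "sensitivity", "hd95")
    regions = ("et", "wt", "tc")
    header = "variant," + ",".join(f"{r}_{m}" for r in regions for m in metrics)
    lines = [header]
    for variant, res in results.items():
        row = [variant] + [f"{res['mean'][f'{r}_{m}']:.4f}"
                           for r in regions for m in metrics]
        lines.append(",".join(row))
    return "\n".join(lines)
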