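"""Dual Recalibration Module: closed-form identities and brute-force oracles."""
import numpy as np
import pytest

from recalseg.drm import DualRecalibration
from recalseg.errors import InvalidShapeError
from recalseg.nn import Tensor

R = 8
SHAPE = (1, R, 4, 4, 4)


def make_drm(mode="full", smn_width=4, rng_seed=0, composition="sequential"):
    return DualRecalibration(R, {"t1c": smn_width, "flair": smn_width},
                             mode=mode, composition=composition,
                             rng=np.random.default_rng(rng_seed))


def make_inputs(rng, smn_width=4):
    f_mmn = Tensor(rng.normal(size=SHAPE).astype(np.float32))
    smn = {b: Tensor(rng.normal(size=(1, smn_width, 4, 4, 4)).astype(np.float32))
           for b in ("t1c", "flair")}
    return f_mmn, smn


# ------------------------------------------------------------ oracle helpers
def conv1x1_oracle(f, weight, bias):
    """Explicit 1x1x1 convolution: out[o] = sum_c w[o,c] f[c] + b[o]."""
    w = weight.data.reshape(weight.shape[0], weight.shape[1])
    out = np.einsum("oc,bcdhw->bodhw", w, f)
    return out + bias.data.reshape(1, -1, 1, 1, 1)


def spatial_weights_oracle(drm, blocks):
    """Per-voxel softmax over the compressed branch maps, by explicit exp."""
    logits = np.concatenate([
        conv1x1_oracle(blocks[b], drm.sr_compress[b].weight,
                       drm.sr_compress[b].bias)
        for b in drm.branches], axis=1)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def channel_weights_oracle(drm, blocks):
    """sigmoid(FC(concat(GAP per branch))) by explicit summation."""
    gaps = [blocks[b].mean(axis=(2, 3, 4)) for b in drm.branches]
    pooled = np.concatenate(gaps, axis=1)
    out = {}
    for b in drm.branches:
        fc = drm.cr_fc[b]
        z = pooled @ fc.weight.data + fc.bias.data
        out[b] = 1.0 / (1.0 + np.exp(-z))
    return out


def full_drm_oracle(drm, f_mmn, smn_feats):
    """Step-by-step recomputation: project, SR, CR on SR outputs, sum."""
    blocks = {"mmn": f_mmn.data.copy()}
    for b, f in smn_feats.items():
        blocks[b] = conv1x1_oracle(f.data, drm.project[b].weight,
                                   drm.project[b].bias)
    w = spatial_weights_oracle(drm, blocks)
    sr = {b: blocks[b] * w[:, i:i + 1] for i, b in enumerate(drm.branches)}
    u = channel_weights_oracle(drm, sr)
    cr = {b: sr[b] * u[b][:, :, None, None, None] for b in drm.branches}
    return sum(cr[b] for b in drm.branches)


def zero_stage(convs_or_fcs):
    for layer in convs_or_fcs.values():
        layer.weight.data[:] = 0.0
        layer.bias.data[:] = 0.0


# ------------------------------------------------------------------ identities
def test_zeroed_compression_gives_uniform_spatial_weights(rng):
    drm = make_drm(smn_width=R)
    zero_stage(drm.sr_compress)
    blocks = {b: Tensor(rng.normal(size=SHAPE).astype(np.float32))
              for b in drm.branches}
    out, sw = drm.spatial_recalibrate(blocks)
    for b in drm.branches:
        assert np.allclose(sw.weights[b], 1.0 / 3.0, atol=1e-6)
        assert np.allclose(out[b].data, blocks[b].data / 3.0, atol=1e-6)


def test_softmax_closed_form_for_log_two_logit(rng):
    """Branch logits (ln 2, 0, 0) must weight as (1/2, 1/4, 1/4)."""
    drm = make_drm(smn_width=R)
    zero_stage(drm.sr_compress)
    drm.sr_compress["mmn"].bias.data[:] = np.log(2.0)
    blocks = {b: Tensor(rng.normal(size=SHAPE).astype(np.float32))
              for b in drm.branches}
    _, sw = drm.spatial_recalibrate(blocks)
    assert np.allclose(sw.weights["mmn"], 0.5, atol=1e-6)
    assert np.allclose(sw.weights["t1c"], 0.25, atol=1e-6)
    assert np.allclose(sw.weights["flair"], 0.25, atol=1e-6)


def test_zeroed_fc_heads_give_half_channel_weights(rng):
    drm = make_drm(smn_width=R)
    zero_stage(drm.cr_fc)
    blocks = {b: Tensor(rng.normal(size=SHAPE).astype(np.float32))
              for b in drm.branches}
    out, cw = drm.channel_recalibrate(blocks)
    for b in drm.branches:
        assert np.allclose(cw.weights[b], 0.5, atol=1e-7)
        assert np.allclose(out[b].data, blocks[b].data / 2.0, atol=1e-6)


def test_gap_of_constant_feature_is_exact(rng):
    drm = make_drm(smn_width=R)
    const = np.arange(R, dtype=np.float32)
    blocks = {b: Tensor(np.broadcast_to(const[None, :, None, None, None],
                                        SHAPE).copy())
              for b in drm.branches}
    gap = blocks["mmn"].mean(axis=(2, 3, 4)).data
    assert np.array_equal(gap[0], const)


def test_double_zeroing_gives_sixth_of_projected_sum(rng):
    """Uniform SR (1/3) then uniform CR (1/2) scales the sum by 1/6."""
    drm = make_drm()
    zero_stage(drm.sr_compress)
    zero_stage(drm.cr_fc)
    f_mmn, smn = make_inputs(rng)
    fused, _, _ = drm.forward_with_weights(f_mmn, smn)
    projected = sum(conv1x1_oracle(smn[b].data, drm.project[b].weight,
                                   drm.project[b].bias) for b in ("t1c", "flair"))
    expected = (f_mmn.data + projected) / 6.0
    assert np.allclose(fused.data, expected, atol=1e-5)


def test_plain_fusion_with_identity_weights_sums_inputs(rng):
    """mode=none with identity projection and summing 1x1 fusion conv."""
    drm = make_drm(mode="none", smn_width=R)
    for b in ("t1c", "flair"):
        drm.project[b].weight.data[:] = np.eye(R).reshape(R, R, 1, 1, 1)
        drm.project[b].bias.data[:] = 0.0
    drm.fuse_conv.weight.data[:] = 0.0
    drm.fuse_conv.bias.data[:] = 0.0
    for k in range(3):                      # branch k contributes channel r
        for r in range(R):
            drm.fuse_conv.weight.data[r, k * R + r, 0, 0, 0] = 1.0
    f_mmn, smn = make_inputs(rng, smn_width=R)
    fused = drm(f_mmn, smn)
    expected = f_mmn.data + smn["t1c"].data + smn["flair"].data
    assert np.allclose(fused.data, expected, atol=1e-5)


def test_identity_projection_with_equal_widths_is_identity(rng):
    drm = make_drm(smn_width=R)
    drm.project["t1c"].weight.data[:] = np.eye(R).reshape(R, R, 1, 1, 1)
    drm.project["t1c"].bias.data[:] = 0.0
    f = Tensor(rng.normal(size=SHAPE).astype(np.float32))
    assert np.allclose(drm.project_channels("t1c", f).data, f.data, atol=1e-6)


def test_projection_maps_width_and_rejects_spatial_mismatch(rng):
    drm = DualRecalibration(32, {"t1c": 16, "flair": 16},
                            rng=np.random.default_rng(0))
    f = Tensor(rng.normal(size=(1, 16, 8, 8, 8)).astype(np.float32))
    assert drm.project_channels("t1c", f).shape == (1, 32, 8, 8, 8)
    bad = {"mmn": Tensor(np.zeros((1, 32, 8, 8, 8), dtype=np.float32)),
           "t1c": Tensor(np.zeros((1, 32, 4, 4, 4), dtype=np.float32)),
           "flair": Tensor(np.zeros((1, 32, 8, 8, 8), dtype=np.float32))}
    with pytest.raises(InvalidShapeError):
        drm.spatial_recalibrate(bad)


# ---------------------------------------------------------------- oracles
@pytest.mark.parametrize("seed", range(5))
def test_random_drm_matches_step_by_step_recomputation(seed):
    rng = np.random.default_rng(seed)
    drm = make_drm(rng_seed=seed + 100)
    f_mmn, smn = make_inputs(rng)
    fused, sw, cw = drm.forward_with_weights(f_mmn, smn)
    expected = full_drm_oracle(drm, f_mmn, smn)
    assert np.allclose(fused.data, expected, rtol=1e-4, atol=1e-5)
    # weight invariants
    total = sum(sw.weights[b] for b in drm.branches)
    assert np.allclose(total, 1.0, atol=1e-5)
    for b in drm.branches:
        assert np.all(cw.weights[b] > 0.0) and np.all(cw.weights[b] < 1.0)


def test_fused_output_is_the_weighted_recombination(rng):
    """Eq-style decomposition: fused = sum_b u_b * (w_b * projected_b); a
    zeroed branch input contributes exactly nothing."""
    drm = make_drm(rng_seed=3)
    f_mmn, smn = make_inputs(rng)
    smn["t1c"].data[:] = 0.0
    drm.project["t1c"].bias.data[:] = 0.0   # zero input stays zero after projection
    fused, sw, cw = drm.forward_with_weights(f_mmn, smn)
    blocks = {"mmn": f_mmn.data,
              "t1c": conv1x1_oracle(smn["t1c"].data, drm.project["t1c"].weight,
                                    drm.project["t1c"].bias),
              "flair": conv1x1_oracle(smn["flair"].data, drm.project["flair"].weight,
                                      drm.project["flair"].bias)}
    terms = {b: cw.weights[b][:, :, None, None, None]
             * (sw.weights[b][:, None] * blocks[b]) for b in drm.branches}
    assert np.allclose(fused.data, sum(terms.values()), rtol=1e-4, atol=1e-5)
    assert np.allclose(terms["t1c"], 0.0)


def test_all_modes_share_the_output_shape(rng):
    f_mmn, smn = make_inputs(rng)
    shapes = set()
    for mode in ("full", "sr_only", "cr_only", "none"):
        drm = make_drm(mode=mode)
        shapes.add(drm(f_mmn, smn).shape)
    assert shapes == {SHAPE}


def test_parallel_composition_weights_come_from_raw_inputs(rng):
    drm = make_drm(composition="parallel", rng_seed=9)
    f_mmn, smn = make_inputs(rng)
    fused, sw, cw = drm.forward_with_weights(f_mmn, smn)
    blocks = {"mmn": f_mmn.data,
              "t1c": conv1x1_oracle(smn["t1c"].data, drm.project["t1c"].weight,
                                    drm.project["t1c"].bias),
              "flair": conv1x1_oracle(smn["flair"].data, drm.project["flair"].weight,
                                      drm.project["flair"].bias)}
    u_raw = channel_weights_oracle(drm, blocks)
    for b in drm.branches:
        assert np.allclose(cw.weights[b], u_raw[b], rtol=1e-4, atol=1e-6)
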