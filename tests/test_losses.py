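"""Loss functions against closed forms and scalar-loop oracles."""
import numpy as np
import pytest

from recalseg.errors import InvalidConfigError, InvalidShapeError
from recalseg.losses import ce_loss, compound_loss, dice_loss, loss_terms, total_loss
from recalseg.nn import Tensor


def softmax_np(logits):
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def dice_oracle(logits, onehot, eps=1e-5):
    """Scalar-loop soft Dice in float64: per class, 2*sum(pt)/(sum p + sum t)."""
    probs = softmax_np(np.asarray(logits, dtype=np.float64))
    onehot = np.asarray(onehot, dtype=np.float64)
    n_classes = probs.shape[1]
    dices = []
    for j in range(n_classes):
        inter = num_p = num_t = 0.0
        for b in range(probs.shape[0]):
            for idx in np.ndindex(probs.shape[2:]):
                p = probs[(b, j) + idx]
                t = onehot[(b, j) + idx]
                inter += p * t
                num_p += p
                num_t += t
        dices.append((2 * inter + eps) / (num_p + num_t + eps))
    return 1.0 - float(np.mean(dices))


def ce_oracle(logits, onehot):
    """Scalar-loop cross-entropy with the 1/(Np*M) normalization."""
    probs = softmax_np(np.asarray(logits, dtype=np.float64))
    onehot = np.asarray(onehot, dtype=np.float64)
    n_classes = probs.shape[1]
    m = probs.size // n_classes
    acc = 0.0
    for j in range(n_classes):
        for b in range(probs.shape[0]):
            for idx in np.ndindex(probs.shape[2:]):
                acc += onehot[(b, j) + idx] * np.log(max(probs[(b, j) + idx], 1e-12))
    return -acc / (n_classes * m)


def random_instance(rng, n_classes=4, shape=(2, 2, 3)):
    logits = rng.normal(size=(1, n_classes) + shape).astype(np.float32)
    labels = rng.integers(0, n_classes, size=(1,) + shape)
    onehot = np.moveaxis(np.eye(n_classes, dtype=np.float32)[labels], -1, 1)
    return logits, onehot


def test_perfect_prediction_drives_dice_loss_to_zero(rng):
    _, onehot = random_instance(rng)
    logits = 50.0 * (2.0 * onehot - 1.0)       # softmax ~ exact one-hot
    assert dice_loss(Tensor(logits), onehot).item() < 1e-4
    assert ce_loss(Tensor(logits), onehot).item() < 1e-4


def test_uniform_two_class_instance_has_half_dice_loss():
    """Np=2, M=4, p=0.5 everywhere, truth balanced -> soft Dice 0.5."""
    logits = np.zeros((1, 2, 1, 1, 4), dtype=np.float32)
    onehot = np.zeros_like(logits)
    onehot[0, 0, 0, 0, :2] = 1.0
    onehot[0, 1, 0, 0, 2:] = 1.0
    assert dice_loss(Tensor(logits), onehot).item() == pytest.approx(0.5, abs=1e-5)


def test_uniform_four_class_ce_is_quarter_log_four(rng):
    _, onehot = random_instance(rng, shape=(2, 3, 3))
    logits = np.zeros_like(onehot)
    expected = np.log(4.0) / 4.0
    assert ce_loss(Tensor(logits), onehot).item() == pytest.approx(expected, rel=1e-5)


@pytest.mark.parametrize("seed", range(10))
def test_vectorized_losses_match_scalar_loops(seed):
    rng = np.random.default_rng(seed)
    n_classes = int(rng.integers(2, 5))
    shape = tuple(rng.integers(2, 4, size=3))
    logits, onehot = random_instance(rng, n_classes=n_classes, shape=shape)
    assert dice_loss(Tensor(logits), onehot).item() == pytest.approx(
        dice_oracle(logits, onehot), rel=1e-5)
    assert ce_loss(Tensor(logits), onehot).item() == pytest.approx(
        ce_oracle(logits, onehot), rel=1e-5)


def test_losses_are_permutation_equivariant_over_voxels(rng):
    logits, onehot = random_instance(rng, shape=(2, 3, 2))
    perm = rng.permutation(12)
    lg = logits.reshape(1, 4, -1)[:, :, perm].reshape(logits.shape)
    oh = onehot.reshape(1, 4, -1)[:, :, perm].reshape(onehot.shape)
    assert dice_loss(Tensor(lg), oh).item() == pytest.approx(
        dice_loss(Tensor(logits), onehot).item(), rel=1e-5)
    assert ce_loss(Tensor(lg), oh).item() == pytest.approx(
        ce_loss(Tensor(logits), onehot).item(), rel=1e-5)


def test_losses_decrease_as_mass_moves_to_the_true_class(rng):
    logits, onehot = random_instance(rng, shape=(2, 2, 2))
    true_class = int(np.argmax(onehot[0, :, 0, 0, 0]))
    d0 = dice_loss(Tensor(logits), onehot).item()
    c0 = ce_loss(Tensor(logits), onehot).item()
    for bump in (0.5, 1.0, 2.0):
        boosted = logits.copy()
        boosted[0, true_class, 0, 0, 0] += bump
        assert dice_loss(Tensor(boosted), onehot).item() <= d0 + 1e-7
        assert ce_loss(Tensor(boosted), onehot).item() <= c0 + 1e-7


def test_shape_mismatch_is_rejected(rng):
    logits, onehot = random_instance(rng)
    with pytest.raises(InvalidShapeError):
        dice_loss(Tensor(logits), onehot[:, :3])
    with pytest.raises(InvalidShapeError):
        ce_loss(Tensor(logits[:, :, :1]), onehot)


def test_total_loss_boundaries_and_arithmetic():
    assert total_loss(0.8, 0.4, 0.6, 1.0) == 0.8
    assert total_loss(0.8, 0.4, 0.6, 0.0) == pytest.approx(0.5)
    assert total_loss(0.8, 0.4, 0.6, 0.5) == pytest.approx(0.65)
    terms = loss_terms(0.8, 0.4, 0.6, 0.5)
    assert terms.l_total == pytest.approx(0.65)
    with pytest.raises(InvalidConfigError):
        total_loss(1.0, 1.0, 1.0, 1.5)


def test_compound_loss_is_dice_plus_ce(rng):
    logits, onehot = random_instance(rng)
    expected = (dice_loss(Tensor(logits), onehot).item()
                + ce_loss(Tensor(logits), onehot).item())
    assert compound_loss(Tensor(logits), onehot).item() == pytest.approx(
        expected, rel=1e-6)
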