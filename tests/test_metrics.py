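"""Evaluation metrics against printed-count cases and all-pairs brute force."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recalseg.errors import InvalidShapeError
from recalseg.io_brats import LabelVolume
from recalseg.metrics import (ConfusionCounts, confusion, evaluate_labels,
                              hd95, overlap_metrics)


def brute_force_hd95(pred, true, spacing):
    """O(n^2) surface-distance oracle with explicit neighbor scan."""
    def surface(mask):
        pts = []
        shape = mask.shape
        for idx in np.argwhere(mask):
            for ax in range(3):
                for d in (-1, 1):
                    n = idx.copy()
                    n[ax] += d
                    if (n < 0).any() or (n >= shape).any() or not mask[tuple(n)]:
                        pts.append(idx)
                        break
                else:
                    continue
                break
        return np.asarray(pts, dtype=float)

    sp = np.asarray(spacing, dtype=float)
    sp_p, sp_t = surface(pred) * sp, surface(true) * sp
    d_pt = [min(np.linalg.norm(p - t) for t in sp_t) for p in sp_p]
    d_tp = [min(np.linalg.norm(t - p) for p in sp_p) for t in sp_t]
    return max(np.percentile(d_pt, 95), np.percentile(d_tp, 95))


def random_mask(rng, shape=(12, 12, 12), n_voxels=20):
    mask = np.zeros(shape, dtype=bool)
    idx = rng.choice(np.prod(shape), size=n_voxels, replace=False)
    mask.ravel()[idx] = True
    return mask


def test_confusion_identical_and_disjoint_masks():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[:2] = True
    c = confusion(a, a)
    assert (c.n_tp, c.n_fp, c.n_fn) == (32, 0, 0)
    b = np.zeros_like(a)
    b[3, :2] = True
    c = confusion(b, a)
    assert (c.n_tp, c.n_fp, c.n_fn) == (0, 8, 32)


@pytest.mark.parametrize("seed", range(5))
def test_confusion_matches_per_voxel_tally(seed):
    rng = np.random.default_rng(seed)
    pred = rng.random((8, 8, 8)) > 0.5
    true = rng.random((8, 8, 8)) > 0.5
    c = confusion(pred, true)
    tp = fp = fn = 0
    for idx in np.ndindex(pred.shape):
        tp += pred[idx] and true[idx]
        fp += pred[idx] and not true[idx]
        fn += true[idx] and not pred[idx]
    assert (c.n_tp, c.n_fp, c.n_fn) == (tp, fp, fn)


@pytest.mark.parametrize("counts,expected", [
    ((2, 1, 1), (4 / 6, 2 / 3, 2 / 3)),
    ((8, 2, 2), (0.8, 0.8, 0.8)),
    ((5, 0, 0), (1.0, 1.0, 1.0)),
    ((0, 0, 0), (1.0, 1.0, 1.0)),          # both masks empty
    ((0, 3, 0), (0.0, 0.0, 0.0)),          # prediction only
])
def test_overlap_metrics_from_printed_counts(counts, expected):
    result = overlap_metrics(ConfusionCounts(*counts))
    assert result == pytest.approx(expected)


@given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_dice_is_the_harmonic_mean_of_ppv_and_sensitivity(tp, fp, fn):
    dice, sens, ppv = overlap_metrics(ConfusionCounts(tp, fp, fn))
    assert 0.0 <= dice <= 1.0
    if tp > 0:
        assert dice == pytest.approx(2 * ppv * sens / (ppv + sens))


def test_overlap_scores_stay_in_unit_interval(rng):
    for _ in range(50):
        c = ConfusionCounts(*(int(v) for v in rng.integers(0, 30, 3)))
        for value in overlap_metrics(c):
            assert 0.0 <= value <= 1.0


def test_hd95_identical_masks_is_zero(rng):
    mask = random_mask(rng)
    assert hd95(mask, mask) == 0.0


def test_hd95_single_voxel_pair_is_their_distance():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros_like(a)
    a[0, 0, 0] = True
    b[3, 0, 0] = True
    assert hd95(a, b, (1, 1, 1)) == pytest.approx(3.0)
    assert hd95(a, b, (2, 1, 1)) == pytest.approx(6.0)


@pytest.mark.parametrize("spacing", [(1, 1, 1), (1, 1, 2)])
@pytest.mark.parametrize("seed", range(5))
def test_hd95_matches_all_pairs_brute_force(seed, spacing):
    rng = np.random.default_rng(seed)
    pred, true = random_mask(rng), random_mask(rng)
    assert hd95(pred, true, spacing) == pytest.approx(
        brute_force_hd95(pred, true, spacing), abs=1e-9)


def test_hd95_is_symmetric_and_translation_invariant(rng):
    pred, true = random_mask(rng), random_mask(rng)
    assert hd95(pred, true) == pytest.approx(hd95(true, pred), abs=1e-12)
    shifted_p = np.roll(np.pad(pred, 3), 2, axis=(0, 1))
    shifted_t = np.roll(np.pad(true, 3), 2, axis=(0, 1))
    assert hd95(shifted_p, shifted_t) == pytest.approx(hd95(pred, true), abs=1e-9)


def test_hd95_empty_mask_conventions():
    empty = np.zeros((4, 4, 4), dtype=bool)
    full = ~empty
    assert hd95(empty, empty) == 0.0
    diag = np.sqrt(3 * 16.0)
    assert hd95(empty, full, (1, 1, 1)) == pytest.approx(diag)
    with pytest.raises(InvalidShapeError):
        hd95(empty, np.zeros((4, 4, 5), dtype=bool))


def test_case_report_for_identical_phantom_labels(default_phantom):
    _, lv = default_phantom
    report = evaluate_labels(lv, lv)
    for region in ("wt", "tc", "et"):
        scores = report.as_dict()[region]
        assert scores["dice"] == 1.0
        assert scores["hd95"] == 0.0
    flat = report.flat()
    assert set(flat) == {f"{r}_{m}" for r in ("wt", "tc", "et")
                        for m in ("dice", "sensitivity", "ppv", "hd95")}
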