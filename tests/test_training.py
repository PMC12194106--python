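"""Loss correctness, initialization, schedule, folds, and the train loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catransunet import (Adam, ModelConfig, ReduceLROnPlateau, SceneParams,
                         TrainConfig, balanced_bce_loss, build_dataset,
                         build_model, dice_coefficient, five_fold_split,
                         init_weights, load_checkpoint, save_checkpoint,
                         train_loop)
from conftest import numeric_gradient
from catransunet import autodiff as ad


# ---------------------------------------------------------------------------
# Balanced BCE
# ---------------------------------------------------------------------------

def test_loss_closed_form_single_pixel():
    """gt=1, logit=0 (sigma=0.5) -> -ln(0.5) ~= 0.6931."""
    loss = balanced_bce_loss(np.zeros((1, 1)), np.ones((1, 1)))
    assert float(loss.data) == pytest.approx(-math.log(0.5), abs=1e-6)


def test_loss_two_pixel_hand_case():
    """sigma(pred)=(0.8,0.8), gt=(1,0) -> -(ln .8 + ln .2)/2 ~= 0.9163."""
    logit = math.log(0.8 / 0.2)
    loss = balanced_bce_loss(np.array([[logit, logit]]), np.array([[1.0, 0.0]]))
    expect = -(math.log(0.8) + math.log(0.2)) / 2
    assert float(loss.data) == pytest.approx(expect, abs=1e-6)


def test_loss_vanishes_for_confident_correct_predictions():
    logits = np.array([[40.0, -40.0]])
    gt = np.array([[1.0, 0.0]])
    assert float(balanced_bce_loss(logits, gt).data) < 1e-12


def test_loss_rejects_non_binary_ground_truth():
    with pytest.raises(ValueError, match="binary"):
        balanced_bce_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))


def test_pos_weight_scales_foreground_terms():
    base = float(balanced_bce_loss(np.zeros((1, 2)), np.array([[1.0, 0.0]])).data)
    weighted = float(balanced_bce_loss(np.zeros((1, 2)), np.array([[1.0, 0.0]]),
                                       pos_weight=3.0).data)
    # only the gt=1 pixel's -ln(0.5) is tripled
    assert weighted == pytest.approx(base + math.log(2), abs=1e-6)


def test_loss_gradient_matches_finite_differences(rng):
    logits = rng.standard_normal((1, 1, 3, 3))
    gt = (rng.random((1, 1, 3, 3)) > 0.6).astype(np.float64)

    def scalar(x):
        return float(balanced_bce_loss(x, gt, pos_weight=2.0).data)

    t = ad.Tensor(logits.copy(), requires_grad=True)
    balanced_bce_loss(t, gt, pos_weight=2.0).backward()
    num = numeric_gradient(scalar, logits)
    assert np.abs(num - t.grad).max() / np.abs(num).max() < 1e-4


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_loss_permutation_and_duplication_invariance(seed):
    """The mean loss ignores pixel order and exact duplication."""
    r = np.random.default_rng(seed)
    logits = r.standard_normal(12)
    gt = (r.random(12) > 0.5).astype(float)
    base = float(balanced_bce_loss(logits[None], gt[None]).data)
    perm = r.permutation(12)
    assert float(balanced_bce_loss(logits[perm][None], gt[perm][None]).data) \
        == pytest.approx(base, rel=1e-6)
    dup = float(balanced_bce_loss(np.tile(logits, 2)[None],
                                  np.tile(gt, 2)[None]).data)
    assert dup == pytest.approx(base, rel=1e-6)


def test_dice_conventions():
    assert dice_coefficient(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0
    a = np.zeros((4, 4)); a[:2] = 1
    assert dice_coefficient(a, a) == 1.0
    assert dice_coefficient(a, 1 - a) == 0.0


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _tiny():
    return ModelConfig(stage_widths=[8, 16, 24, 32], bottleneck_width=32,
                       input_size=64, casc_grid=16)


def test_init_is_reproducible_and_seed_sensitive():
    m1 = init_weights(build_model(_tiny()), seed=7)
    m2 = init_weights(build_model(_tiny()), seed=7)
    m3 = init_weights(build_model(_tiny()), seed=8)
    s1, s2, s3 = m1.state_dict(), m2.state_dict(), m3.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
    assert any(not np.array_equal(s1[k], s3[k]) for k in s1)


def test_bottleneck_is_identity_after_init(rng):
    model = init_weights(build_model(_tiny()), seed=3)
    x = rng.standard_normal((1, 32, 4, 4)).astype(np.float32)
    out = model.bottleneck(x)
    assert out.data.tobytes() == x.tobytes()


# ---------------------------------------------------------------------------
# Schedule and folds
# ---------------------------------------------------------------------------

def test_plateau_schedule_drops_lr_by_factor_ten():
    class P:  # minimal parameter stub
        pass

    opt = Adam([], lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.1, patience=2)
    sched.step(1.0)            # establishes the best
    assert not sched.step(1.0)
    assert sched.step(1.0)     # second stale evaluation triggers the cut
    assert opt.lr == pytest.approx(1e-4)


def test_improvement_resets_patience():
    opt = Adam([], lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.1, patience=2)
    for m in (1.0, 0.9, 0.8, 0.7, 0.6):
        sched.step(m)
    assert opt.lr == pytest.approx(1e-3)


@pytest.mark.parametrize("n,sizes", [(100, {20}), (103, {21, 20})])
def test_five_fold_sizes(n, sizes):
    folds = five_fold_split(list(range(n)), seed=0)
    assert {len(f) for f in folds} == sizes


def test_five_folds_partition_the_index_set():
    folds = five_fold_split(list(range(23)), seed=5)
    allidx = np.concatenate(folds)
    assert sorted(allidx) == list(range(23))
    assert len(set(allidx)) == 23
    again = five_fold_split(list(range(23)), seed=5)
    assert all(np.array_equal(a, b) for a, b in zip(folds, again))
    with pytest.raises(ValueError, match="at least 5"):
        five_fold_split([1, 2, 3], seed=0)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _scenes(n=4, size=64, seed=2):
    return build_dataset([n], seed=seed,
                         base_params=SceneParams(canvas_size=size, seed=seed))


def test_loop_reduces_loss_and_records_history():
    scenes = _scenes()
    model = init_weights(build_model(_tiny()), seed=1)
    cfg = TrainConfig(total_iterations=20, batch_size=4, val_fraction=0.0,
                      val_interval=10, seed=1, pos_weight="auto")
    model, hist = train_loop(model, scenes, cfg)
    assert len(hist["loss"]) == 20
    assert hist["loss"][-1] < hist["loss"][0]
    assert hist["val"] and "lr" in hist["val"][-1]


def test_empty_dataset_raises():
    model = build_model(_tiny())
    with pytest.raises(ValueError, match="empty"):
        train_loop(model, [], TrainConfig())


def test_fixed_seed_reproduces_loss_trajectory():
    scenes = _scenes()
    cfg = TrainConfig(total_iterations=6, batch_size=4, val_fraction=0.0,
                      val_interval=6, seed=9)
    runs = []
    for _ in range(2):
        model = init_weights(build_model(_tiny()), seed=9)
        _, hist = train_loop(model, scenes, cfg)
        runs.append(hist["loss"])
    assert runs[0] == runs[1]


def test_checkpoint_round_trip(tmp_path, rng):
    model = init_weights(build_model(_tiny()), seed=4)
    save_checkpoint(tmp_path / "ck.npz", model, TrainConfig(), iteration=12)
    loaded, meta = load_checkpoint(tmp_path / "ck.npz")
    assert meta["iteration"] == 12
    x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
    model.eval(); loaded.eval()
    with ad.no_grad():
        assert np.array_equal(model(x).data, loaded(x).data)
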