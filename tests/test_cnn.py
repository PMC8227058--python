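"""CNN unit checks: augmentation involutions, determinism, degenerate training,
fold partitioning and leakage. Kept small (tiny images / few epochs); the full
cross-validation accuracy run lives in the acceptance suite."""

import numpy as np
import pytest

import htpyield as h
from htpyield.cnn import (
    CNNRegressor,
    _augment_batch,
    build_regressor,
    lfcnn_spec,
    macnn_table_spec,
    resolve_arch,
)
from htpyield.extraction import PlotImage


def _random_images(rng, n=24, px=32):
    return (rng.random((n, px, px, 3)) * 255).astype(np.uint8)


def test_augment_flips_involution_and_histograms(rng):
    img = PlotImage(7, _random_images(rng, 1)[0])
    variants = h.augment_flips(img)
    assert len(variants) == 4
    assert all(v.plot_id == 7 for v in variants)
    # flipping twice recovers the original
    assert (h.augment_flips(variants[1])[1].pixels == img.pixels).all()
    assert (h.augment_flips(variants[2])[2].pixels == img.pixels).all()
    # flips permute pixels: per-channel histograms identical
    for v in variants[1:]:
        for c in range(3):
            assert (np.bincount(v.pixels[..., c].ravel(), minlength=256)
                    == np.bincount(img.pixels[..., c].ravel(), minlength=256)).all()


def test_asymmetric_pattern_changes_under_flip():
    px = np.zeros((8, 8, 3), dtype=np.uint8)
    px[:, :4] = 255
    variants = h.augment_flips(px)
    assert (variants[1] != px).any()


def test_build_regressor_deterministic_and_param_counts():
    m1, n1 = build_regressor("macnn", 32, seed=5)
    m2, n2 = build_regressor("macnn", 32, seed=5)
    assert n1 == n2
    for (l1, k1), (l2, k2) in zip(m1.parameters(), m2.parameters()):
        assert (l1.params[k1] == l2.params[k2]).all()
    # wide variant lands near the million-parameter scale
    _, n_wide = build_regressor(macnn_table_spec(), 64, seed=0)
    assert 0.55e6 <= n_wide <= 2.2e6


def test_zero_conv_blocks_rejected():
    with pytest.raises(ValueError):
        build_regressor(h.ArchSpec(conv_blocks=()), 32, seed=0)
    with pytest.raises(ValueError):
        resolve_arch("resnet999")


def test_multistream_network_runs(rng):
    model, n = build_regressor(lfcnn_spec(n_streams=3), 32, seed=1)
    x = rng.random((4, 3, 32, 32)).astype(np.float32)
    out = model.forward(x, train=True)
    assert out.shape == (4, 1)
    model.backward(np.ones_like(out, dtype=np.float32))
    assert n == model.n_params()


def test_constant_target_converges(rng):
    imgs = _random_images(rng, n=20)
    est = CNNRegressor(input_px=32, epochs=5, batch_size=10, augment=False,
                       val_fraction=0.0, random_state=0)
    est.fit(imgs, np.full(20, 1234.0))
    assert est.predict(imgs) == pytest.approx(np.full(20, 1234.0), abs=1e-6)


def test_zero_learning_rate_freezes_weights(rng):
    imgs = _random_images(rng, n=12)
    y = rng.normal(size=12)
    # no dropout and one full batch per epoch so the train-mode loss is
    # reproducible epoch to epoch when the weights cannot move
    arch = h.ArchSpec(dropout_rate=0.0)
    est = CNNRegressor(arch=arch, input_px=32, epochs=3, batch_size=12,
                       learning_rate=0.0, augment=False, val_fraction=0.0,
                       random_state=1)
    ref, _ = build_regressor(arch, 32, seed=1)
    est.fit(imgs, y)
    for (la, ka), (lb, kb) in zip(est.network_.parameters(), ref.parameters()):
        if not isinstance(la.params[ka], np.ndarray):
            continue
        assert np.allclose(la.params[ka], lb.params[kb])
    assert np.ptp(est.loss_trace_) < 1e-6


def test_fit_deterministic_per_seed(rng):
    imgs = _random_images(rng, n=16)
    y = rng.normal(1000, 100, size=16)
    preds = []
    for _ in range(2):
        est = CNNRegressor(input_px=32, epochs=2, batch_size=8, augment=False,
                           val_fraction=0.0, random_state=3)
        est.fit(imgs, y)
        preds.append(est.predict(imgs))
    assert (preds[0] == preds[1]).all()


def test_nonfinite_targets_rejected(rng):
    imgs = _random_images(rng, n=4)
    est = CNNRegressor(input_px=32, epochs=1)
    with pytest.raises(ValueError):
        est.fit(imgs, [1.0, 2.0, np.nan, 4.0])


def test_crossval_fold_partition(rng):
    imgs = _random_images(rng, n=30)
    y = rng.normal(1000, 100, size=30)
    htp = h.crossval_predict(imgs, y, k=10, seed=4, input_px=32, epochs=1,
                             batch_size=16, augment=False, val_fraction=0.0)
    sizes = np.bincount(htp.folds)
    assert sizes.tolist() == [3] * 10
    assert (htp.folds >= 0).all()
    assert np.isfinite(htp.values).all()
    assert len(htp.fold_metrics) == 10


def test_leave_one_out_boundary(rng):
    imgs = _random_images(rng, n=12)
    y = rng.normal(size=12)
    htp = h.crossval_predict(imgs, y, k=12, seed=0, input_px=32, epochs=1,
                             batch_size=8, augment=False, val_fraction=0.0)
    assert np.bincount(htp.folds).tolist() == [1] * 12


def test_k_larger_than_n_rejected(rng):
    imgs = _random_images(rng, n=5)
    with pytest.raises(ValueError):
        h.crossval_predict(imgs, np.ones(5), k=6, input_px=32)


def test_no_leakage_augmented_copies_stay_in_training_fold():
    """Augmentation happens inside fit on the training images only: the
    augmented batch contains flips of training plots and nothing else."""
    rng = np.random.default_rng(0)
    x = rng.random((6, 3, 8, 8)).astype(np.float32)
    aug = _augment_batch(x)
    assert aug.shape[0] == 24
    # every augmented image is a flip of an original training image
    for block, flip in zip(range(4), [lambda a: a,
                                      lambda a: a[:, :, :, ::-1],
                                      lambda a: a[:, :, ::-1, :],
                                      lambda a: a[:, :, ::-1, ::-1]]):
        assert np.allclose(aug[6 * block: 6 * (block + 1)], flip(x))
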