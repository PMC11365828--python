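"""Losses against brute-force oracles; model contracts; training smoke."""

import numpy as np
import pytest

from osteoplan import nets
from osteoplan import pipeline as pp

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Independent oracle implementations (naive, loop-based where feasible)
# ---------------------------------------------------------------------------


def oracle_ncc(a, b):
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum()
                 / (np.sqrt((am**2).sum()) * np.sqrt((bm**2).sum())))


def oracle_gc(y, yh):
    """Direct evaluation: mean of horizontal/vertical gradient-image NCCs."""
    lam1, lam2 = np.gradient(y, axis=1), np.gradient(yh, axis=1)
    kap1, kap2 = np.gradient(y, axis=0), np.gradient(yh, axis=0)
    return 0.5 * (oracle_ncc(lam1, lam2) + oracle_ncc(kap1, kap2))


def oracle_bce(y, yh, eps=1e-7):
    p = np.clip(yh, eps, 1 - eps)
    total = 0.0
    for yi, pi in zip(y.ravel(), p.ravel()):
        total += yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
    return -total / y.size


def oracle_dice_ce(y, yh, eps=1e-7):
    val = 0.0
    for c in range(1, y.shape[0]):
        num = 2.0 * (y[c] * yh[c]).sum()
        den = y[c].sum() + yh[c].sum()
        val += 1.0 - num / den
    p = np.clip(yh, eps, 1 - eps)
    val += float(-(y * np.log(p)).sum() / y[0].size)
    return val


# ---------------------------------------------------------------------------
# Loss tests
# ---------------------------------------------------------------------------


class TestGradientCorrelation:
    def test_self_correlation_is_one(self):
        y = rng.random((16, 16))
        assert nets.gradient_correlation(y, y) == pytest.approx(1.0)

    def test_affine_invariance(self):
        y = rng.random((16, 16))
        assert nets.gradient_correlation(y, 3.2 * y + 0.7) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert nets.gradient_correlation(a, b) == pytest.approx(
            nets.gradient_correlation(b, a), abs=1e-12)

    def test_matches_bruteforce_formula(self):
        for _ in range(5):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            assert nets.gradient_correlation(a, b) == pytest.approx(
                oracle_gc(a, b), abs=1e-10)

    def test_constant_input_guard(self):
        with pytest.warns(UserWarning):
            val = nets.gradient_correlation(np.full((8, 8), 0.3),
                                            rng.random((8, 8)))
        assert val == 0.0

    def test_gradient_matches_finite_differences(self):
        y, yh = rng.random((12, 12)), rng.random((12, 12))
        _, g = nets.gradient_correlation(y, yh, return_grad=True)
        for i, j in [(0, 0), (5, 7), (11, 11), (3, 0)]:
            eps = 1e-6
            yh[i, j] += eps
            up = nets.gradient_correlation(y, yh)
            yh[i, j] -= 2 * eps
            dn = nets.gradient_correlation(y, yh)
            yh[i, j] += eps
            assert g[i, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


class TestSeparationLoss:
    def test_zero_at_identity(self):
        y = rng.random((16, 16))
        assert nets.separation_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_pair_uses_guard_value(self):
        with pytest.warns(UserWarning):
            val = nets.separation_loss(np.zeros((8, 8)), np.ones((8, 8)))
        assert val == pytest.approx(1.0)  # 0.5 * (MSE=1 + (1 - GC=0))

    def test_minimum_at_identity(self):
        y = rng.random((16, 16))
        shuffled = rng.permutation(y.ravel()).reshape(y.shape)
        assert nets.separation_loss(y, shuffled) > nets.separation_loss(y, y)


class TestBceLoss:
    def test_uniform_half_gives_log_two(self):
        y = np.full((10, 10), 0.5)
        assert nets.bce_loss(y, y) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_perfect_binary_prediction_is_eps_level(self):
        y = (rng.random((12, 12)) > 0.5).astype(float)
        assert nets.bce_loss(y, y) <= 1.1e-7

    def test_matches_bruteforce_formula(self):
        y, yh = rng.random((16, 16)), rng.random((16, 16))
        assert nets.bce_loss(y, yh) == pytest.approx(oracle_bce(y, yh),
                                                     abs=1e-10)


class TestDiceCeLoss:
    @staticmethod
    def _onehot(labels, n=2):
        return np.stack([(labels == c).astype(float) for c in range(n)])

    def test_zero_at_perfect_onehot(self):
        y = self._onehot(rng.integers(0, 2, (16, 16, 16)))
        val = nets.dice_ce_loss(y, y)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_matches_bruteforce_formula(self):
        y = self._onehot(rng.integers(0, 2, (16, 16, 16)))
        logits = rng.normal(size=(2, 16, 16, 16))
        yh = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        assert nets.dice_ce_loss(y, yh) == pytest.approx(
            oracle_dice_ce(y, yh), abs=1e-10)

    def test_uniform_prediction_on_balanced_target(self):
        lab = np.zeros((8, 8, 8), int)
        lab[:4] = 1
        y = self._onehot(lab)
        yh = np.full_like(y, 0.5)
        assert nets.dice_ce_loss(y, yh) == pytest.approx(
            oracle_dice_ce(y, yh), abs=1e-10)

    def test_disjoint_prediction_dice_term(self):
        lab = np.zeros((6, 6, 6), int)
        lab[:3] = 1
        y = self._onehot(lab)
        yh = self._onehot(1 - lab).astype(float)
        val = nets.dice_ce_loss(y, yh)
        # dice term = number of foreground classes (1); every voxel's true
        # class is predicted at the clipping floor, so CE = -log(eps)
        assert val == pytest.approx(1.0 - np.log(1e-7), rel=1e-6)

    def test_unnormalized_prediction_rejected(self):
        y = self._onehot(np.zeros((4, 4, 4), int))
        with pytest.raises(ValueError):
            nets.dice_ce_loss(y, 0.7 * y)


# ---------------------------------------------------------------------------
# Model contracts
# ---------------------------------------------------------------------------


class TestSeparationModel:
    def test_forward_shapes_and_range(self):
        m = nets.build_separation_model(
            nets.separation_config(input_size=64, base_channels=2), seed=0)
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        outs = m.forward(x)
        for side in ("right", "left"):
            assert outs[side].data.shape == (1, 1, 64, 64)
            assert outs[side].data.min() >= 0.0
            assert outs[side].data.max() <= 1.0

    def test_decoder_branches_have_equal_parameter_counts(self):
        m = nets.build_separation_model(
            nets.separation_config(input_size=64, base_channels=2), seed=0)
        count = {"right": 0, "left": 0}
        for name, p in m.params.items():
            for side in count:
                if f"_{side}" in name:
                    count[side] += p.data.size
        assert count["right"] == count["left"] > 0

    def test_one_step_decreases_loss(self):
        m = nets.build_separation_model(
            nets.separation_config(input_size=32, base_channels=2,
                                   n_levels=2), seed=1)
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        t = {"right": rng.random((1, 1, 32, 32)).astype(np.float32),
             "left": rng.random((1, 1, 32, 32)).astype(np.float32)}
        opt = nets.Adam(m.params, 0.01)
        m.zero_grad()
        l0 = nets._loss_and_backward(m, (x,), t, "separation")
        opt.step()
        m.zero_grad()
        l1 = nets._loss_and_backward(m, (x,), t, "separation")
        assert l1 < l0

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            nets.separation_config(input_size=60, n_levels=4)


class TestLandmarkModel:
    def test_output_shape_and_sigmoid_range(self):
        m = nets.build_landmark_model(
            nets.landmark_config(3, input_size=32, base_channels=2,
                                 n_levels=2), 3, seed=0)
        y = m.forward(rng.random((1, 1, 32, 32)).astype(np.float32))
        assert y.data.shape == (1, 3, 32, 32)
        assert y.data.min() >= 0.0 and y.data.max() <= 1.0

    def test_channel_count_contract(self):
        with pytest.raises(ValueError):
            nets.landmark_config(4)

    def test_overfits_single_study(self, small_studies):
        """200 steps on one study halve (at least) the initial BCE."""
        _, _, studies, _ = small_studies
        sample = pp.landmark_samples(studies[:1], "sagittal")[0]
        m = nets.build_landmark_model(
            nets.landmark_config(3, input_size=128, base_channels=4,
                                 learning_rate=1e-3), 3, seed=0)
        opt = nets.Adam(m.params, 1e-3)
        losses = []
        for _ in range(200):
            m.zero_grad()
            losses.append(nets._loss_and_backward(m, sample[0], sample[1],
                                                  "landmarks"))
            opt.step()
        assert losses[-1] < 0.5 * losses[0]


class TestReconstructionModel:
    def test_cube_edge_follows_quarter_rule(self):
        cfg = nets.reconstruction_config(input_size=128, base_channels=2)
        m = nets.build_reconstruction_model(cfg, seed=0)
        assert m.cube == 32
        cfg512 = nets.reconstruction_config(input_size=512, base_channels=2)
        assert nets.ReconstructionModel(cfg512, seed=0).cube == 128

    def test_softmax_normalized_output(self):
        m = nets.build_reconstruction_model(
            nets.reconstruction_config(input_size=32, base_channels=2), seed=0)
        f = rng.random((1, 1, 32, 32)).astype(np.float32)
        s = rng.random((1, 1, 32, 32)).astype(np.float32)
        out = m.forward(f, s)
        assert out.data.shape == (1, 2, 8, 8, 8)
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-6)

    def test_unequal_input_sizes_rejected(self):
        m = nets.build_reconstruction_model(
            nets.reconstruction_config(input_size=32, base_channels=2), seed=0)
        with pytest.raises(ValueError):
            m.forward(rng.random((1, 1, 32, 32)), rng.random((1, 1, 16, 16)))

    def test_translation_consistency_four_px_one_voxel(self):
        """Shifting both inputs 4 px shifts the output field by 1 voxel.

        Exact away from the borders (outside the padded receptive field);
        checked on the softmax probabilities, which are shift-equivariant
        there to float precision.
        """
        m = nets.build_reconstruction_model(
            nets.reconstruction_config(input_size=128, base_channels=2),
            seed=3)
        f = rng.random((1, 1, 128, 128)).astype(np.float32)
        s = rng.random((1, 1, 128, 128)).astype(np.float32)
        a = m.forward(f, s).data[0]
        mrg = 8
        # frontal u maps to the X axis (last) of the (Y, V, X) cube.
        # 8 px = 2 voxels matches the 3D pooling stride: exact equivariance
        b8 = m.forward(np.roll(f, 8, axis=3), s).data[0]
        assert np.allclose(np.roll(a, 2, axis=3)[..., mrg:-mrg],
                           b8[..., mrg:-mrg], atol=1e-6)
        # 4 px = 1 voxel straddles the pooled grid: equivariant up to the
        # pooling phase, so the argmax volumes agree almost everywhere
        b4 = m.forward(np.roll(f, 4, axis=3), s).data[0]
        agree = (np.roll(a, 1, axis=3).argmax(0)[..., mrg:-mrg]
                 == b4.argmax(0)[..., mrg:-mrg]).mean()
        assert agree > 0.95


class TestExtractLandmark:
    def test_recovers_synthetic_gaussian_center(self):
        from osteoplan import drr
        for u0, v0 in [(20.4, 33.7), (8.0, 8.0), (50.6, 12.2)]:
            hm = drr.make_heatmaps({"x": (u0, v0)}, 4.0, (64, 64))
            u, v = nets.extract_landmark(hm.channel("x"))
            assert abs(u - u0) <= 0.5 and abs(v - v0) <= 0.5

    def test_single_pixel_peak(self):
        ch = np.zeros((16, 16))
        ch[9, 4] = 0.7
        u, v = nets.extract_landmark(ch)
        assert (u, v) == (4.0, 9.0)

    def test_tie_breaks_to_smallest_v_then_u(self):
        ch = np.zeros((16, 16))
        ch[3, 10] = 1.0
        ch[12, 2] = 1.0
        u, v = nets.extract_landmark(ch)
        assert v < 10  # picked the smaller-v peak

    def test_all_zero_returns_sentinel(self):
        assert nets.extract_landmark(np.zeros((8, 8))) is None


class TestTraining:
    def _tiny_dataset(self):
        xs = [rng.random((1, 1, 16, 16)).astype(np.float32) for _ in range(6)]
        ts = [np.clip(np.concatenate([x] * 3, axis=1)
                      + 0.05 * rng.standard_normal((1, 3, 16, 16)), 0, 1
                      ).astype(np.float32) for x in xs]
        samples = [((x,), t) for x, t in zip(xs, ts)]
        return {"train": samples[:4], "val": samples[4:]}

    def test_loss_trend_and_seed_determinism(self):
        cfg = nets.landmark_config(3, input_size=16, base_channels=2,
                                   n_levels=2, epochs=5, learning_rate=1e-3,
                                   batch_size=2)
        data = self._tiny_dataset()
        m1 = nets.build_landmark_model(cfg, 3, seed=7)
        m1, h1 = nets.train(m1, data, cfg, seed=9)
        assert h1.train[-1] < h1.train[0]
        m2 = nets.build_landmark_model(cfg, 3, seed=7)
        m2, h2 = nets.train(m2, data, cfg, seed=9)
        assert h1.train[-1] == pytest.approx(h2.train[-1], abs=1e-6)
        assert h1.best_epoch == h2.best_epoch

    def test_empty_split_rejected(self):
        cfg = nets.landmark_config(3, input_size=16, n_levels=2)
        m = nets.build_landmark_model(cfg, 3)
        with pytest.raises(ValueError):
            nets.train(m, {"train": []}, cfg)

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = nets.landmark_config(3, input_size=16, base_channels=2,
                                   n_levels=2)
        m = nets.build_landmark_model(cfg, 3, seed=0)
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        before = m.forward(x).data
        m.save(tmp_path / "ck.npz")
        m2 = nets.build_landmark_model(cfg, 3, seed=99)
        m2.load(tmp_path / "ck.npz")
        assert np.allclose(m2.forward(x).data, before)


class TestPredictStudy:
    def test_outputs_binary_and_sides_independent(self, small_studies):
        cfg, _, studies, _ = small_studies
        spec = cfg.recon_spec()
        rcfg = nets.reconstruction_config(input_size=128, base_channels=2)
        recon = nets.build_reconstruction_model(rcfg, seed=0)
        models = {"recon_left": recon, "recon_right": recon}
        res = nets.predict_study(models, studies[0], spec,
                                 separation_mode="oracle",
                                 crop_landmarks="truth")
        for side in ("left", "right"):
            assert set(np.unique(res.volumes[side].grid)) <= {0, 1}
        only_right = nets.predict_study({"recon_right": recon}, studies[0],
                                        spec, separation_mode="oracle",
                                        crop_landmarks="truth")
        assert "left" not in only_right.volumes
        assert np.array_equal(only_right.volumes["right"].grid,
                              res.volumes["right"].grid)

    def test_missing_separation_model_raises(self, small_studies):
        _, _, studies, _ = small_studies
        with pytest.raises(KeyError):
            nets.predict_study({}, studies[0], separation_mode="network")
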