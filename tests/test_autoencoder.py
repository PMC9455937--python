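"""Convolutional autoencoder: shape contracts, decoder oracle, gradients,
training behavior."""

import numpy as np
import pytest

import motionmend as mm
from motionmend._nnops import (conv_adjoint, conv_grad_w, conv_same, maxpool2,
                               maxpool2_grad, unpool2, unpool2_adjoint)
from motionmend.autoencoder import AEParams, LatentCode, TrainHyper, decode_array


def random_params(rng, n_filters=8, dims=12, width=5):
    return AEParams(
        W=rng.normal(0, 0.1, (n_filters, dims, width)),
        b=rng.normal(0, 0.1, n_filters),
        norm_mean=rng.normal(0, 1.0, dims),
        norm_std=np.full(dims, 2.0),
    )


def brute_decode(h, params):
    """Direct-summation transposed convolution (independent oracle)."""
    F, D, w = params.W.shape
    c = w // 2
    m = h.n_frames
    g = np.repeat(h.values.T, 2, axis=0)[:m] - params.b
    wt = params.W[:, :, ::-1]  # reflected along the frame axis
    out = np.zeros((m, D))
    for t in range(m):
        for d in range(D):
            acc = 0.0
            for f in range(F):
                for tau in range(w):
                    tt = t + tau - c
                    if 0 <= tt < m:
                        acc += wt[f, d, tau] * g[tt, f]
            out[t, d] = acc
    return out * params.norm_std + params.norm_mean


class TestShapes:
    def test_full_size_latent_shape(self, skel):
        # 240 frames x 22 joints (66 dims) -> 256 x 120 latent
        rng = np.random.default_rng(0)
        clip, _ = mm.generate_motion(skel, 240, 60.0, mm.GaitParams(seed=0))
        clip = mm.add_phantom_joint(clip)
        params = AEParams(W=rng.normal(0, 0.01, (256, 66, 25)),
                          b=np.zeros(256), norm_mean=np.zeros(66),
                          norm_std=np.ones(66))
        latent = mm.encode(clip, params)
        assert latent.values.shape == (256, 120)
        out = mm.decode(latent, params)
        assert out.shape == (240, 22, 3)

    def test_latent_non_negative(self, skel):
        rng = np.random.default_rng(1)
        clip, _ = mm.generate_motion(skel, 64, 60.0, mm.GaitParams(seed=1))
        params = random_params(rng, dims=3 * skel.n_joints)
        latent = mm.encode(clip, params)
        assert (latent.values >= 0).all()

    def test_zero_input_zero_bias_zero_latent(self):
        rng = np.random.default_rng(2)
        params = random_params(rng)
        params.b[:] = 0.0
        x = np.tile(params.norm_mean, (20, 1))  # normalizes to exactly zero
        latent = mm.encode(x, params)
        assert np.all(latent.values == 0.0)

    def test_dimension_mismatch_rejected(self, skel):
        rng = np.random.default_rng(3)
        clip, _ = mm.generate_motion(skel, 40, 60.0, mm.GaitParams(seed=2))
        params = random_params(rng, dims=12)
        with pytest.raises(ValueError):
            mm.encode(clip, params)

    def test_short_clip_rejected(self):
        rng = np.random.default_rng(4)
        params = random_params(rng, width=5)
        with pytest.raises(ValueError):
            mm.encode(np.zeros((3, 12)), params)


class TestDecoder:
    @pytest.mark.parametrize("m", [10, 11])
    def test_matches_brute_force_oracle(self, m):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        h = LatentCode(np.abs(rng.normal(size=(8, (m + 1) // 2))), m)
        np.testing.assert_allclose(decode_array(h, params),
                                   brute_decode(h, params), atol=1e-9)

    def test_inverse_pool_replicates_single_value(self):
        h = np.array([[3.0]])
        np.testing.assert_array_equal(unpool2(h.T, 2), [[3.0], [3.0]])

    def test_decode_affine_in_latent(self):
        """decode(aH1 + bH2) = a*decode(H1) + b*decode(H2) + (1-a-b)*decode(0)."""
        rng = np.random.default_rng(6)
        params = random_params(rng)
        m = 12
        h1 = np.abs(rng.normal(size=(8, 6)))
        h2 = np.abs(rng.normal(size=(8, 6)))
        a, b = 0.3, 0.5
        mix = decode_array(LatentCode(a * h1 + b * h2, m), params)
        d1 = decode_array(LatentCode(h1, m), params)
        d2 = decode_array(LatentCode(h2, m), params)
        d0 = decode_array(LatentCode(np.zeros((8, 6)), m), params)
        np.testing.assert_allclose(mix, a * d1 + b * d2 + (1 - a - b) * d0,
                                   atol=1e-9)

    def test_pool_relu_commute(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(2, 16, 5))
        a, _ = maxpool2(np.maximum(z, 0.0))
        b, _ = maxpool2(z)
        np.testing.assert_array_equal(a, np.maximum(b, 0.0))


class TestGradients:
    def test_training_gradients_match_numerics(self):
        """Analytic adjoints of the full forward pass vs central differences."""
        rng = np.random.default_rng(8)
        B, M, D, F, w = 2, 9, 4, 3, 5
        x = rng.normal(size=(B, M, D))
        W = rng.normal(size=(F, D, w))
        b = rng.normal(size=F)

        def loss(W_, b_):
            z = conv_same(x, W_) + b_
            p, _ = maxpool2(z)
            g = unpool2(np.maximum(p, 0.0), M)
            return np.sum(conv_adjoint(g - b_, W_) ** 2)

        z = conv_same(x, W) + b
        p, arg = maxpool2(z)
        g = unpool2(np.maximum(p, 0.0), M)
        gb = g - b
        yn = conv_adjoint(gb, W)
        dyn = 2.0 * yn
        dW = conv_grad_w(dyn, gb, w)
        dgb = conv_same(dyn, W)
        db = -dgb.sum(axis=(0, 1))
        dh = unpool2_adjoint(dgb)
        dp = dh * (p > 0)
        dz = maxpool2_grad(dp, arg, M)
        dW += conv_grad_w(x, dz, w)
        db += dz.sum(axis=(0, 1))

        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (2, 3, 4)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            num = (loss(Wp, b) - loss(Wm, b)) / (2 * eps)
            assert dW[idx] == pytest.approx(num, rel=1e-4)
        for i in range(3):
            bp, bm = b.copy(), b.copy()
            bp[i] += eps
            bm[i] -= eps
            num = (loss(W, bp) - loss(W, bm)) / (2 * eps)
            assert db[i] == pytest.approx(num, rel=1e-4)


class TestTraining:
    def test_deterministic_given_seed(self, skel):
        corpus = mm.generate_corpus(skel, 3, 60, seed=1)
        hyper = TrainHyper(epochs=2, seed=9)
        p1, _ = mm.train(corpus, hyper, n_filters=8, width=5)
        p2, _ = mm.train(corpus, hyper, n_filters=8, width=5)
        assert np.array_equal(p1.W, p2.W) and np.array_equal(p1.b, p2.b)

    def test_loss_decreases(self, trained):
        _, losses = trained
        assert losses[-1] < losses[0]

    def test_overfits_single_repeated_clip(self, skel):
        clip, _ = mm.generate_motion(skel, 120, 60.0, mm.GaitParams(seed=3))
        corpus = [clip] * 4
        hyper = TrainHyper(alpha=0.0, dropout_rate=0.0, epochs=400,
                           learning_rate=0.002, batch_size=4, seed=0)
        _, losses = mm.train(corpus, hyper, n_filters=32, width=15)
        assert losses[-1] < 0.1 * losses[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            mm.train([], TrainHyper(epochs=1))

    def test_model_save_load_round_trip(self, skel, tmp_path):
        corpus = mm.generate_corpus(skel, 2, 60, seed=2)
        params, _ = mm.train(corpus, TrainHyper(epochs=1, seed=1),
                             n_filters=4, width=5)
        path = tmp_path / "model.npz"
        params.save(path)
        back = AEParams.load(path)
        assert np.array_equal(back.W, params.W)
        assert back.joint_names == params.joint_names


class TestReconstruction:
    def test_output_shape_equals_input(self, trained, bench_cfg):
        params, _ = trained
        from motionmend.experiment import make_test_clips, _to_local
        clip, _ = _to_local(make_test_clips(bench_cfg)[0])
        rec = mm.reconstruct(clip, params)
        assert rec.positions.shape == clip.positions.shape

    def test_reconstruction_beats_corruption(self, trained, bench_cfg):
        """Manifold denoising: reconstruction error of a held-out clip is
        below the raw error of the same clip corrupted at sigma = 10."""
        params, _ = trained
        from motionmend.experiment import make_test_clips, _to_local
        clean, _ = _to_local(make_test_clips(bench_cfg)[0])
        noisy = mm.corrupt_awgn(clean, 10.0, seed=1)
        rec = mm.reconstruct(noisy, params)
        assert mm.joint_rmse(rec, clean)[1] < mm.joint_rmse(noisy, clean)[1]

    def test_in_manifold_reconstructs_better_than_noise(self, trained,
                                                        bench_cfg):
        params, _ = trained
        from motionmend.experiment import make_test_clips, _to_local
        clean, _ = _to_local(make_test_clips(bench_cfg)[0])
        rng = np.random.default_rng(12)
        pure_noise = clean.copy()
        pure_noise.positions = rng.normal(0, 30.0, clean.positions.shape)
        res_motion = mm.joint_rmse(mm.reconstruct(clean, params), clean)[1]
        res_noise = mm.joint_rmse(mm.reconstruct(pure_noise, params),
                                  pure_noise)[1]
        assert res_motion < res_noise


class TestEstimator:
    def test_fit_transform_api(self, skel):
        corpus = mm.generate_corpus(skel, 3, 60, seed=4)
        ae = mm.MotionAutoencoder(n_filters=8, width=5, epochs=2, seed=0)
        ae.fit(corpus)
        assert ae.W_.shape == (8, 3 * skel.n_joints, 5)
        out = ae.transform(corpus[0])
        assert out.positions.shape == corpus[0].positions.shape
        assert ae.get_params()["n_filters"] == 8
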