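import numpy as np
import pytest

from platemorph import segmentation as seg
from platemorph.phantom import PhantomSpec, RenderSpec, make_platelet_mask, render_image
from platemorph.segmentation import nn
from platemorph.stats import pixel_confusion
from platemorph.types import DegenerateInputError, GrayImage, ParameterError


class TestNormalizeMinmax:
    def test_formula(self):
        img = GrayImage(np.array([[2.0, 4.0, 6.0], [2.0, 4.0, 6.0]]))
        out = seg.normalize_minmax(img)
        assert np.allclose(out.pixels[0], [0.0, 0.5, 1.0])

    def test_identity_on_unit_range(self):
        pix = np.linspace(0, 1, 64).reshape(8, 8)
        out = seg.normalize_minmax(GrayImage(pix))
        assert np.allclose(out.pixels, pix)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        pix = rng.uniform(0, 1, (16, 16))
        a = seg.normalize_minmax(GrayImage(pix))
        b = seg.normalize_minmax(GrayImage(3.5 * pix + 11.0))
        assert np.allclose(a.pixels, b.pixels)

    def test_exact_range(self):
        rng = np.random.default_rng(2)
        out = seg.normalize_minmax(GrayImage(rng.uniform(3, 9, (20, 20))))
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            seg.normalize_minmax(GrayImage(np.full((8, 8), 4.0)))


class TestPadReflect:
    def test_native_resolution_to_network_input(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.uniform(0, 1, (1608, 1608)))
        padded = seg.pad_reflect(img, 2048)
        assert padded.shape == (2048, 2048)
        # centred: 220-pixel borders
        assert np.array_equal(padded.pixels[220:-220, 220:-220], img.pixels)

    def test_borders_are_reflections(self):
        img = GrayImage(np.arange(16.0).reshape(4, 4))
        padded = seg.pad_reflect(img, 8)
        # pad (top=2): row 2 holds the original row 0; row 1 mirrors row 1
        assert np.array_equal(padded.pixels[1, 2:6], img.pixels[1])
        assert np.array_equal(padded.pixels[0, 2:6], img.pixels[2])

    def test_already_at_target_unchanged(self):
        rng = np.random.default_rng(3)
        img = GrayImage(rng.uniform(0, 1, (32, 32)))
        assert np.array_equal(seg.pad_reflect(img, 32).pixels, img.pixels)

    @pytest.mark.parametrize("shape", [(5, 9), (16, 16), (31, 7), (1, 3)])
    def test_round_trip_bit_exact(self, shape):
        rng = np.random.default_rng(4)
        pix = rng.uniform(0, 1, shape)
        padded = seg.pad_reflect(GrayImage(pix), 32)
        assert padded.shape == (32, 32)
        assert np.array_equal(seg.crop_center(padded.pixels, shape), pix)

    def test_target_too_small_rejected(self):
        with pytest.raises(ParameterError):
            seg.pad_reflect(GrayImage(np.zeros((64, 64))), 32)


class TestAugmentPair:
    @pytest.fixture
    def pair(self):
        mask, _ = make_platelet_mask(PhantomSpec(body_semi_axes=(10.0, 6.0)))
        img = render_image(mask, RenderSpec(halo_amplitude=0.0, blur_sigma=0.0,
                                            noise_sd=0.0))
        return seg.TrainPair(img, mask)

    def test_identity_draw(self, pair):
        rng = np.random.default_rng(0)
        out = seg.augment_pair(pair, rng, {"rotation": False, "flipping": False,
                                           "resizing": False})
        assert np.array_equal(out.phase.pixels, pair.phase.pixels)
        assert np.array_equal(out.truth.pixels, pair.truth.pixels)

    def test_same_transform_for_image_and_mask(self, pair):
        rng = np.random.default_rng(7)
        out = seg.augment_pair(pair, rng, {"rotation": True, "flipping": True,
                                           "resizing": False})
        # the dark body must coincide exactly with the transformed mask
        body = out.phase.pixels < 0.5
        assert (body == out.truth.pixels).all()

    def test_mask_stays_boolean_under_resizing(self, pair):
        rng = np.random.default_rng(8)
        out = seg.augment_pair(pair, rng, {"rotation": False, "flipping": False,
                                           "resizing": True})
        assert out.truth.pixels.dtype == bool
        assert out.truth.shape == pair.truth.shape

    def test_flip_moves_gradient(self):
        pix = np.tile(np.linspace(0, 1, 16), (16, 1))
        img = GrayImage(pix)
        from platemorph.types import BinaryMask
        pair = seg.TrainPair(img, BinaryMask(pix > 0.5))
        flipped = np.array([seg.augment_pair(
            pair, np.random.default_rng(s),
            {"rotation": False, "flipping": True, "resizing": False}
        ).phase.pixels[0, 0] for s in range(20)])
        assert (flipped > 0.9).any() and (flipped < 0.1).any()


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self):
        # seed chosen so no pre-activation sits near a ReLU kink and no
        # pooling window has a tie; finite differences are meaningless at
        # those nondifferentiable points, so the test asserts the
        # preconditions before trusting the comparison.
        rng = np.random.default_rng(3)
        depth = 2
        params = nn.init_params(depth, base_filters=2, rng=rng)
        for k in params:
            params[k] = rng.normal(0.0, 0.5, size=params[k].shape)
        x = rng.normal(size=(1, 1, 4, 4))
        t = (rng.uniform(size=(1, 1, 4, 4)) > 0.5).astype(float)

        cache = {}
        logits = nn.forward(params, x, depth, cache)
        for i in range(depth):
            _, z1, _, z2, a2 = cache["acts"][f"enc{i}"]
            assert min(np.abs(z1).min(), np.abs(z2).min()) > 1e-4
            if i < depth - 1:
                win = a2.reshape(*a2.shape[:2], a2.shape[2] // 2, 2,
                                 a2.shape[3] // 2, 2)
                win = win.transpose(0, 1, 2, 4, 3, 5).reshape(-1, 4)
                # the max must be attained uniquely (ties among smaller
                # entries are harmless for the gradient)
                assert all((w == w.max()).sum() == 1 for w in win)
        _, dlogits = nn.bce_loss(logits, t)
        grads = nn.backward(params, cache, dlogits, depth)

        eps = 1e-6
        for name, w in params.items():
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                w[idx] += eps
                lp, _ = nn.bce_loss(nn.forward(params, x, depth), t)
                w[idx] -= 2 * eps
                lm, _ = nn.bce_loss(nn.forward(params, x, depth), t)
                w[idx] += eps
                numeric = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7), name

    def test_maxpool_routes_gradient_to_argmax(self):
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        y, mask = nn.maxpool2(x)
        assert y[0, 0, 0, 0] == 4.0
        dx = nn.maxpool2_backward(np.ones((1, 1, 1, 1)), mask)
        assert dx[0, 0].tolist() == [[0.0, 0.0], [0.0, 1.0]]


def _tiny_pairs(n, canvas=32, seed=0):
    rng = np.random.default_rng(seed)
    render = RenderSpec(mode="phase_contrast", halo_amplitude=0.3,
                        blur_sigma=1.0, noise_sd=0.03)
    pairs = []
    for i in range(n):
        a = rng.uniform(6, 9)
        b = rng.uniform(5, a)
        spec = PhantomSpec(body_semi_axes=(a, b),
                           orientation=rng.uniform(0, np.pi), seed=i)
        mask, _ = make_platelet_mask(spec, canvas_shape=(canvas, canvas))
        pairs.append(seg.TrainPair(
            render_image(mask, render, seed=100 + i), mask))
    return pairs


class TestMemorization:
    def test_prediction_on_training_images_reproduces_truth(self):
        pairs = _tiny_pairs(16, seed=1)
        cfg = seg.NetConfig(input_size=32, depth=2, base_filters=8,
                            max_epochs=80, learning_rate=3e-3, seed=0,
                            patience=80)
        model = seg.build_and_train(pairs, cfg)
        tp = fp = fn = 0
        for pair in pairs:
            pred = seg.predict(model, pair.phase)
            c = pixel_confusion(pred, pair.truth)
            tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
        assert tp / (tp + fp + fn) >= 0.96


class TestTraining:
    def test_returned_snapshot_is_argmin_of_validation_loss(self):
        pairs = _tiny_pairs(8)
        cfg = seg.NetConfig(input_size=32, depth=2, base_filters=4,
                            max_epochs=6, seed=0, patience=0)
        model = seg.build_and_train(pairs, cfg)
        assert model.val_loss[model.best_epoch] == min(model.val_loss)

    def test_deterministic_loss_curves(self):
        pairs = _tiny_pairs(6)
        cfg = seg.NetConfig(input_size=32, depth=2, base_filters=4,
                            max_epochs=3, seed=5, patience=0)
        m1 = seg.build_and_train(pairs, cfg)
        m2 = seg.build_and_train(pairs, cfg)
        assert m1.train_loss == m2.train_loss
        assert m1.val_loss == m2.val_loss

    def test_non_divisible_input_size_rejected(self):
        with pytest.raises(ParameterError):
            seg.NetConfig(input_size=33, depth=3)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ParameterError):
            seg.build_and_train(_tiny_pairs(1), seg.NetConfig(input_size=32))

    def test_save_load_round_trip(self, tmp_path):
        pairs = _tiny_pairs(4)
        cfg = seg.NetConfig(input_size=32, depth=2, base_filters=4,
                            max_epochs=2, seed=0)
        model = seg.build_and_train(pairs, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = seg.TrainedModel.load(path)
        assert loaded.config == model.config
        img = pairs[0].phase
        assert np.array_equal(seg.predict(loaded, img).pixels,
                              seg.predict(model, img).pixels)


@pytest.fixture(scope="module")
def predict_model():
    from platemorph.benchmark import phantom_render_pairs

    pairs = phantom_render_pairs(16, seed=1, canvas=32)
    cfg = seg.NetConfig(input_size=32, depth=2, base_filters=8,
                        max_epochs=80, learning_rate=3e-3, seed=0,
                        patience=80)
    return seg.build_and_train(pairs, cfg)


class TestPredict:

    def test_output_dimensions_match_input(self, predict_model):
        model = predict_model
        rng = np.random.default_rng(0)
        img = GrayImage(rng.uniform(0, 1, (25, 29)))
        assert seg.predict(model, img).shape == (25, 29)

    def test_empty_field_near_empty_mask(self, predict_model):
        model = predict_model
        rng = np.random.default_rng(1)
        img = GrayImage(0.7 + rng.normal(0, 0.03, (32, 32)))
        mask = seg.predict(model, img)
        assert mask.pixels.mean() < 0.001

    def test_too_large_image_rejected(self, predict_model):
        model = predict_model
        with pytest.raises(ParameterError):
            seg.predict(model, GrayImage(np.zeros((64, 64))))
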