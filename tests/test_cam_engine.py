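"""CAM weighting schemes, their closed-form oracles, and upsampling."""

import numpy as np
import pytest

import camroad as cr
from camroad import nn
from camroad.cam_engine import ForwardOracle, channel_weights
from tests.conftest import build_gap_model, build_two_logit_model

RNG = np.random.default_rng(11)


def first_ref(model):
    return cr.enumerate_target_layers(model)[0]


# ---------------------------------------------------------------------------
# closed-form oracles


def test_gradcam_on_gap_model_is_proportional_to_activation():
    """y = GAP(A): the gradient is constant, so the map is alpha * A with alpha > 0."""
    model = build_gap_model()
    x = RNG.uniform(0.1, 1.0, size=(1, 1, 8, 8))
    frame = cr.compute_cam(model, x, first_ref(model), 0, "gradcam")
    ratio = frame.pre_relu_map / x[0, 0]
    np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)
    assert ratio.flat[0] > 0


def test_everywhere_negative_activations_rectify_to_zero():
    model = build_gap_model()
    x = -RNG.uniform(0.1, 1.0, size=(1, 1, 8, 8))  # negative image -> negative A
    frame = cr.compute_cam(model, x, first_ref(model), 0, "gradcam")
    np.testing.assert_array_equal(frame.raw_map, 0.0)


def test_gradcam_weight_equals_constant_gradient():
    g = np.full((2, 4, 4), 0.25)
    g[1] = -0.5
    kind, alpha = channel_weights(cr.get_scheme("gradcam"), RNG.normal(size=(2, 4, 4)), g)
    assert kind == "channel"
    np.testing.assert_allclose(alpha, [0.25, -0.5])


def test_elementwise_scheme_formulas_on_hand_case():
    a = np.array([[[1.0, -1.0], [2.0, 0.0]], [[0.0, 1.0], [1.0, 1.0]]])
    g = np.array([[[1.0, 1.0], [-1.0, 0.0]], [[2.0, -1.0], [0.0, 1.0]]])
    _, hires = channel_weights(cr.get_scheme("hirescam"), a, g)
    np.testing.assert_allclose(hires, [[1.0, -2.0], [-2.0, 1.0]])
    _, elem = channel_weights(cr.get_scheme("gradcam_elementwise"), a, g)
    np.testing.assert_allclose(elem, [[1.0, 0.0], [0.0, 1.0]])
    kind, w = channel_weights(cr.get_scheme("layercam"), a, g)
    assert kind == "pixel"
    np.testing.assert_allclose((w * a).sum(axis=0), [[1.0, -1.0], [0.0, 1.0]])


def test_eigencam_recovers_rank_one_structure():
    u = RNG.normal(size=5)
    v = RNG.normal(size=12)
    a = np.outer(u, v).reshape(5, 3, 4)
    _, m = channel_weights(cr.get_scheme("eigencam"), a)
    flat = m.reshape(-1)
    cos = abs(flat @ v) / (np.linalg.norm(flat) * np.linalg.norm(v))
    assert cos == pytest.approx(1.0, abs=1e-10)
    assert flat.sum() >= 0


def test_eigencam_is_class_invariant():
    model = build_two_logit_model()
    x = RNG.uniform(size=(1, 1, 8, 8))
    ref = first_ref(model)
    f0 = cr.compute_cam(model, x, ref, 0, "eigencam")
    f1 = cr.compute_cam(model, x, ref, 1, "eigencam")
    np.testing.assert_array_equal(f0.raw_map, f1.raw_map)


def test_gradcam_is_class_discriminative_on_disjoint_evidence():
    model = build_two_logit_model(size=8)
    x = RNG.uniform(0.2, 1.0, size=(1, 1, 8, 8))
    refs = cr.enumerate_target_layers(model)
    halves = next(r for r in refs if r.name == "halves")
    m0 = cr.compute_cam(model, x, halves, 0, "gradcam").raw_map
    m1 = cr.compute_cam(model, x, halves, 1, "gradcam").raw_map
    assert np.unravel_index(m0.argmax(), m0.shape)[1] < 4  # class 0 -> left half
    assert np.unravel_index(m1.argmax(), m1.shape)[1] >= 4  # class 1 -> right half


@pytest.mark.parametrize("scheme", ["gradcam", "hirescam", "xgradcam"])
def test_linear_schemes_are_scale_covariant(scheme):
    model = build_gap_model()
    x = RNG.uniform(0.1, 1.0, size=(1, 1, 8, 8))
    ref = first_ref(model)
    base = cr.compute_cam(model, x, ref, 0, scheme).pre_relu_map
    scaled = cr.compute_cam(model, 3.0 * x, ref, 0, scheme).pre_relu_map
    np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-8)


def test_gradcampp_and_eigengradcam_produce_finite_maps(trained_model, lesion_samples):
    refs = [r for r in cr.enumerate_target_layers(trained_model) if r.shape_class == "spatial2d"]
    img = lesion_samples[0].image[None]
    for scheme in ("gradcampp", "eigengradcam"):
        frame = cr.compute_cam(trained_model, img, refs[-1], 1, scheme)
        assert np.all(np.isfinite(frame.raw_map))
        assert frame.raw_map.shape == (64, 64)


# ---------------------------------------------------------------------------
# perturbation schemes


def test_ablationcam_zero_weight_channel_scores_zero():
    """A channel the head ignores leaves the score unchanged when ablated."""
    conv = nn.Conv2d(1, 2, 1, bias=True)
    conv.params["weight"][:] = 1.0
    conv.params["bias"][:] = 0.0
    head = nn.Linear(2, 1, bias=True)
    head.params["weight"][:] = np.array([[1.0, 0.0]])
    head.params["bias"][:] = 0.0
    model = nn.Sequential(
        [("conv", conv), ("gap", nn.GlobalAvgPool()), ("flat", nn.Flatten()), ("head", head)],
        input_shape=(1, 4, 4))
    x = RNG.uniform(0.5, 1.0, size=(1, 1, 4, 4))
    ref = first_ref(model)
    acts = cr.capture(model, x, [ref], target=0)
    oracle = ForwardOracle(model, x, ref, acts.activation(ref), 0)
    _, alpha = channel_weights(cr.get_scheme("ablationcam"), acts.activation(ref)[0],
                               oracle=oracle)
    assert alpha[1] == pytest.approx(0.0, abs=1e-9)
    assert alpha[0] > 0.5  # ablating the used channel removes the whole score


def test_scorecam_weights_are_a_distribution(trained_model, lesion_samples):
    refs = [r for r in cr.enumerate_target_layers(trained_model) if r.shape_class == "spatial2d"]
    img = lesion_samples[0].image[None]
    ref = refs[-1]
    acts = cr.capture(trained_model, img, [ref], target=1)
    oracle = ForwardOracle(trained_model, img, ref, acts.activation(ref), 1)
    kind, alpha = channel_weights(cr.get_scheme("scorecam"), acts.activation(ref)[0],
                                  oracle=oracle)
    assert kind == "channel"
    assert alpha.sum() == pytest.approx(1.0)
    assert (alpha >= 0).all()


def test_scorecam_all_zero_activations_yield_zero_weights():
    a = np.zeros((3, 4, 4))
    model = build_gap_model()
    ref = first_ref(model)
    oracle = ForwardOracle(model, np.zeros((1, 1, 8, 8)), ref, a[None], 0)
    _, alpha = channel_weights(cr.get_scheme("scorecam"), a, oracle=oracle)
    np.testing.assert_array_equal(alpha, 0.0)


# ---------------------------------------------------------------------------
# randomcam


def test_randomcam_weights_bounded_and_seed_reproducible():
    a = RNG.uniform(size=(16, 4, 4))
    _, w1 = channel_weights(cr.get_scheme("randomcam", rng_seed=5), a)
    _, w2 = channel_weights(cr.get_scheme("randomcam", rng_seed=5), a)
    _, w3 = channel_weights(cr.get_scheme("randomcam", rng_seed=6), a)
    assert np.all(w1 >= -1.0) and np.all(w1 <= 1.0)
    np.testing.assert_array_equal(w1, w2)
    assert not np.array_equal(w1, w3)


def test_randomcam_maps_reproducible_per_seed(trained_model, lesion_samples):
    ref = [r for r in cr.enumerate_target_layers(trained_model)
           if r.shape_class == "spatial2d"][-1]
    img = lesion_samples[0].image[None]
    a = cr.compute_cam(trained_model, img, ref, 1, cr.get_scheme("randomcam", rng_seed=3))
    b = cr.compute_cam(trained_model, img, ref, 1, cr.get_scheme("randomcam", rng_seed=3))
    c = cr.compute_cam(trained_model, img, ref, 1, cr.get_scheme("randomcam", rng_seed=4))
    np.testing.assert_array_equal(a.raw_map, b.raw_map)
    assert not np.array_equal(a.raw_map, c.raw_map)


# ---------------------------------------------------------------------------
# refusals and errors


def test_vector1d_layer_is_refused(trained_model, lesion_samples):
    refs = cr.enumerate_target_layers(trained_model)
    head = refs[-1]
    assert head.shape_class == "vector1d"
    with pytest.raises(ValueError, match="filtered out"):
        cr.compute_cam(trained_model, lesion_samples[0].image[None], head, 1, "gradcam")


def test_gradient_scheme_on_gradient_free_layer_errors():
    model = nn.Sequential(
        [("conv", nn.Conv2d(1, 1, 3, padding=1, rng=RNG)), ("stop", nn.StopGradient()),
         ("gap", nn.GlobalAvgPool()), ("flat", nn.Flatten()),
         ("head", nn.Linear(1, 1, rng=RNG))],
        input_shape=(1, 4, 4))
    ref = first_ref(model)
    with pytest.raises(ValueError, match="no gradient path"):
        cr.compute_cam(model, np.ones((1, 1, 4, 4)), ref, 0, "gradcam")


def test_unknown_scheme_lists_supported_names():
    with pytest.raises(KeyError, match="gradcam"):
        cr.get_scheme("nope")


# ---------------------------------------------------------------------------
# upsampling


def test_upsample_constant_extension():
    out = cr.upsample(np.array([[3.5]]), (6, 7))
    np.testing.assert_array_equal(out, np.full((6, 7), 3.5))


def test_upsample_2x2_to_4x4_closed_form():
    m = np.array([[0.0, 3.0], [6.0, 9.0]])
    out = cr.upsample(m, (4, 4))
    # corner alignment preserves the four original values at the corners
    np.testing.assert_allclose([out[0, 0], out[0, 3], out[3, 0], out[3, 3]], [0, 3, 6, 9])
    # interior follows the bilinear weights on the 1/3-spaced grid
    np.testing.assert_allclose(out[0], [0.0, 1.0, 2.0, 3.0])
    np.testing.assert_allclose(out[:, 0], [0.0, 2.0, 4.0, 6.0])
    np.testing.assert_allclose(out[1, 1], 3.0)


def test_upsample_same_shape_is_identity():
    m = RNG.normal(size=(5, 7))
    np.testing.assert_array_equal(cr.upsample(m, (5, 7)), m)


def test_upsample_rejects_zero_size_target():
    with pytest.raises(ValueError):
        cr.upsample(np.ones((2, 2)), (0, 4))
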