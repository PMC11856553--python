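"""Attribution methods: closed-form oracles, equivalences, invariants."""

import numpy as np
import pytest

from xaiseg import (OcclusionConfig, feature_ablation, grad_cam,
                    guided_backprop, guided_grad_cam, input_x_gradient,
                    layer_gradient_x_activation, channel_heatmap,
                    neuron_gradient, occlusion, saliency, benchmark_methods)
from xaiseg.attribution import (feature_ablation_raw, occlusion_raw,
                                heatmap_to_png)
from xaiseg.nn import ReLU


# -- gradient methods on the linear analytic scorer --------------------------

def test_saliency_of_linear_scorer_is_weight_pattern(linear_handle):
    img = np.full((12, 12), 0.5)
    hm = saliency(linear_handle, img, 1)
    w = np.abs(linear_handle.w)
    expect = (w - w.min()) / (w.max() - w.min())
    assert np.allclose(hm.values, expect)


def test_constant_scorer_gives_zero_heatmap():
    class Constant:
        input_size = (8, 8)
        n_classes = 2

        def _check_target(self, t):
            pass

        def forward(self, image):
            return np.array([1.0, 2.0])

        def input_gradient(self, image, target, guided=False):
            return np.zeros((1, 8, 8))

    hm = saliency(Constant(), np.ones((8, 8)), 1)
    assert hm.values.sum() == 0.0
    occ = occlusion(Constant(), np.ones((8, 8)),
                    1, OcclusionConfig(window=(2, 2), stride=(2, 2)))
    assert occ.values.sum() == 0.0


def test_input_x_gradient_zero_image(linear_handle):
    hm = input_x_gradient(linear_handle, np.zeros((12, 12)), 1)
    assert hm.values.sum() == 0.0


def test_input_x_gradient_linear_scorer(linear_handle):
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(12, 12))
    hm = input_x_gradient(linear_handle, img, 1)
    raw = np.abs(img * linear_handle.w)
    expect = (raw - raw.min()) / (raw.max() - raw.min())
    assert np.allclose(hm.values, expect)


def test_input_x_gradient_equals_saliency_on_ones(linear_handle):
    img = np.ones((12, 12))
    assert np.allclose(input_x_gradient(linear_handle, img, 1).values,
                       saliency(linear_handle, img, 1).values)


# -- guided rectifier rule ---------------------------------------------------

def test_guided_rule_passes_positive_forward_and_gradient():
    relu = ReLU()
    relu.forward(np.array([2.0]))
    assert relu.backward(np.array([1.0]), guided=True) == np.array([1.0])


def test_guided_rule_blocks_negative_incoming_gradient():
    # y = -relu(x), x > 0: incoming gradient -1 must be zeroed
    relu = ReLU()
    relu.forward(np.array([2.0]))
    assert relu.backward(np.array([-1.0]), guided=True) == np.array([0.0])


def test_guided_rule_blocks_nonpositive_preactivation():
    relu = ReLU()
    relu.forward(np.array([0.0, -1.0]))
    out = relu.backward(np.array([1.0, 1.0]), guided=True)
    assert np.array_equal(out, np.zeros(2))


def test_guided_backprop_equals_saliency_without_rectifiers(linear_handle):
    img = np.random.default_rng(1).uniform(size=(12, 12))
    assert np.allclose(guided_backprop(linear_handle, img, 1).values,
                       saliency(linear_handle, img, 1).values)


# -- grad-cam ----------------------------------------------------------------

class _LayerStub:
    """Handle exposing one fabricated feature map with unit mean-gradient."""

    input_size = (6, 6)
    n_classes = 2

    def __init__(self, acts, grads):
        self._acts, self._grads = acts, grads

    def layer_names(self):
        return ["stage"]

    def _check_target(self, t):
        pass

    def input_gradient(self, image, target, guided=False):
        return np.ones((1,) + self.input_size)

    def layer_activations_and_gradients(self, image, target, layer):
        return self._acts, self._grads


def test_grad_cam_closed_form_single_map():
    # scorer = spatial mean of the single feature map: alpha = 1/(h*w),
    # so the map is rectify(A)/max(rectify(A)) after normalisation
    rng = np.random.default_rng(2)
    acts = rng.normal(size=(1, 6, 6))
    grads = np.full((1, 6, 6), 1.0 / 36.0)
    hm = grad_cam(_LayerStub(acts, grads), np.zeros((6, 6)), 1, "stage")
    cam = np.maximum(acts[0] / 36.0, 0)
    assert np.allclose(hm.values, cam / cam.max())


def test_grad_cam_all_negative_sums_give_zero_map():
    acts = -np.ones((2, 4, 4))
    grads = np.ones((2, 4, 4))
    stub = _LayerStub(acts, grads)
    stub.input_size = (4, 4)
    hm = grad_cam(stub, np.zeros((4, 4)), 1, "stage")
    assert hm.values.sum() == 0.0


def test_grad_cam_output_matches_input_shape(handle16, rng):
    img = rng.uniform(size=(16, 16))
    for layer in handle16.layer_names():
        hm = grad_cam(handle16, img, 1, layer)
        assert hm.values.shape == (16, 16)
        assert hm.raw_range[0] >= 0.0  # rectified before normalisation


def test_grad_cam_unknown_layer_raises(handle16, rng):
    with pytest.raises(ValueError):
        grad_cam(handle16, rng.uniform(size=(16, 16)), 1, "nope")


def test_guided_grad_cam_zero_factor_annihilates():
    acts = -np.ones((1, 6, 6))   # cam == 0 everywhere
    grads = np.ones((1, 6, 6))
    hm = guided_grad_cam(_LayerStub(acts, grads), np.zeros((6, 6)), 1,
                         "stage")
    assert hm.values.sum() == 0.0


def test_guided_grad_cam_constant_product_normalises_to_zero():
    # both factors strictly positive constants -> all-equal raw map -> zeros
    acts = np.ones((1, 6, 6))
    grads = np.ones((1, 6, 6))
    hm = guided_grad_cam(_LayerStub(acts, grads), np.zeros((6, 6)), 1,
                         "stage")
    assert hm.values.sum() == 0.0


# -- occlusion / ablation ----------------------------------------------------

class _SumScorer:
    """Class-1 score = sum of all pixels: drops are exactly window sums."""

    def __init__(self, size):
        self.input_size = (size, size)
        self.n_classes = 2

    def _check_target(self, t):
        pass

    def forward(self, image):
        x = np.asarray(image, dtype=np.float64)
        s = float(x.sum())
        return np.array([-s, s])


def test_occlusion_whole_image_window():
    rng = np.random.default_rng(3)
    img = rng.uniform(size=(8, 8))
    raw = occlusion_raw(_SumScorer(8), img, 1,
                        OcclusionConfig(window=(8, 8), stride=(1, 1)))
    assert np.allclose(raw, img.sum())


def test_occlusion_unit_window_recovers_pixels():
    rng = np.random.default_rng(4)
    img = rng.uniform(size=(8, 8))
    raw = occlusion_raw(_SumScorer(8), img, 1,
                        OcclusionConfig(window=(1, 1), stride=(1, 1)))
    assert np.allclose(raw, img)


def test_occlusion_window_too_large_raises():
    with pytest.raises(ValueError):
        occlusion(_SumScorer(8), np.zeros((8, 8)), 1,
                  OcclusionConfig(window=(9, 9), stride=(1, 1)))


def test_occlusion_matches_bruteforce_loop(handle16, rng):
    """Independent oracle: explicit per-window forward calls."""
    img = rng.uniform(size=(16, 16))
    cfg = OcclusionConfig(window=(4, 4), stride=(2, 2), baseline=0.0)
    raw = occlusion_raw(handle16, img, 1, cfg)

    y0 = handle16.forward(img)[1]
    total = np.zeros((16, 16))
    count = np.zeros((16, 16))
    for r in range(0, 16 - 4 + 1, 2):
        for c in range(0, 16 - 4 + 1, 2):
            occluded = img.copy()
            occluded[r:r + 4, c:c + 4] = 0.0
            d = y0 - handle16.forward(occluded)[1]
            total[r:r + 4, c:c + 4] += d
            count[r:r + 4, c:c + 4] += 1
    oracle = np.divide(total, count, out=np.zeros_like(total),
                       where=count > 0)
    assert np.array_equal(raw, oracle)


def test_single_pixel_ablation_equals_unit_occlusion(handle16, rng):
    img = rng.uniform(size=(16, 16))
    groups = np.arange(256).reshape(16, 16)
    ab = feature_ablation_raw(handle16, img, 1, groups)
    oc = occlusion_raw(handle16, img, 1,
                       OcclusionConfig(window=(1, 1), stride=(1, 1)))
    assert np.array_equal(ab, oc)


def test_ablation_single_group_whole_image():
    rng = np.random.default_rng(5)
    img = rng.uniform(size=(8, 8))
    raw = feature_ablation_raw(_SumScorer(8), img, 1, np.zeros((8, 8), int))
    assert np.allclose(raw, img.sum())


def test_ablation_shape_mismatch_raises(handle16):
    with pytest.raises(ValueError):
        feature_ablation(handle16, np.zeros((16, 16)), 1,
                         np.zeros((4, 4), int))


# -- layer / neuron methods --------------------------------------------------

def test_layer_attribution_shape_matches_stage(handle16, rng):
    img = rng.uniform(size=(16, 16))
    la = layer_gradient_x_activation(handle16, img, 1, "conv1")
    acts = handle16.layer_activations(img, "conv1")
    assert la.channels.shape == acts.shape
    assert la.channels.shape[0] == handle16.net.widths[0]


def test_layer_attribution_zero_input_gives_zero_maps(handle16):
    la = layer_gradient_x_activation(handle16, np.zeros((16, 16)), 1,
                                     "conv1")
    assert np.abs(la.channels).sum() == 0.0


def test_channel_heatmap_contract(handle16, rng):
    img = rng.uniform(size=(16, 16))
    la = layer_gradient_x_activation(handle16, img, 1, "conv2")
    hm = channel_heatmap(la, 0)
    assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0
    with pytest.raises(ValueError):
        channel_heatmap(la, 999)


def test_neuron_gradient_of_output_unit_equals_saliency(handle16, rng):
    img = rng.uniform(size=(16, 16))
    a = neuron_gradient(handle16, img, ("output", 1))
    b = saliency(handle16, img, 1)
    assert np.array_equal(a.values, b.values)


def test_neuron_gradient_finite_difference_oracle(handle16, rng):
    img = rng.uniform(size=(16, 16))
    neuron = ("conv2", 3, 2, 2)
    g = handle16.neuron_input_gradient(img, neuron)

    def act(x):
        handle16.net.forward(handle16._as_batch(x))
        return handle16.net.stage_activation("conv2")[0, 3, 2, 2]

    eps = 1e-5
    for _ in range(10):
        i, j = rng.integers(0, 16, 2)
        p, m = img.copy(), img.copy()
        p[i, j] += eps
        m[i, j] -= eps
        fd = (act(p) - act(m)) / (2 * eps)
        assert abs(fd - g[0, i, j]) < 1e-3


def test_neuron_index_out_of_range_raises(handle16, rng):
    with pytest.raises(ValueError):
        neuron_gradient(handle16, rng.uniform(size=(16, 16)),
                        ("conv1", 999, 0, 0))


# -- shared heatmap invariants ----------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_heatmap_bounds_and_peak(handle16, seed):
    rng = np.random.default_rng(seed)
    img = rng.uniform(size=(16, 16))
    for fn in (saliency, input_x_gradient, guided_backprop):
        hm = fn(handle16, img, 1)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0
        assert hm.values.max() == 1.0 or hm.values.sum() == 0.0


def test_heatmap_png_export_roundtrip(handle16, rng, tmp_path):
    from xaiseg.io_formats import read_image
    img = rng.uniform(size=(16, 16))
    hm = saliency(handle16, img, 1)
    path = tmp_path / "hm.png"
    heatmap_to_png(hm, path)
    back = read_image(path)
    assert np.abs(back - hm.values).max() <= 0.5 / 255 + 1e-9


# -- benchmark ---------------------------------------------------------------

def test_benchmark_table_shape_and_order(handle16, rng):
    img = rng.uniform(size=(16, 16))
    table = benchmark_methods(handle16, img,
                              ["saliency", "guided_backprop"], repeats=2,
                              occ_config=OcclusionConfig(window=(4, 4),
                                                         stride=(4, 4)))
    assert list(table.columns) == ["method", "seconds"]
    assert len(table) == 2
    assert table["seconds"].is_monotonic_increasing


def test_benchmark_rejects_unknown_method(handle16, rng):
    with pytest.raises(ValueError):
        benchmark_methods(handle16, rng.uniform(size=(16, 16)), ["nope"])


def test_benchmark_rejects_empty_list(handle16, rng):
    with pytest.raises(ValueError):
        benchmark_methods(handle16, rng.uniform(size=(16, 16)), [])
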