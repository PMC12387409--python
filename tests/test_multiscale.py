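import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placido_edge.kernels import DoGParams, make_dog_kernel, make_mexican_hat
from placido_edge.multiscale import (
    ScaleResponse,
    accumulate_shifted_responses,
    convolve_reflect,
    enhance_with_dog,
    extract_coarse_edges,
    fuse_scales,
)


def brute_force_accumulate(image, kernel, step, centered=False):
    """Literal shift-loop evaluation of the multi-position accumulation."""
    a = np.abs(convolve_reflect(image, kernel))
    start = -(step // 2) if centered else 0
    offsets = list(range(start, start + step))
    weights = {o: 1.0 for o in offsets}
    if centered and step % 2 == 0:
        offsets = list(range(start, start + step + 1))
        weights = {o: 1.0 for o in offsets}
        weights[offsets[0]] = weights[offsets[-1]] = 0.5
    pad = max(abs(min(offsets)), abs(max(offsets)))
    p = np.pad(a, pad, mode="symmetric")
    h, w = image.shape
    out = np.zeros_like(a)
    for by in offsets:
        for bx in offsets:
            out += (weights[by] * weights[bx]
                    * p[pad + by:pad + by + h, pad + bx:pad + bx + w])
    return out


class TestAccumulate:
    def test_step_one_is_abs_convolution(self, rng):
        img = rng.random((24, 24))
        k = make_mexican_hat(1.5, 5)
        got = accumulate_shifted_responses(img, k, 1).response
        np.testing.assert_allclose(got, np.abs(convolve_reflect(img, k)),
                                   atol=1e-12)

    def test_constant_image_zero_mean_kernel(self):
        img = np.full((30, 30), 0.7)
        dog = make_dog_kernel(DoGParams(1.0, 2.0), half_width=8)
        s = accumulate_shifted_responses(img, dog, 3).response
        assert np.abs(s[10:-10, 10:-10]).max() < 1e-2

    @pytest.mark.parametrize("step, centered", [
        (3, False), (2, False), (3, True), (6, True),
    ])
    def test_matches_brute_force_shift_loop(self, rng, step, centered):
        img = rng.random((32, 32))
        k = make_mexican_hat(1.0, 4)
        got = accumulate_shifted_responses(img, k, step,
                                           centered=centered).response
        want = brute_force_accumulate(img, k, step, centered=centered)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_translation_consistency(self, rng):
        img = rng.random((40, 40))
        k = make_mexican_hat(1.0, 4)
        s0 = accumulate_shifted_responses(img, k, 3).response
        s1 = accumulate_shifted_responses(np.roll(img, 1, axis=0),
                                          k, 3).response
        # interior rows shift with the image
        np.testing.assert_allclose(s1[11:-10, 10:-10], s0[10:-11, 10:-10],
                                   atol=1e-10)

    def test_invalid_step(self, rng):
        with pytest.raises(ValueError):
            accumulate_shifted_responses(rng.random((8, 8)),
                                         make_mexican_hat(1.0, 3), 0)


class TestFusion:
    def test_single_scale_is_identity(self, rng):
        f = rng.random((12, 12))
        fused = fuse_scales([ScaleResponse(f, sigma=2.0)])
        np.testing.assert_allclose(fused.weights, [1.0])
        np.testing.assert_array_equal(fused.total, f)

    def test_identical_fields_share_weight(self, rng):
        f = rng.random((12, 12))
        fused = fuse_scales([ScaleResponse(f.copy()), ScaleResponse(f.copy())])
        np.testing.assert_allclose(fused.weights, [0.5, 0.5])

    def test_weighted_sum_scalar_oracle(self, rng):
        fields = [rng.random((10, 10)) for _ in range(3)]
        fused = fuse_scales([ScaleResponse(f) for f in fields])
        stds = np.array([f.std() for f in fields])
        want = sum((s / stds.sum()) * f for s, f in zip(stds, fields))
        np.testing.assert_allclose(fused.total, want, atol=1e-12)

    @given(n=st.integers(1, 5), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_weights_nonnegative_and_normalized(self, n, seed):
        r = np.random.default_rng(seed)
        fused = fuse_scales([ScaleResponse(r.random((8, 8)))
                             for _ in range(n)])
        assert np.all(fused.weights >= 0)
        assert abs(fused.weights.sum() - 1.0) < 1e-9

    def test_degenerate_all_constant_raises(self):
        with pytest.raises(ValueError):
            fuse_scales([ScaleResponse(np.zeros((6, 6))),
                         ScaleResponse(np.ones((6, 6)))])

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse_scales([ScaleResponse(rng.random((6, 6))),
                         ScaleResponse(rng.random((7, 7)))])


class TestDoGEnhancement:
    def test_constant_field_maps_to_near_zero(self):
        dog = make_dog_kernel(DoGParams(1.0, 2.0))
        out = enhance_with_dog(np.full((40, 40), 3.0), dog)
        assert np.abs(out[12:-12, 12:-12]).max() < 5e-3

    def test_impulse_reproduces_kernel(self):
        dog = make_dog_kernel(DoGParams(1.0, 2.0), half_width=6)
        field = np.zeros((31, 31))
        field[15, 15] = 1.0
        out = enhance_with_dog(field, dog)
        np.testing.assert_allclose(out[9:22, 9:22], dog, atol=1e-12)


class TestCoarseExtraction:
    def test_flat_field_gives_empty_mask(self):
        with pytest.warns(UserWarning):
            out = extract_coarse_edges(np.zeros((20, 20)))
        assert not out.mask.any()

    def test_small_components_are_dropped(self):
        field = np.full((40, 40), -1.0)
        field[10:13, 5:26] = 2.0      # long bar -> large outline component
        field[30, 30] = 0.5           # speck -> 1-px crossing component
        out = extract_coarse_edges(field, min_component=5)
        assert out.mask.any()
        assert not out.mask[28:33, 28:33].any()
        assert np.all(out.component_sizes >= 5)

    def test_mask_is_thin(self, circle_detection):
        """No 2x2 block of the candidate mask is fully set."""
        m = circle_detection.intermediates["mask"]
        blocks = m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]
        assert not blocks.any()

    def test_circle_front_end_traces_single_ring(self, circle_detection):
        """Full front-end on the disc: one closed ring within 2 px of r=150."""
        from skimage.measure import label
        m = circle_detection.intermediates["mask"]
        rows, cols = np.nonzero(m)
        r = np.hypot(cols - 200, rows - 200)
        assert np.all(np.abs(r - 150) < 2.0)
        _, n = label(m, connectivity=2, return_num=True)
        assert n == 1

    def test_phantom_edge_contrast_over_background(self, phantom):
        """|Ef| on ring edges dwarfs |Ef| on the empty background."""
        import placido_edge as pe
        spec, img, truth = phantom
        res = pe.detect_subpixel_edges(img, keep_intermediates=True)
        ef = res.intermediates["Ef"]
        cx, cy = truth["center"]
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        r = np.hypot(xx - cx, yy - cy)
        edges = np.asarray(truth["ring_edge_radii"])
        near = np.abs(r[None] - edges[:, None, None]).min(axis=0) < 0.7
        background = r > max(truth["ring_radii"]) + 8
        ratio = np.abs(ef[near]).mean() / np.abs(ef[background]).mean()
        assert ratio > 2.0
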