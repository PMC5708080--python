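"""Built-in ops: element-wise math, Gaussian filtering, DoG, stats, map, eval.

The Gaussian check uses an independent dense-convolution oracle with explicit
mirror indexing; composition laws are checked against manual chains.
"""

from math import ceil

import numpy as np
import pytest

import ndops
from ndops.errors import (
    DomainError, ParseError, ShapeError, UnboundIdentifierError,
)
from ndops.types import FLOAT64, INT16, UINT8

from conftest import assert_images_equal


# ---------------------------------------------------------------------------
# independent dense-convolution oracle

def _mirror(i, n):
    """Reflect an index into [0, n) without repeating the edge sample."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i
        if i >= n:
            i = 2 * n - 2 - i
    return i


def _dense_gauss_oracle(arr, sigma):
    radius = max(1, ceil(3 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-(x * x) / (2 * sigma * sigma))
    kernel /= kernel.sum()
    out = arr.astype(float)
    for axis in range(arr.ndim):
        src = out.copy()
        out = np.zeros_like(src)
        for idx in np.ndindex(src.shape):
            acc = 0.0
            for k, w in zip(range(-radius, radius + 1), kernel):
                j = list(idx)
                j[axis] = _mirror(idx[axis] + k, src.shape[axis])
                acc += w * src[tuple(j)]
            out[idx] = acc
    return out


class TestMath:
    def test_add_constant_to_gradient(self, ctx):
        img = ndops.make_fixture("gradient", UINT8, (1, 4))
        out = ctx.ops.run("math.add", img, 10)
        assert out.to_array().tolist() == [[10, 11, 12, 13]]

    def test_uint8_addition_saturates(self, ctx):
        img = ndops.make_fixture("constant", UINT8, (2, 2), value=250)
        out = ctx.ops.run("math.add", img, 10)
        assert out.to_array().tolist() == [[255, 255], [255, 255]]

    def test_subtraction_clamps_at_zero_for_unsigned(self, ctx):
        img = ndops.make_fixture("constant", UINT8, (2, 2), value=3)
        out = ctx.ops.run("math.sub", img, 10)
        assert out.to_array().tolist() == [[0, 0], [0, 0]]

    def test_shape_mismatch_is_a_shape_error(self, ctx):
        a = ndops.make_fixture("constant", UINT8, (2, 2), value=1)
        b = ndops.make_fixture("constant", UINT8, (2, 3), value=1)
        with pytest.raises(ShapeError):
            ctx.ops.run("math.add", a, b)

    def test_integer_division_rounds_half_to_even_after_real_division(self, ctx):
        img = ndops.create_image(UINT8, (1, 4))
        for j, v in enumerate([1, 3, 5, 7]):
            img.set((0, j), v)
        out = ctx.ops.run("math.div", img, 2.0)
        assert out.to_array().tolist() == [[0, 2, 2, 4]]

    def test_division_by_zero_sample_reports_coordinate(self, ctx):
        a = ndops.make_fixture("constant", UINT8, (2, 2), value=4)
        b = ndops.make_fixture("impulse", UINT8, (2, 2), coord=(0, 0))
        with pytest.raises(DomainError, match="zero"):
            ctx.ops.run("math.div", a, b)

    def test_sqrt_of_squares(self, ctx):
        img = ndops.create_image(UINT8, (1, 4))
        for j, v in enumerate([0, 1, 4, 9]):
            img.set((0, j), v)
        out = ctx.ops.run("math.sqrt", img)
        assert out.to_array().tolist() == [[0, 1, 2, 3]]

    @pytest.mark.parametrize("family", ["add", "sub", "mul", "div"])
    def test_generic_and_array_optimized_agree(self, ctx, family):
        a = ndops.make_fixture("noise", INT16, (5, 6), seed=3)
        b = ctx.ops.run("math.add",
                        ndops.make_fixture("noise", UINT8, (5, 6), seed=4), 1)
        b = ndops.convert_layout(b, "array")
        generic = ctx.ops.resolve(f"math.{family}", (ndops.PlanarImage,
                                                     ndops.PlanarImage))
        assert generic.descriptor.id.endswith("img-img")
        out_generic = ctx.ops.run(f"math.{family}",
                                  ndops.convert_layout(a, "planar"),
                                  ndops.convert_layout(b, "planar"))
        out_array = ctx.ops.run(f"math.{family}", a, b)
        assert np.array_equal(out_generic.to_array(), out_array.to_array())


class TestGauss:
    def test_constant_image_is_preserved(self, ctx):
        img = ndops.make_fixture("constant", FLOAT64, (5, 5), value=7.0)
        out = ctx.ops.run("filter.gauss", img, 2.0)
        assert np.max(np.abs(out.to_array() - 7.0)) <= 1e-9

    def test_sigma_zero_is_bitwise_identity(self, ctx):
        img = ndops.make_fixture("noise", UINT8, (6, 7), seed=5)
        out = ctx.ops.run("filter.gauss", img, 0.0)
        assert np.array_equal(out.to_array(), img.to_array())

    def test_negative_sigma_rejected(self, ctx):
        img = ndops.make_fixture("constant", FLOAT64, (3, 3), value=1.0)
        with pytest.raises(DomainError):
            ctx.ops.run("filter.gauss", img, -1.0)

    @pytest.mark.parametrize("sigma", [0.8, 1.0, 2.0])
    def test_matches_dense_convolution_oracle(self, ctx, sigma):
        img = ndops.make_fixture("noise", FLOAT64, (9, 8), seed=2)
        out = ctx.ops.run("filter.gauss", img, sigma)
        expected = _dense_gauss_oracle(img.to_array(), sigma)
        assert np.max(np.abs(out.to_array() - expected)) < 1e-10

    def test_impulse_response_is_kernel_outer_product(self, ctx):
        from ndops.ops.builtins import gaussian_kernel
        img = ndops.make_fixture("impulse", FLOAT64, (9, 9), coord=(4, 4))
        out = ctx.ops.run("filter.gauss", img, 1.0)
        k = gaussian_kernel(1.0)
        expected = np.zeros((9, 9))
        expected[1:8, 1:8] = np.outer(k, k)
        assert np.max(np.abs(out.to_array() - expected)) < 1e-12


class TestDoG:
    def test_equal_sigmas_give_zero_image(self, ctx):
        img = ndops.make_fixture("noise", FLOAT64, (7, 7), seed=1)
        out = ctx.ops.run("image.dog", img, 1.5, 1.5)
        assert np.max(np.abs(out.to_array())) == 0.0

    def test_equals_manual_subtraction_of_gaussians(self, ctx):
        img = ndops.make_fixture("noise", FLOAT64, (8, 6), seed=9)
        dog = ctx.ops.run("image.dog", img, 2.0, 1.0)
        manual = ctx.ops.run("math.sub",
                             ctx.ops.run("filter.gauss", img, 2.0),
                             ctx.ops.run("filter.gauss", img, 1.0))
        assert np.array_equal(dog.to_array(), manual.to_array())

    def test_impulse_response_is_difference_of_kernels(self, ctx):
        img = ndops.make_fixture("impulse", FLOAT64, (15, 15), coord=(7, 7))
        out = ctx.ops.run("image.dog", img, 2.0, 1.0)
        expected = _dense_gauss_oracle(img.to_array(), 2.0) \
            - _dense_gauss_oracle(img.to_array(), 1.0)
        assert np.max(np.abs(out.to_array() - expected)) < 1e-10

    def test_descriptor_declares_its_op_chain(self, ctx):
        match = ctx.ops.resolve("image.dog", (ndops.ArrayImage, float, float))
        assert set(match.descriptor.chain) == \
            {"filter.gauss", "math.sub"}


class TestStats:
    def test_mean_of_small_gradient(self, ctx):
        img = ndops.make_fixture("gradient", UINT8, (1, 4))
        assert ctx.ops.run("stats.mean", img) == 1.5

    def test_mean_decomposes_into_sum_over_size(self, ctx):
        img = ndops.make_fixture("noise", UINT8, (6, 7), seed=13)
        total = ctx.ops.run("stats.sum", img)
        count = ctx.ops.run("stats.size", img)
        assert ctx.ops.run("stats.mean", img) == float(total) / float(count)
        assert count == 42

    def test_min_max_match_numpy(self, ctx):
        img = ndops.make_fixture("noise", INT16, (5, 5), seed=21)
        arr = img.to_array()
        assert ctx.ops.run("stats.min", img) == arr.min()
        assert ctx.ops.run("stats.max", img) == arr.max()

    def test_roi_stats_aggregate_only_selected_samples(self, ctx):
        img = ndops.make_fixture("gradient", UINT8, (4, 4))
        roi = ndops.MaskROI(((0, 3), (0, 3)),
                            lambda c: (c[0] + c[1]) % 2 == 0)
        values = [v for _, v in img.iterate(roi)]
        assert ctx.ops.run("stats.sum", img, roi) == sum(values)
        assert ctx.ops.run("stats.size", img, roi) == len(values)
        assert ctx.ops.run("stats.mean", img, roi) == \
            sum(values) / len(values)

    def test_empty_roi_rejected(self, ctx):
        img = ndops.make_fixture("gradient", UINT8, (4, 4))
        roi = ndops.MaskROI(((0, 3), (0, 3)), lambda c: False)
        with pytest.raises(DomainError, match="empty"):
            ctx.ops.run("stats.mean", img, roi)


class TestMap:
    def test_map_sqrt(self, ctx):
        img = ndops.create_image(UINT8, (1, 4))
        for j, v in enumerate([0, 1, 4, 9]):
            img.set((0, j), v)
        inst = ctx.ops.instance("math.sqrt", [float])
        out = ctx.ops.run("image.map", img, inst)
        assert out.to_array().tolist() == [[0, 1, 2, 3]]

    def test_map_identity_is_bitwise_equal(self, ctx):
        img = ndops.make_fixture("noise", UINT8, (4, 5), seed=6)
        inst = ctx.ops.instance("math.identity", [float])
        out = ctx.ops.run("image.map", img, inst)
        assert np.array_equal(out.to_array(), img.to_array())

    def test_map_matches_per_sample_loop_oracle(self, ctx):
        img = ndops.make_fixture("noise", FLOAT64, (5, 4), seed=31)
        inst = ctx.ops.instance("math.sqrt", [float])
        out = ctx.ops.run("image.map", img, inst)
        expected = [[img.get((i, j)) ** 0.5 for j in range(4)]
                    for i in range(5)]
        assert np.allclose(out.to_array(), expected, atol=1e-12)

    def test_layout_is_preserved(self, ctx):
        img = ndops.make_fixture("noise", UINT8, (4, 4), seed=1,
                                 layout="planar")
        inst = ctx.ops.instance("math.identity", [float])
        assert ctx.ops.run("image.map", img, inst).layout == "planar"


class TestEval:
    @pytest.mark.parametrize("expr,expected", [
        ("2+3*4", 14),
        ("(2+3)*4", 20),
        ("a/b", 2.5),
        ("10-2-3", 5),              # left associativity
        ("-3+5", 2),
        ("2*-3", -6),
        ("sqrt(16)", 4.0),
    ])
    def test_scalar_expressions(self, ctx, expr, expected):
        assert ctx.ops.run("script.eval", expr, {"a": 5, "b": 2}) == expected

    def test_image_expression_equals_dog(self, ctx):
        img = ndops.make_fixture("noise", FLOAT64, (6, 6), seed=77)
        via_eval = ctx.ops.run("script.eval",
                               "sub(gauss(image,2),gauss(image,1))",
                               {"image": img})
        direct = ctx.ops.run("image.dog", img, 2.0, 1.0)
        assert np.array_equal(via_eval.to_array(), direct.to_array())

    def test_parse_error_carries_position(self, ctx):
        with pytest.raises(ParseError) as err:
            ctx.ops.run("script.eval", "2+*3")
        assert err.value.position == 2

    def test_unbound_identifier_rejected(self, ctx):
        with pytest.raises(UnboundIdentifierError):
            ctx.ops.run("script.eval", "nope+1")

    def test_string_concatenation_renders_numbers(self, ctx):
        result = ctx.ops.run("script.eval", '"n=" + 3 + "!"')
        assert result == "n=3!"


class TestLayoutTransparency:
    OPS = [("math.add", (7,)), ("math.sub", (3,)), ("math.mul", (2,)),
           ("math.sqrt", ()), ("filter.gauss", (1.0,)),
           ("image.dog", (2.0, 1.0))]

    @pytest.mark.parametrize("t", [UINT8, FLOAT64], ids=lambda t: t.name)
    def test_results_identical_across_layouts(self, ctx, t):
        for seed in range(5):
            base = ndops.make_fixture("noise", t, (6, 5), seed=seed)
            for op, args in self.OPS:
                reference = ctx.ops.run(op, ndops.convert_layout(base, "array"),
                                        *args)
                for layout in ("planar", "cell"):
                    other = ctx.ops.run(
                        op, ndops.convert_layout(base, layout), *args)
                    assert_images_equal(reference, other, tol=1e-12)
                scalar_ref = ctx.ops.run("stats.mean", base)
                for layout in ("planar", "cell"):
                    assert ctx.ops.run(
                        "stats.mean",
                        ndops.convert_layout(base, layout)) == scalar_ref
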