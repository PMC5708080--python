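"""Op matching: resolution order, converters, special ops, purity, kinds.

The central check is an independent brute-force matcher: every candidate in a
small generated registry is scored with the documented key
(penalty asc, specificity asc, priority desc, id asc) by a re-implementation
that shares no code with the engine, and the engine must agree on every
generated request.
"""

import itertools

import numpy as np
import pytest

import ndops
from ndops.containers import ArrayImage, Image, PlanarImage
from ndops.context import Context, PluginDescriptor
from ndops.convert import ConvertService, ConverterDescriptor
from ndops.errors import NoMatchError, UnknownOpError
from ndops.ops.engine import OpDescriptor, OpService, Param, checksum
from ndops.types import FLOAT64, UINT8


class TestResolveExamples:
    def test_image_plus_real_selects_constant_variant(self, ctx):
        img = ndops.make_fixture("constant", UINT8, (2, 2), value=1,
                                 layout="planar")
        match = ctx.ops.resolve("math.add", (type(img), float))
        assert match.descriptor.id == "math.add#img-const"
        assert match.penalty == 0

    def test_image_pair_selects_elementwise_variant(self, ctx):
        match = ctx.ops.resolve("math.add", (PlanarImage, PlanarImage))
        assert match.descriptor.id == "math.add#img-img"

    def test_array_specialized_variant_beats_generic(self, ctx):
        match = ctx.ops.resolve("math.sqrt", (ArrayImage,))
        assert match.descriptor.id == "math.sqrt#img-array"
        generic = ctx.ops.resolve("math.sqrt", (PlanarImage,))
        assert generic.descriptor.id == "math.sqrt#img"

    def test_unknown_name_and_incompatible_args_raise_distinct_errors(self, ctx):
        with pytest.raises(UnknownOpError):
            ctx.ops.resolve("nosuch.op", (int,))
        with pytest.raises(NoMatchError) as err:
            ctx.ops.resolve("filter.gauss", (str, dict))
        assert err.value.near_misses

    def test_exact_match_always_beats_converter_assisted(self, ctx):
        # int args must convert to float: penalty 2; a registered exact
        # (int, int) op must win regardless of priority.
        ctx.ops.register(OpDescriptor(
            id="test.addint", name="math.add",
            params=(Param("a", int), Param("b", int)), output=int,
            func=lambda c, a, b: a + b, priority=-100))
        match = ctx.ops.resolve("math.add", (int, int))
        assert match.descriptor.id == "test.addint"


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence


class _Base:
    pass


class _Mid(_Base):
    pass


class _Leaf(_Mid):
    pass


_PARAM_TYPES = (_Base, _Mid, float)
_ARG_TYPES = (_Leaf, _Mid, float, int)
_CONVERTERS = (
    ConverterDescriptor("conv.int-float", int, float, 1,
                        lambda c, v: float(v)),
    ConverterDescriptor("conv.mid-float", _Mid, float, 1,
                        lambda c, v: 0.0),
)


def _bare_ops_context(op_descriptors, converters):
    ctx = Context([
        PluginDescriptor("service.convert", "convert", 0, ConvertService),
        PluginDescriptor("service.ops", "ops", 0, OpService),
    ])
    for conv in converters:
        ctx.convert.register(conv)
    for d in op_descriptors:
        ctx.ops.register(d)
    return ctx


def _oracle_resolve(descriptors, converters, name, arg_types):
    """Independent scorer: enumerate candidates, score, pick by stated key."""
    scored = []
    for d in descriptors:
        if name not in (d.name, *d.aliases) or len(d.params) != len(arg_types):
            continue
        penalty = specificity = 0
        ok = True
        for at, p in zip(arg_types, d.params):
            if issubclass(at, p.type):
                specificity += at.__mro__.index(p.type)
            elif any(issubclass(at, c.from_type)
                     and issubclass(c.to_type, p.type) for c in converters):
                penalty += 1
            else:
                ok = False
                break
        if ok:
            scored.append((penalty, specificity, -d.priority, d.id))
    if not scored:
        return None
    return min(scored)[3]


def _registries():
    """Generated registries: up to 8 ops with varied signatures/priorities."""
    rng = np.random.default_rng(1234)
    pools = []
    for trial in range(60):
        n_ops = int(rng.integers(1, 9))
        descriptors = []
        for i in range(n_ops):
            arity = int(rng.integers(1, 4))
            params = tuple(
                Param(f"p{j}", _PARAM_TYPES[int(rng.integers(len(_PARAM_TYPES)))])
                for j in range(arity))
            descriptors.append(OpDescriptor(
                id=f"t.op#{trial}.{i}", name="t.op", params=params,
                output=object, func=lambda c, *a: None,
                priority=float(rng.integers(-2, 3))))
        with_conv = bool(rng.integers(0, 2))
        pools.append((descriptors, _CONVERTERS if with_conv else ()))
    return pools


class TestBruteForceOracle:
    def test_resolver_agrees_with_exhaustive_scoring(self):
        checked = 0
        for descriptors, converters in _registries():
            ctx = _bare_ops_context(descriptors, converters)
            for arity in (1, 2, 3):
                for arg_types in itertools.product(_ARG_TYPES, repeat=arity):
                    expected = _oracle_resolve(descriptors, converters,
                                               "t.op", arg_types)
                    if expected is None:
                        with pytest.raises((NoMatchError, UnknownOpError)):
                            ctx.ops.resolve("t.op", arg_types)
                    else:
                        got = ctx.ops.resolve("t.op", arg_types)
                        assert got.descriptor.id == expected, \
                            f"registry mismatch for {arg_types}"
                    checked += 1
        assert checked > 3000

    def test_penalty_counts_converted_arguments(self):
        d = OpDescriptor(id="t.f", name="t.f",
                         params=(Param("a", float), Param("b", float)),
                         output=float, func=lambda c, a, b: a + b)
        ctx = _bare_ops_context([d], _CONVERTERS)
        match = ctx.ops.resolve("t.f", (int, float))
        assert match.penalty == 1
        assert match.conversion_plan == ("conv.int-float", "direct")


class TestRunAndConverters:
    def test_constant_add_applies_numeric_conversion(self, ctx):
        img = ndops.make_fixture("constant", UINT8, (2, 2), value=2)
        out = ctx.ops.run("math.add", img, 10)
        assert out.to_array().tolist() == [[12, 12], [12, 12]]

    def test_string_argument_parsed_by_converter(self, ctx):
        img = ndops.make_fixture("constant", UINT8, (2, 2), value=2)
        out = ctx.ops.run("math.add", img, "3")
        assert out.to_array().tolist() == [[5, 5], [5, 5]]

    def test_memoized_second_call_skips_execution(self, ctx):
        ctx.ops.memoize = True
        img = ndops.make_fixture("noise", UINT8, (4, 4), seed=1)
        first = ctx.ops.run("stats.sum", img)
        count = dict(ctx.ops.exec_counts)
        second = ctx.ops.run("stats.sum", img)
        assert second == first
        assert ctx.ops.exec_counts == count   # no new execution

    def test_memoization_is_off_by_default(self, ctx):
        img = ndops.make_fixture("noise", UINT8, (4, 4), seed=1)
        ctx.ops.run("stats.sum", img)
        before = ctx.ops.exec_counts["stats.sum#whole"]
        ctx.ops.run("stats.sum", img)
        assert ctx.ops.exec_counts["stats.sum#whole"] == before + 1


class TestSpecialOps:
    def test_instance_reuses_one_match_over_ten_inputs(self, ctx):
        images = [ndops.make_fixture("noise", FLOAT64, (4, 5), seed=s)
                  for s in range(10)]
        before = ctx.ops.match_count
        inst = ctx.ops.instance("filter.gauss", [Image], [1.5])
        assert ctx.ops.match_count == before + 1
        results = [inst(img) for img in images]
        assert ctx.ops.match_count == before + 1   # zero further matching
        for img, res in zip(images, results):
            direct = ctx.ops.run("filter.gauss", img, 1.5)
            assert np.allclose(res.to_array(), direct.to_array(), atol=0)

    def test_binary_instance_matches_elementwise_oracle(self, ctx, rng):
        inst = ctx.ops.instance("math.add", [ArrayImage, ArrayImage])
        a = ndops.make_fixture("noise", UINT8, (3, 4), seed=7)
        b = ndops.make_fixture("noise", UINT8, (3, 4), seed=8)
        out = inst(a, b)
        expected = [[min(255, a.get((i, j)) + b.get((i, j)))
                     for j in range(4)] for i in range(3)]
        assert out.to_array().tolist() == expected

    def test_nullary_create_instance_returns_fresh_zero_images(self, ctx):
        inst = ctx.ops.instance("create.img", [], [UINT8, (2, 2)])
        img1, img2 = inst(), inst()
        assert img1 is not img2
        assert img1.to_array().tolist() == [[0, 0], [0, 0]]
        img1.set((0, 0), 5)
        assert img2.get((0, 0)) == 0

    def test_incompatible_primary_input_raises_type_error(self, ctx):
        inst = ctx.ops.instance("filter.gauss", [Image], [1.0])
        with pytest.raises(TypeError):
            inst("not an image")


class TestPurityAndKinds:
    @pytest.mark.parametrize("op,args", [
        ("math.add", (10,)), ("math.mul", (3,)), ("math.sqrt", ()),
        ("filter.gauss", (1.0,)), ("image.dog", (2.0, 1.0)),
        ("stats.mean", ()),
    ])
    def test_function_kind_leaves_inputs_unmodified(self, ctx, op, args):
        img = ndops.make_fixture("noise", UINT8, (5, 6), seed=11)
        before = checksum(img)
        ctx.ops.run(op, img, *args)
        assert checksum(img) == before

    @pytest.mark.parametrize("family", ["add", "sub", "mul", "div"])
    def test_function_computer_inplace_agree(self, ctx, family):
        for seed in range(10):
            a = ndops.make_fixture("noise", UINT8, (4, 5), seed=seed)
            b = ctx.ops.run("math.add",
                            ndops.make_fixture("noise", UINT8, (4, 5),
                                               seed=seed + 100), 1)
            fresh = ctx.ops.run(f"math.{family}", a, b)
            out = ndops.create_image(UINT8, (4, 5))
            ctx.ops.run_computer(f"math.{family}", out, a, b)
            mutated = ndops.convert_layout(a, "array")
            ctx.ops.run_inplace(f"math.{family}", mutated, b)
            assert np.array_equal(fresh.to_array(), out.to_array())
            assert np.array_equal(fresh.to_array(), mutated.to_array())


class TestAmbiguity:
    def test_full_tie_picks_name_ascending_and_warns(self, ctx):
        for op_id in ("test.b-variant", "test.a-variant"):
            ctx.ops.register(OpDescriptor(
                id=op_id, name="test.tied", params=(Param("a", float),),
                output=float, func=lambda c, a: a))
        match = ctx.ops.resolve("test.tied", (float,))
        assert match.descriptor.id == "test.a-variant"
        assert any("ambiguous" in m for m in ctx.log.messages("warn"))
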