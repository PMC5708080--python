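"""Built-in op library.

Element-wise math (add/sub/mul/div/sqrt) over image-image, image-constant and
scalar signatures, each in generic and array-optimized registrations; a
separable Gaussian filter and the difference-of-Gaussians built by chaining it
with subtraction; sum/size/min/max/mean statistics (mean is itself composed
from sum, size and division); element-wise map over a special-op instance;
expression evaluation; and image creation.

Arithmetic saturates to the output sample type's bounds, and real-to-integer
results round half-to-even (one rule everywhere, shared with ``clamp_cast``).
Integer image division divides in real arithmetic first, then rounds. The
generic and array-optimized registrations of each op compute identical values
— integer paths are exact (arbitrary precision), real paths are IEEE double —
so layout and specialization never change results.
"""

from __future__ import annotations

import math
from math import ceil, prod

import numpy as np
from scipy import ndimage as _scipy_ndimage

from ..containers import (
    ArrayImage, CellImage, Image, MaskROI, PlanarImage, create_image,
    storage_dtype,
)
from ..errors import DomainError, ShapeError
from ..types import COMPLEX, FLOAT64, REAL, SampleType, clamp_cast
from .engine import OpDescriptor, Param, SpecialOp


# ---------------------------------------------------------------------------
# helpers

def _like(img: Image, sample_type: SampleType | None = None) -> Image:
    """Fresh zero image matching ``img``'s shape and layout (function-backed
    inputs produce array outputs, since results must be writable)."""
    t = sample_type or img.sample_type
    if isinstance(img, PlanarImage):
        return PlanarImage(t, img.shape)
    if isinstance(img, CellImage):
        return CellImage(t, img.shape, img.cell_shape, img.capacity, None)
    return ArrayImage(t, img.shape)


def _store_result(img: Image, data: np.ndarray) -> None:
    t = img.sample_type
    if t.is_integral and t.bounded:
        if data.dtype == object:
            caster = np.frompyfunc(
                lambda v: clamp_cast(v, FLOAT64, t), 1, 1)
            data = caster(data)
        else:
            data = np.clip(np.rint(data), float(t.min), float(t.max))
        data = data.astype(storage_dtype(t))
    else:
        data = data.astype(storage_dtype(t))
    img.write_block((0,) * img.ndim, data)


def _compute_array(img: Image) -> np.ndarray:
    """Whole image as an exact compute array: object (big-int) for integral
    types, float64/complex128 for real/complex."""
    arr = img.to_array()
    t = img.sample_type
    if t.kind == REAL:
        return arr.astype(np.float64)
    if t.kind == COMPLEX:
        return arr.astype(np.complex128)
    return arr.astype(object)


# ---------------------------------------------------------------------------
# element-wise math kernels

def _scalar_add(a, b, coords=None):
    return a + b


def _scalar_sub(a, b, coords=None):
    return a - b


def _scalar_mul(a, b, coords=None):
    return a * b


def _scalar_div(a, b, coords=None):
    if b == 0:
        where = f" at coordinate {coords}" if coords is not None else ""
        raise DomainError(f"division by zero{where}")
    return a / b


_SCALAR_FNS = {"add": _scalar_add, "sub": _scalar_sub,
               "mul": _scalar_mul, "div": _scalar_div}


def _ew_image_image(fn):
    def kernel(ctx, a: Image, b: Image, target: Image | None = None):
        if a.shape != b.shape:
            raise ShapeError(
                f"shape mismatch: {a.shape} vs {b.shape}")
        out = target if target is not None else _like(a)
        t = out.sample_type
        for coords in np.ndindex(a.shape):
            r = fn(a.get(coords), b.get(coords), coords)
            out.set(coords, clamp_cast(r, FLOAT64, t))
        return out
    return kernel


def _ew_image_const(fn):
    def kernel(ctx, a: Image, c: float, target: Image | None = None):
        out = target if target is not None else _like(a)
        t = out.sample_type
        for coords in np.ndindex(a.shape):
            r = fn(a.get(coords), c, coords)
            out.set(coords, clamp_cast(r, FLOAT64, t))
        return out
    return kernel


def _ew_unary(fn):
    def kernel(ctx, a: Image, target: Image | None = None):
        out = target if target is not None else _like(a)
        t = out.sample_type
        for coords in np.ndindex(a.shape):
            out.set(coords, clamp_cast(fn(a.get(coords)), FLOAT64, t))
        return out
    return kernel


def _np_binary(fn_name):
    # Vectorized over exact compute arrays; division checks zeros first.
    def kernel(ctx, a: ArrayImage, b, target: Image | None = None):
        da = _compute_array(a)
        if isinstance(b, Image):
            if a.shape != b.shape:
                raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
            db = _compute_array(b)
        else:
            db = b
        if fn_name == "div":
            zeros = np.argwhere(np.asarray(db) == 0) if isinstance(b, Image) \
                else ([] if b != 0 else [()])
            if len(zeros) > 0:
                where = tuple(zeros[0]) if isinstance(b, Image) else None
                raise DomainError(
                    f"division by zero at coordinate {where}"
                    if where is not None else "division by zero")
            r = da / db
        elif fn_name == "add":
            r = da + db
        elif fn_name == "sub":
            r = da - db
        else:
            r = da * db
        out = target if target is not None else _like(a)
        _store_result(out, np.asarray(r))
        return out
    return kernel


def _sqrt_value(v):
    if isinstance(v, complex):
        return v ** 0.5
    if v < 0:
        raise DomainError(f"sqrt of negative value {v}")
    return math.sqrt(v)


def _np_sqrt(ctx, a: ArrayImage, target: Image | None = None):
    da = _compute_array(a)
    if da.dtype == object:
        if any(v < 0 for v in da.ravel()):
            raise DomainError("sqrt of negative value")
        r = np.frompyfunc(math.sqrt, 1, 1)(da).astype(np.float64)
    else:
        if da.dtype != np.complex128 and np.any(da < 0):
            raise DomainError("sqrt of negative value")
        r = np.sqrt(da)
    out = target if target is not None else _like(a)
    _store_result(out, r)
    return out


_ALL_KINDS = frozenset({"function", "computer", "inplace"})


def _math_descriptor(op_id, name, kernel, params, aliases=(), priority=0.0):
    return OpDescriptor(
        id=op_id, name=name, params=params, output=Image,
        func=lambda ctx, *args, _k=kernel: _k(ctx, *args),
        computer=lambda ctx, out, *args, _k=kernel: _k(ctx, *args, target=out),
        inplace=lambda ctx, *args, _k=kernel: _k(ctx, *args, target=args[0]),
        priority=priority, aliases=aliases, kinds=_ALL_KINDS)


def _scalar_descriptor(family, fn):
    return OpDescriptor(
        id=f"math.{family}#scalar", name=f"math.{family}",
        params=(Param("a", float), Param("b", float)), output=float,
        func=lambda ctx, a, b, _f=fn: _f(a, b),
        aliases=(family,))


_MATH_DESCRIPTORS = []
for _family in ("add", "sub", "mul", "div"):
    _fn = _SCALAR_FNS[_family]
    _MATH_DESCRIPTORS += [
        _math_descriptor(f"math.{_family}#img-img", f"math.{_family}",
                         _ew_image_image(_fn),
                         (Param("a", Image), Param("b", Image)),
                         aliases=(_family,)),
        _math_descriptor(f"math.{_family}#img-const", f"math.{_family}",
                         _ew_image_const(_fn),
                         (Param("a", Image), Param("b", float, primary=False)),
                         aliases=(_family,)),
        _math_descriptor(f"math.{_family}#img-img-array", f"math.{_family}",
                         _np_binary(_family),
                         (Param("a", ArrayImage), Param("b", ArrayImage)),
                         aliases=(_family,)),
        _math_descriptor(f"math.{_family}#img-const-array", f"math.{_family}",
                         _np_binary(_family),
                         (Param("a", ArrayImage),
                          Param("b", float, primary=False)),
                         aliases=(_family,)),
        _scalar_descriptor(_family, _fn),
    ]

MATH_SQRT_IMG = _math_descriptor(
    "math.sqrt#img", "math.sqrt", _ew_unary(_sqrt_value),
    (Param("a", Image),), aliases=("sqrt",))
MATH_SQRT_IMG_ARRAY = _math_descriptor(
    "math.sqrt#img-array", "math.sqrt", _np_sqrt,
    (Param("a", ArrayImage),), aliases=("sqrt",))
MATH_SQRT_SCALAR = OpDescriptor(
    id="math.sqrt#scalar", name="math.sqrt",
    params=(Param("a", float),), output=float,
    func=lambda ctx, a: _sqrt_value(a), aliases=("sqrt",))
MATH_IDENTITY_SCALAR = OpDescriptor(
    id="math.identity#scalar", name="math.identity",
    params=(Param("a", float),), output=float,
    func=lambda ctx, a: a, aliases=("identity",))

(MATH_ADD_IMG_IMG, MATH_ADD_IMG_CONST, MATH_ADD_IMG_IMG_ARRAY,
 MATH_ADD_IMG_CONST_ARRAY, MATH_ADD_SCALAR,
 MATH_SUB_IMG_IMG, MATH_SUB_IMG_CONST, MATH_SUB_IMG_IMG_ARRAY,
 MATH_SUB_IMG_CONST_ARRAY, MATH_SUB_SCALAR,
 MATH_MUL_IMG_IMG, MATH_MUL_IMG_CONST, MATH_MUL_IMG_IMG_ARRAY,
 MATH_MUL_IMG_CONST_ARRAY, MATH_MUL_SCALAR,
 MATH_DIV_IMG_IMG, MATH_DIV_IMG_CONST, MATH_DIV_IMG_IMG_ARRAY,
 MATH_DIV_IMG_CONST_ARRAY, MATH_DIV_SCALAR) = _MATH_DESCRIPTORS


# ---------------------------------------------------------------------------
# Gaussian filtering and difference of Gaussians

def gaussian_kernel(sigma: float) -> np.ndarray:
    """Sampled Gaussian, normalized to sum 1, radius max(1, ceil(3 sigma))."""
    radius = max(1, ceil(3 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def _gauss(ctx, img: Image, sigma: float):
    if sigma < 0:
        raise DomainError(f"sigma must be non-negative, got {sigma}")
    out = _like(img)
    if sigma == 0:
        out.write_block((0,) * img.ndim, img.to_array())
        return out
    data = img.to_array().astype(np.float64)
    kernel = gaussian_kernel(sigma)
    for axis in range(img.ndim):
        data = _scipy_ndimage.correlate1d(data, kernel, axis=axis,
                                          mode="mirror")
    _store_result(out, data)
    return out


FILTER_GAUSS = OpDescriptor(
    id="filter.gauss#separable", name="filter.gauss",
    params=(Param("img", Image), Param("sigma", float, primary=False)),
    output=Image, func=_gauss, aliases=("gauss",))


def _dog(ctx, img: Image, sigma1: float, sigma2: float):
    # Deliberately a chain of existing ops, not a bespoke kernel.
    blurred1 = ctx.ops.run("filter.gauss", img, sigma1)
    blurred2 = ctx.ops.run("filter.gauss", img, sigma2)
    return ctx.ops.run("math.sub", blurred1, blurred2)


IMAGE_DOG = OpDescriptor(
    id="image.dog#chained", name="image.dog",
    params=(Param("img", Image), Param("sigma1", float, primary=False),
            Param("sigma2", float, primary=False)),
    output=Image, func=_dog, aliases=("dog",),
    chain=("filter.gauss", "filter.gauss", "math.sub"))


# ---------------------------------------------------------------------------
# statistics

def _block_shape_for(shape, max_samples=1 << 20):
    bs = [1] * len(shape)
    budget = max_samples
    for d in range(len(shape) - 1, -1, -1):
        bs[d] = min(shape[d], max(1, budget))
        budget //= max(1, bs[d])
    return tuple(bs)


def _iter_blocks(img: Image):
    bs = _block_shape_for(img.shape)
    grid = tuple(-(-e // b) for e, b in zip(img.shape, bs))
    for cell in np.ndindex(grid):
        origin = tuple(c * b for c, b in zip(cell, bs))
        extent = tuple(min(b, e - o)
                       for b, e, o in zip(bs, img.shape, origin))
        yield img.read_block(origin, extent)


def _exact_block_sum(block: np.ndarray):
    if block.dtype == object:
        return sum(block.ravel().tolist())
    if block.dtype.kind in "ui":
        return int(block.sum(dtype=np.object_)) if block.dtype.itemsize == 8 \
            else int(block.sum(dtype=np.int64))
    return float(block.sum(dtype=np.float64)) if block.dtype.kind == "f" \
        else complex(block.sum())


def _stats_sum(ctx, img: Image):
    total = 0
    for block in _iter_blocks(img):
        total += _exact_block_sum(block)
    return total


def _stats_size(ctx, img: Image):
    return prod(img.shape)


def _stats_min(ctx, img: Image):
    best = None
    for block in _iter_blocks(img):
        m = min(block.ravel().tolist()) if block.dtype == object \
            else block.min().item()
        best = m if best is None else min(best, m)
    return best


def _stats_max(ctx, img: Image):
    best = None
    for block in _iter_blocks(img):
        m = max(block.ravel().tolist()) if block.dtype == object \
            else block.max().item()
        best = m if best is None else max(best, m)
    return best


def _stats_mean(ctx, img: Image):
    # Composition: mean = div(sum, size).
    total = ctx.ops.run("stats.sum", img)
    count = ctx.ops.run("stats.size", img)
    return ctx.ops.run("math.div", float(total), float(count))


def _roi_values(img: Image, roi: MaskROI):
    values = [v for _, v in img.iterate(roi)]
    if not values:
        raise DomainError("empty ROI")
    return values


def _stats_sum_roi(ctx, img, roi):
    return sum(_roi_values(img, roi))


def _stats_size_roi(ctx, img, roi):
    return len(_roi_values(img, roi))


def _stats_min_roi(ctx, img, roi):
    return min(_roi_values(img, roi))


def _stats_max_roi(ctx, img, roi):
    return max(_roi_values(img, roi))


def _stats_mean_roi(ctx, img, roi):
    values = _roi_values(img, roi)
    return ctx.ops.run("math.div", float(sum(values)), float(len(values)))


def _stats_descriptor(family, func, with_roi=False):
    params = (Param("img", Image),) if not with_roi else \
        (Param("img", Image), Param("roi", MaskROI, primary=False))
    suffix = "#roi" if with_roi else "#whole"
    return OpDescriptor(
        id=f"stats.{family}{suffix}", name=f"stats.{family}",
        params=params, output=object, func=func, aliases=(family,))


STATS_SUM = _stats_descriptor("sum", _stats_sum)
STATS_SIZE = _stats_descriptor("size", _stats_size)
STATS_MIN = _stats_descriptor("min", _stats_min)
STATS_MAX = _stats_descriptor("max", _stats_max)
STATS_MEAN = OpDescriptor(
    id="stats.mean#composed", name="stats.mean",
    params=(Param("img", Image),), output=float, func=_stats_mean,
    aliases=("mean",), chain=("stats.sum", "stats.size", "math.div"))
STATS_SUM_ROI = _stats_descriptor("sum", _stats_sum_roi, with_roi=True)
STATS_SIZE_ROI = _stats_descriptor("size", _stats_size_roi, with_roi=True)
STATS_MIN_ROI = _stats_descriptor("min", _stats_min_roi, with_roi=True)
STATS_MAX_ROI = _stats_descriptor("max", _stats_max_roi, with_roi=True)
STATS_MEAN_ROI = OpDescriptor(
    id="stats.mean#roi", name="stats.mean",
    params=(Param("img", Image), Param("roi", MaskROI, primary=False)),
    output=float, func=_stats_mean_roi, aliases=("mean",))


# ---------------------------------------------------------------------------
# map, eval, create

def _map(ctx, img: Image, op: SpecialOp):
    if op.arity != 1:
        raise DomainError("image.map requires a unary special op")
    out = _like(img)
    t = out.sample_type
    expected = op.primary_types[0]
    for coords, v in img.iterate():
        if not isinstance(v, expected):
            v = ctx.convert.convert(v, expected)
        out.set(coords, clamp_cast(op(v), FLOAT64, t))
    return out


IMAGE_MAP = OpDescriptor(
    id="image.map#special-op", name="image.map",
    params=(Param("img", Image), Param("op", SpecialOp, primary=False)),
    output=Image, func=_map, aliases=("map",))


def _eval(ctx, expr: str):
    return ctx.ops.eval(expr)


def _eval_bound(ctx, expr: str, bindings: dict):
    return ctx.ops.eval(expr, bindings)


SCRIPT_EVAL = OpDescriptor(
    id="script.eval#expr", name="script.eval",
    params=(Param("expr", str),), output=object,
    func=_eval, aliases=("eval",))
SCRIPT_EVAL_BOUND = OpDescriptor(
    id="script.eval#expr-bindings", name="script.eval",
    params=(Param("expr", str), Param("bindings", dict, primary=False)),
    output=object, func=_eval_bound, aliases=("eval",))


def _create_img(ctx, sample_type: SampleType, shape: tuple):
    return create_image(sample_type, shape, "array")


CREATE_IMG = OpDescriptor(
    id="create.img#zeros", name="create.img",
    params=(Param("type", SampleType, primary=False),
            Param("shape", tuple, primary=False)),
    output=Image, func=_create_img, aliases=("create",))


#: All shipped op descriptors, in registration order.
BUILTIN_OPS = tuple(_MATH_DESCRIPTORS) + (
    MATH_SQRT_IMG, MATH_SQRT_IMG_ARRAY, MATH_SQRT_SCALAR,
    MATH_IDENTITY_SCALAR,
    FILTER_GAUSS, IMAGE_DOG,
    STATS_SUM, STATS_SIZE, STATS_MIN, STATS_MAX, STATS_MEAN,
    STATS_SUM_ROI, STATS_SIZE_ROI, STATS_MIN_ROI, STATS_MAX_ROI,
    STATS_MEAN_ROI,
    IMAGE_MAP, SCRIPT_EVAL, SCRIPT_EVAL_BOUND, CREATE_IMG,
)
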