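"""N-dimensional image containers, datasets, ROIs and synthetic fixtures.

Four storage layouts share one access contract (coordinate reads/writes plus
row-major iteration, last dimension fastest):

``array``
    One contiguous buffer; bounded to fewer than 2^31 samples.
``planar``
    One buffer per 2D plane of the first two dimensions.
``cell``
    Block-partitioned storage with a bounded number of resident cells;
    least-recently-used cells are evicted to a backing block store and
    transparently reloaded — a writeable virtual stack.
``function``
    Samples computed on demand from coordinates; read-only, so extents may
    reach 2^63−1 without any allocation.

A :class:`Dataset` couples an image with named, physically calibrated axes and
optional per-channel LUT references. :class:`MaskROI` selects samples by a
predicate restricted to a bounding box.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from math import prod
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    BoundsError, CapacityError, DomainError, ImmutabilityError, MetadataError,
)
from .io.blockstore import open_block_store
from .types import (
    ARGB, BOOLEAN, COMPLEX, REAL, SIGNED_INT, UNSIGNED_INT, SampleType,
)

MAX_EXTENT = 2 ** 63 - 1
_ARRAY_LIMIT = 2 ** 31  # samples addressable by a single in-memory buffer


def storage_dtype(t: SampleType):
    """The numpy dtype used to hold samples of ``t`` in memory; ``object``
    for arbitrary-precision and >64-bit types."""
    if t.kind == UNSIGNED_INT or t.kind == ARGB:
        for bits, dt in ((8, np.uint8), (16, np.uint16), (32, np.uint32),
                         (64, np.uint64)):
            if t.bits <= bits:
                return np.dtype(dt)
        return np.dtype(object)
    if t.kind == SIGNED_INT:
        for bits, dt in ((8, np.int8), (16, np.int16), (32, np.int32),
                         (64, np.int64)):
            if t.bits <= bits:
                return np.dtype(dt)
        return np.dtype(object)
    if t.kind == BOOLEAN:
        return np.dtype(np.uint8)
    if t.kind == REAL:
        return np.dtype(np.float32 if t.bits == 32 else np.float64)
    if t.kind == COMPLEX:
        return np.dtype(np.complex64 if t.bits == 64 else np.complex128)
    return np.dtype(object)


def _validate_shape(shape) -> tuple[int, ...]:
    shape = tuple(int(e) for e in shape)
    if len(shape) < 1:
        raise DomainError("images require at least one dimension")
    for d, extent in enumerate(shape):
        if not (1 <= extent <= MAX_EXTENT):
            raise BoundsError(
                f"extent {extent} of dimension {d} outside [1, 2^63-1]",
                dimension=d)
    return shape


@dataclass(frozen=True)
class MaskROI:
    """Region of interest: a coordinate predicate restricted to a closed
    per-dimension bounding box ``[(min0,max0), ...]``."""

    bounding_box: tuple
    predicate: Callable[[tuple], bool] = field(default=lambda coords: True)

    def contains(self, coords) -> bool:
        for c, (lo, hi) in zip(coords, self.bounding_box):
            if c < lo or c > hi:
                return False
        return bool(self.predicate(tuple(coords)))


class Image:
    """Container contract: shape, sample type, layout, access, iteration."""

    layout = "abstract"

    def __init__(self, sample_type: SampleType, shape):
        self.sample_type = sample_type
        self.shape = _validate_shape(shape)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def size(self) -> int:
        return prod(self.shape)

    # -- access ------------------------------------------------------------

    def _check_coords(self, coords):
        if len(coords) != self.ndim:
            raise BoundsError(
                f"expected {self.ndim} coordinates, got {len(coords)}")
        for d, (c, extent) in enumerate(zip(coords, self.shape)):
            if c < 0 or c >= extent:
                raise BoundsError(
                    f"coordinate {c} outside [0,{extent - 1}] in dimension {d}",
                    dimension=d)

    def _check_value(self, value):
        t = self.sample_type
        if t.kind == COMPLEX:
            return complex(value)
        if isinstance(value, complex):
            raise DomainError(f"complex value {value} not storable in {t.name}")
        if t.kind == REAL:
            return float(value)
        iv = int(value)
        if iv != value:
            raise DomainError(
                f"non-integer value {value} not storable in {t.name}")
        if t.bounded and not (t.min <= iv <= t.max):
            raise DomainError(
                f"value {iv} outside [{t.min},{t.max}] for {t.name}")
        return iv

    def get(self, coords):
        raise NotImplementedError

    def set(self, coords, value):
        raise NotImplementedError

    def access(self, coords, new_value=None):
        """Combined accessor: read when ``new_value`` is None, else write and
        return the written value."""
        if new_value is None:
            return self.get(coords)
        self.set(coords, new_value)
        return self.get(coords)

    # -- bulk --------------------------------------------------------------

    def read_block(self, origin, block_shape) -> np.ndarray:
        """Materialize a rectangular region as an ndarray (row-major)."""
        out = np.empty(tuple(block_shape), dtype=storage_dtype(self.sample_type))
        for offset in np.ndindex(tuple(block_shape)):
            out[offset] = self.get(tuple(o + c for o, c in zip(origin, offset)))
        return out

    def write_block(self, origin, block: np.ndarray) -> None:
        for offset in np.ndindex(block.shape):
            self.set(tuple(o + c for o, c in zip(origin, offset)),
                     block[offset].item() if hasattr(block[offset], "item")
                     else block[offset])

    def to_array(self) -> np.ndarray:
        return self.read_block((0,) * self.ndim, self.shape)

    # -- iteration ---------------------------------------------------------

    def iterate(self, roi: Optional[MaskROI] = None):
        """Yield ``(coords, value)`` in row-major order (last dimension
        fastest); with a ROI, only coordinates inside it, same order."""
        if roi is None:
            for coords in np.ndindex(self.shape):
                yield coords, self.get(coords)
            return
        lows = []
        highs = []
        for d, (lo, hi) in enumerate(roi.bounding_box):
            lows.append(max(0, lo))
            highs.append(min(self.shape[d] - 1, hi))
        if any(lo > hi for lo, hi in zip(lows, highs)):
            return
        box_shape = tuple(hi - lo + 1 for lo, hi in zip(lows, highs))
        for offset in np.ndindex(box_shape):
            coords = tuple(lo + o for lo, o in zip(lows, offset))
            if roi.contains(coords):
                yield coords, self.get(coords)

    def __repr__(self):
        return (f"<{type(self).__name__} {self.sample_type.name} "
                f"{'x'.join(map(str, self.shape))} layout={self.layout}>")


class ArrayImage(Image):
    """Single contiguous buffer."""

    layout = "array"

    def __init__(self, sample_type, shape, data: np.ndarray | None = None):
        super().__init__(sample_type, shape)
        plane = prod(self.shape[:2]) if self.ndim >= 2 else self.shape[0]
        if plane >= _ARRAY_LIMIT or self.size >= _ARRAY_LIMIT:
            raise CapacityError(
                f"array layout cannot address {self.size} samples "
                f"(>= 2^31); use the cell or function layout")
        if data is None:
            data = np.zeros(self.shape, dtype=storage_dtype(sample_type))
        self._data = data

    def get(self, coords):
        self._check_coords(coords)
        v = self._data[tuple(coords)]
        return v.item() if hasattr(v, "item") else v

    def set(self, coords, value):
        self._check_coords(coords)
        self._data[tuple(coords)] = self._check_value(value)

    def read_block(self, origin, block_shape):
        idx = tuple(slice(o, o + e) for o, e in zip(origin, block_shape))
        return self._data[idx].copy()

    def write_block(self, origin, block):
        idx = tuple(slice(o, o + e) for o, e in zip(origin, block.shape))
        self._data[idx] = block


class PlanarImage(Image):
    """One buffer per 2D plane of the first two dimensions."""

    layout = "planar"

    def __init__(self, sample_type, shape):
        super().__init__(sample_type, shape)
        if self.ndim < 2:
            self._plane_shape = (self.shape[0],)
            self._rest = ()
        else:
            self._plane_shape = self.shape[:2]
            self._rest = self.shape[2:]
        if prod(self._plane_shape) >= _ARRAY_LIMIT:
            raise CapacityError(
                f"planar layout cannot address {prod(self._plane_shape)} "
                f"samples per plane (>= 2^31); use the cell layout")
        n_planes = prod(self._rest) if self._rest else 1
        dtype = storage_dtype(sample_type)
        self._planes = [np.zeros(self._plane_shape, dtype=dtype)
                        for _ in range(n_planes)]

    def _plane_index(self, coords):
        idx = 0
        for c, extent in zip(coords[2:], self._rest):
            idx = idx * extent + c
        return idx

    def get(self, coords):
        self._check_coords(coords)
        v = self._planes[self._plane_index(coords)][tuple(coords[:2])]
        return v.item() if hasattr(v, "item") else v

    def set(self, coords, value):
        self._check_coords(coords)
        self._planes[self._plane_index(coords)][tuple(coords[:2])] = \
            self._check_value(value)

    @property
    def plane_count(self):
        return len(self._planes)


@dataclass
class CellOptions:
    """Configuration of a cell image: block extents, max resident cells, and
    the backing block-store location (None for an in-memory store)."""

    cell_shape: tuple
    capacity: int = 4
    backing: object = None


class CellImage(Image):
    """Block-partitioned image with LRU write-back caching.

    At most ``capacity`` cells are resident; evicting a dirty cell persists it
    to the backing block store, and missing blocks read back as zeros.
    """

    layout = "cell"

    def __init__(self, sample_type, shape, cell_shape, capacity,
                 backing=None):
        super().__init__(sample_type, shape)
        self.cell_shape = tuple(int(c) for c in cell_shape)
        if len(self.cell_shape) != self.ndim:
            raise DomainError("cell shape rank must equal image rank")
        for d, (c, e) in enumerate(zip(self.cell_shape, self.shape)):
            if c < 1 or c > e:
                raise DomainError(
                    f"cell extent {c} invalid for image extent {e} "
                    f"in dimension {d}")
        if capacity < 1:
            raise DomainError("cell capacity must be at least 1")
        self.capacity = int(capacity)
        self.grid_shape = tuple(-(-e // c)
                                for e, c in zip(self.shape, self.cell_shape))
        self.store = open_block_store(backing, sample_type, self.cell_shape)
        self._dtype = storage_dtype(sample_type)
        self._resident: OrderedDict[int, np.ndarray] = OrderedDict()
        self._dirty: set[int] = set()
        self.max_resident = 0
        self.eviction_count = 0

    # -- cache machinery ---------------------------------------------------

    def _cell_linear(self, coords):
        lin = 0
        for c, cs, g in zip(coords, self.cell_shape, self.grid_shape):
            lin = lin * g + c // cs
        return lin

    def _buffer(self, lin) -> np.ndarray:
        resident = self._resident
        buf = resident.get(lin)
        if buf is not None:
            resident.move_to_end(lin)
            return buf
        while len(resident) >= self.capacity:
            old, old_buf = resident.popitem(last=False)
            self.eviction_count += 1
            if old in self._dirty:
                self.store.save_block(old, old_buf)
                self._dirty.discard(old)
        buf = self.store.load_block(lin)
        if buf.dtype != self._dtype:
            buf = buf.astype(self._dtype)
        resident[lin] = buf
        if len(resident) > self.max_resident:
            self.max_resident = len(resident)
        return buf

    @property
    def resident_count(self):
        return len(self._resident)

    def flush(self):
        """Persist all dirty resident cells without evicting them."""
        for lin in sorted(self._dirty):
            self.store.save_block(lin, self._resident[lin])
        self._dirty.clear()

    # -- access ------------------------------------------------------------

    def get(self, coords):
        self._check_coords(coords)
        lin = self._cell_linear(coords)
        local = tuple(c % cs for c, cs in zip(coords, self.cell_shape))
        v = self._buffer(lin)[local]
        return v.item() if hasattr(v, "item") else v

    def set(self, coords, value):
        self._check_coords(coords)
        value = self._check_value(value)
        lin = self._cell_linear(coords)
        local = tuple(c % cs for c, cs in zip(coords, self.cell_shape))
        self._buffer(lin)[local] = value
        self._dirty.add(lin)

    # -- block access (cell-granular; respects capacity and dirtiness) -----

    def _intersecting_cells(self, origin, block_shape):
        lo = tuple(o // cs for o, cs in zip(origin, self.cell_shape))
        hi = tuple((o + e - 1) // cs
                   for o, e, cs in zip(origin, block_shape, self.cell_shape))
        for cell in np.ndindex(tuple(h - l + 1 for l, h in zip(lo, hi))):
            cell_coords = tuple(l + c for l, c in zip(lo, cell))
            cell_origin = tuple(c * cs
                                for c, cs in zip(cell_coords, self.cell_shape))
            a = tuple(max(o, co) for o, co in zip(origin, cell_origin))
            b = tuple(min(o + e, co + cs) for o, e, co, cs in
                      zip(origin, block_shape, cell_origin, self.cell_shape))
            lin = 0
            for c, g in zip(cell_coords, self.grid_shape):
                lin = lin * g + c
            yield lin, cell_origin, a, b

    def read_block(self, origin, block_shape):
        out = np.empty(tuple(block_shape), dtype=self._dtype)
        for lin, cell_origin, a, b in self._intersecting_cells(
                origin, block_shape):
            buf = self._buffer(lin)
            src = tuple(slice(x - co, y - co)
                        for x, y, co in zip(a, b, cell_origin))
            dst = tuple(slice(x - o, y - o)
                        for x, y, o in zip(a, b, origin))
            out[dst] = buf[src]
        return out

    def write_block(self, origin, block):
        block = np.asarray(block)
        for lin, cell_origin, a, b in self._intersecting_cells(
                origin, block.shape):
            buf = self._buffer(lin)
            src = tuple(slice(x - o, y - o)
                        for x, y, o in zip(a, b, origin))
            dst = tuple(slice(x - co, y - co)
                        for x, y, co in zip(a, b, cell_origin))
            buf[dst] = block[src]
            self._dirty.add(lin)


class FunctionImage(Image):
    """Read-only image whose samples are computed from coordinates.

    ``block_fn(origin, shape) -> ndarray`` optionally vectorizes rectangular
    reads so reductions over virtually unbounded images stay block-at-a-time;
    the peak number of samples materialized at once is tracked.
    """

    layout = "function"

    def __init__(self, sample_type, shape, fn, block_fn=None):
        self.sample_type = sample_type
        shape = tuple(int(e) for e in shape)
        for d, extent in enumerate(shape):
            if not (1 <= extent <= MAX_EXTENT):
                raise BoundsError(
                    f"extent {extent} of dimension {d} outside [1, 2^63-1]",
                    dimension=d)
        self.shape = shape
        self.fn = fn
        self.block_fn = block_fn
        self.max_block_samples = 0

    def get(self, coords):
        self._check_coords(coords)
        return self.fn(tuple(coords))

    def set(self, coords, value):
        raise ImmutabilityError("function-backed images are read-only")

    def read_block(self, origin, block_shape):
        n = prod(tuple(block_shape))
        if n > self.max_block_samples:
            self.max_block_samples = n
        if self.block_fn is not None:
            return self.block_fn(tuple(origin), tuple(block_shape))
        return super().read_block(origin, block_shape)


# ---------------------------------------------------------------------------
# Construction


def create_image(sample_type: SampleType, shape, layout: str = "array",
                 cell_opts: CellOptions | None = None) -> Image:
    """Create a zero-initialized image in the requested layout."""
    if layout == "array":
        return ArrayImage(sample_type, shape)
    if layout == "planar":
        return PlanarImage(sample_type, shape)
    if layout == "cell":
        if cell_opts is None:
            raise DomainError("cell layout requires CellOptions")
        return CellImage(sample_type, shape, cell_opts.cell_shape,
                         cell_opts.capacity, cell_opts.backing)
    if layout == "function":
        dtype = storage_dtype(sample_type)
        zero = dtype.type(0).item() if dtype != np.dtype(object) else 0
        return FunctionImage(
            sample_type, shape, lambda coords: zero,
            block_fn=lambda origin, bs: np.zeros(bs, dtype=dtype))
    raise DomainError(f"unknown layout {layout!r}")


def create_cell_image(sample_type, shape, cell_shape, capacity,
                      backing) -> CellImage:
    return CellImage(sample_type, shape, cell_shape, capacity, backing)


def constant_image(sample_type, shape, value) -> FunctionImage:
    """Function-backed constant image; safe at virtually unbounded extents."""
    dtype = storage_dtype(sample_type)
    return FunctionImage(
        sample_type, shape, lambda coords: value,
        block_fn=lambda origin, bs: np.full(bs, value, dtype=dtype))


# ---------------------------------------------------------------------------
# Axes, datasets


_PRESET_AXES = ("X", "Y", "Z", "TIME", "CHANNEL")


@dataclass(frozen=True)
class Axis:
    """A calibrated dimension: preset or custom label, physical unit, and
    scale (physical units per sample; must be positive)."""

    axis_type: str
    unit: str = ""
    scale: float = 1.0

    def __post_init__(self):
        if not self.scale > 0:
            raise MetadataError(f"axis {self.axis_type}: scale must be > 0")

    @property
    def preset(self) -> bool:
        return self.axis_type in _PRESET_AXES


def default_axes(ndim: int) -> list[Axis]:
    """Uncalibrated axes X, Y, Z, TIME, CHANNEL, dim5, dim6, ..."""
    labels = list(_PRESET_AXES) + [f"dim{i}" for i in range(5, ndim)]
    return [Axis(labels[d]) for d in range(ndim)]


@dataclass
class Dataset:
    """An image plus named calibrated axes and per-channel LUT references."""

    image: Image
    axes: list
    name: str = ""
    channel_luts: Optional[list] = None

    def __post_init__(self):
        if len(self.axes) != self.image.ndim:
            raise MetadataError(
                f"axis count {len(self.axes)} does not match image "
                f"dimension count {self.image.ndim}")
        if self.channel_luts is not None:
            extent = self.channel_extent()
            if extent is None:
                raise MetadataError("channel LUTs given but no CHANNEL axis")
            if len(self.channel_luts) != extent:
                raise MetadataError(
                    f"{len(self.channel_luts)} LUTs for channel extent {extent}")

    def channel_extent(self):
        for d, axis in enumerate(self.axes):
            if axis.axis_type == "CHANNEL":
                return self.image.shape[d]
        return None

    def physical_extent(self) -> list[float]:
        """Per-dimension extent in physical units (samples x scale)."""
        return [e * a.scale for e, a in zip(self.image.shape, self.axes)]


def wrap_dataset(image: Image, axes: Sequence[Axis], name: str = "",
                 channel_luts=None) -> Dataset:
    return Dataset(image, list(axes), name, channel_luts)


# ---------------------------------------------------------------------------
# Synthetic fixtures


def _noise_array(t: SampleType, shape, seed):
    rng = np.random.default_rng(seed)
    if t.kind == REAL:
        return rng.random(shape) * 100.0
    if not t.bounded or t.bits is None or t.bits > 64:
        raise DomainError(f"noise fixture unsupported for {t.name}")
    dtype = storage_dtype(t)
    return rng.integers(t.min, t.max, size=shape, endpoint=True, dtype=dtype)


def make_fixture(pattern: str, t: SampleType, shape, layout: str = "array",
                 *, value=None, coord=None, seed=None,
                 cell_opts: CellOptions | None = None) -> Image:
    """Deterministic test images.

    ``constant c``: all samples c. ``gradient``: row-major index, reduced
    modulo (max+1) for bounded integer types. ``impulse``: 1 at ``coord``,
    0 elsewhere. ``noise``: seeded uniform values over the type's range
    (integers for integer types, reals in [0, 100) for real types).
    """
    shape = _validate_shape(shape)
    dtype = storage_dtype(t)
    if pattern == "constant":
        c = 0 if value is None else value
        if t.bounded and not (t.min <= c <= t.max):
            raise DomainError(f"constant {c} outside bounds of {t.name}")
        if layout == "function":
            return constant_image(t, shape, c)
        arr = np.full(shape, c, dtype=dtype)
    elif pattern == "gradient":
        idx = np.arange(prod(shape), dtype=np.int64)
        if t.bounded and t.is_integral:
            idx = idx % (int(t.max) + 1 - int(t.min)) + int(t.min)
        arr = idx.reshape(shape).astype(dtype)
        if layout == "function":
            strides = np.cumprod((1,) + shape[:0:-1])[::-1]

            def grad_fn(coords):
                lin = sum(c * s for c, s in zip(coords, strides))
                if t.bounded and t.is_integral:
                    lin = lin % (t.max + 1 - t.min) + t.min
                return lin

            return FunctionImage(t, shape, grad_fn)
    elif pattern == "impulse":
        if coord is None:
            raise DomainError("impulse fixture requires a coordinate")
        coord = tuple(coord)
        if layout == "function":
            return FunctionImage(
                t, shape, lambda coords: 1 if coords == coord else 0)
        arr = np.zeros(shape, dtype=dtype)
        arr[coord] = 1
    elif pattern == "noise":
        arr = _noise_array(t, shape, seed)
    else:
        raise DomainError(f"unknown fixture pattern {pattern!r}")

    if layout == "array":
        return ArrayImage(t, shape, data=np.ascontiguousarray(arr, dtype=dtype))
    if layout == "function":
        frozen = np.ascontiguousarray(arr, dtype=dtype)
        return FunctionImage(
            t, shape, lambda coords: frozen[coords].item(),
            block_fn=lambda origin, bs: frozen[
                tuple(slice(o, o + e) for o, e in zip(origin, bs))].copy())
    img = create_image(t, shape, layout, cell_opts=cell_opts or CellOptions(
        cell_shape=tuple(min(16, e) for e in shape)))
    img.write_block((0,) * len(shape), arr.astype(dtype))
    return img


def convert_layout(img: Image, layout: str,
                   cell_opts: CellOptions | None = None) -> Image:
    """Copy an image's samples into a different storage layout."""
    arr = img.to_array()
    if layout == "array":
        return ArrayImage(img.sample_type, img.shape, data=arr.copy())
    out = create_image(img.sample_type, img.shape, layout,
                       cell_opts=cell_opts or CellOptions(
                           cell_shape=tuple(min(16, e) for e in img.shape)))
    if layout == "function":
        frozen = arr.copy()
        return FunctionImage(
            img.sample_type, img.shape, lambda coords: frozen[coords].item(),
            block_fn=lambda origin, bs: frozen[
                tuple(slice(o, o + e) for o, e in zip(origin, bs))].copy())
    out.write_block((0,) * img.ndim, arr)
    return out
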