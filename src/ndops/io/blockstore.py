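"""Raw cell-block stores backing disk-cached images.

A block store persists fixed-shape cell buffers under integer linear indices.
The file-backed store writes one ``cell_<index>.blk`` file per cell, whose
contents are the cell's samples in row-major order — bit-packed for bounded
integer types, big-endian IEEE for real/complex types — plus an ``index.txt``
sidecar recording the sample type and cell shape. A never-saved block loads as
zeros. An in-memory variant provides the same contract for transient images.
"""

from __future__ import annotations

import os
from math import prod

import numpy as np

from ..errors import StorageError
from ..types import (
    COMPLEX, REAL, SampleType, bytes_required, pack_samples, unpack_samples,
)
from .location import Location, resolve_location

_REAL_DTYPES = {("real", 32): ">f4", ("real", 64): ">f8",
                ("complex", 64): ">c8", ("complex", 128): ">c16"}


def _codec_dtype(t: SampleType):
    if t.kind == REAL:
        return _REAL_DTYPES[("real", t.bits)]
    if t.kind == COMPLEX:
        return _REAL_DTYPES[("complex", t.bits)]
    return None


def encode_block(samples: np.ndarray, t: SampleType) -> bytes:
    dtype = _codec_dtype(t)
    if dtype is not None:
        return np.ascontiguousarray(samples).astype(dtype).tobytes()
    return pack_samples(np.ascontiguousarray(samples).ravel(), t)


def decode_block(data: bytes, t: SampleType, n: int) -> np.ndarray:
    dtype = _codec_dtype(t)
    if dtype is not None:
        return np.frombuffer(data, dtype=dtype, count=n).astype(dtype[1:])
    return np.array(unpack_samples(data, t, n))


class _BaseStore:
    def __init__(self, sample_type: SampleType, cell_shape):
        self.sample_type = sample_type
        self.cell_shape = tuple(int(c) for c in cell_shape)
        self.samples_per_cell = prod(self.cell_shape)
        self.save_count = 0
        self.load_count = 0

    def save_block(self, index: int, samples: np.ndarray) -> None:
        self.save_count += 1
        self._put(index, encode_block(samples, self.sample_type))

    def load_block(self, index: int) -> np.ndarray:
        self.load_count += 1
        data = self._get(index)
        if data is None:
            return self._zeros()
        return decode_block(data, self.sample_type,
                            self.samples_per_cell).reshape(self.cell_shape)

    def _zeros(self) -> np.ndarray:
        dtype = _codec_dtype(self.sample_type)
        if dtype is not None:
            return np.zeros(self.cell_shape, dtype=dtype[1:])
        if self.sample_type.bits is not None and self.sample_type.bits > 64:
            return np.zeros(self.cell_shape, dtype=object)
        return np.zeros(self.cell_shape, dtype=np.int64)

    def block_count(self) -> int:
        raise NotImplementedError

    def has_block(self, index: int) -> bool:
        raise NotImplementedError


class MemoryBlockStore(_BaseStore):
    """Block store keeping encoded blocks in a dict (transient images)."""

    def __init__(self, sample_type, cell_shape):
        super().__init__(sample_type, cell_shape)
        self._blocks: dict[int, bytes] = {}

    def _put(self, index, data):
        self._blocks[index] = data

    def _get(self, index):
        return self._blocks.get(index)

    def has_block(self, index):
        return index in self._blocks

    def block_count(self):
        return len(self._blocks)


class CellBlockStore(_BaseStore):
    """File-backed block store: one ``cell_<i>.blk`` per cell plus a
    ``key=value`` sidecar (``index.txt``) naming type and cell shape."""

    SIDECAR = "index.txt"

    def __init__(self, location, sample_type: SampleType, cell_shape):
        super().__init__(sample_type, cell_shape)
        loc = resolve_location(location)
        if loc.scheme != "file":
            raise StorageError("file-backed block store requires a file location")
        self.directory = loc.path
        try:
            os.makedirs(self.directory, exist_ok=True)
        except OSError as exc:
            raise StorageError(f"backing not writable: {exc}") from exc
        sidecar = os.path.join(self.directory, self.SIDECAR)
        expected = {
            "type": sample_type.name,
            "cell_shape": ",".join(str(c) for c in self.cell_shape),
        }
        if os.path.exists(sidecar):
            found = {}
            with open(sidecar, "r", encoding="utf-8") as fh:
                for line in fh:
                    key, sep, value = line.rstrip("\n").partition("=")
                    if sep:
                        found[key] = value
            if found != expected:
                raise StorageError(
                    f"sidecar mismatch in {self.directory}: "
                    f"found {found}, expected {expected}")
        else:
            with open(sidecar, "w", encoding="utf-8") as fh:
                for key, value in expected.items():
                    fh.write(f"{key}={value}\n")

    def _path(self, index: int) -> str:
        return os.path.join(self.directory, f"cell_{index}.blk")

    def _put(self, index, data):
        try:
            with open(self._path(index), "wb") as fh:
                fh.write(data)
        except OSError as exc:
            raise StorageError(f"backing not writable: {exc}") from exc

    def _get(self, index):
        path = self._path(index)
        if not os.path.exists(path):
            return None
        with open(path, "rb") as fh:
            return fh.read()

    def has_block(self, index):
        return os.path.exists(self._path(index))

    def block_count(self):
        return sum(1 for name in os.listdir(self.directory)
                   if name.startswith("cell_") and name.endswith(".blk"))


def open_block_store(backing, sample_type: SampleType, cell_shape):
    """Backing of None -> in-memory store; otherwise file-backed under the
    resolved directory location."""
    if backing is None:
        return MemoryBlockStore(sample_type, cell_shape)
    return CellBlockStore(backing, sample_type, cell_shape)
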