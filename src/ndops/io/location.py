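"""Data locations and random-access byte handles.

A :class:`Location` is a descriptor of where bytes live — a file path or a
named in-memory buffer (``bytes:<name>``). A :class:`DataHandle` is a seekable
read/write stream over a location. In-memory buffers live in a process-wide
named registry so that independent handles on one ``bytes:`` location observe
each other's writes, mirroring file semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from ..errors import LocationError

#: Process-wide registry of named in-memory buffers.
_BYTES_REGISTRY: dict[str, bytearray] = {}


def clear_bytes_registry() -> None:
    """Drop all named in-memory buffers (test isolation helper)."""
    _BYTES_REGISTRY.clear()


@dataclass(frozen=True)
class Location:
    scheme: str           # "file" | "bytes"
    spec: str             # file path, or buffer name

    @property
    def path(self) -> str:
        if self.scheme != "file":
            raise LocationError(f"{self} has no filesystem path")
        return self.spec

    def buffer(self) -> bytearray:
        if self.scheme != "bytes":
            raise LocationError(f"{self} has no in-memory buffer")
        return _BYTES_REGISTRY.setdefault(self.spec, bytearray())

    @property
    def name(self) -> str:
        return os.path.basename(self.spec) if self.scheme == "file" else self.spec


def resolve_location(spec) -> Location:
    """Resolve a location spec: plain paths map to the ``file`` scheme,
    ``bytes:<name>`` to the in-memory scheme. Other URI schemes are
    unsupported."""
    if isinstance(spec, Location):
        return spec
    if not isinstance(spec, str) or not spec:
        raise LocationError(f"empty or non-string location spec: {spec!r}")
    if spec.startswith("bytes:"):
        name = spec[len("bytes:"):]
        if not name:
            raise LocationError("bytes: location requires a buffer name")
        return Location("bytes", name)
    if "://" in spec:
        scheme = spec.split("://", 1)[0]
        if scheme == "file":
            return Location("file", spec[len("file://"):])
        raise LocationError(f"unsupported location scheme {scheme!r}")
    return Location("file", spec)


class DataHandle:
    """Random access into a location's raw bytes.

    Maintains ``0 <= position <= length``; reads never cross the end of data
    (a short or empty bytes object signals end-of-data).
    """

    def __init__(self, location: Location, writable: bool):
        self.location = location
        self.writable = writable
        self._pos = 0
        if location.scheme == "bytes":
            self._buf = location.buffer()
            self._file = None
        else:
            path = location.path
            if writable:
                parent = os.path.dirname(os.path.abspath(path))
                if not os.path.isdir(parent):
                    raise FileNotFoundError(
                        f"parent directory does not exist: {parent}")
                mode = "r+b" if os.path.exists(path) else "w+b"
            else:
                if not os.path.exists(path):
                    raise FileNotFoundError(f"no such file: {path}")
                mode = "rb"
            self._file = open(path, mode)
            self._buf = None

    # -- geometry ----------------------------------------------------------

    @property
    def length(self) -> int:
        if self._buf is not None:
            return len(self._buf)
        cur = self._file.tell()
        self._file.seek(0, os.SEEK_END)
        end = self._file.tell()
        self._file.seek(cur)
        return end

    @property
    def position(self) -> int:
        return self._pos

    def seek(self, pos: int) -> None:
        if pos < 0:
            raise LocationError("cannot seek before start of data")
        self._pos = pos

    # -- I/O ---------------------------------------------------------------

    def read(self, n: int = -1) -> bytes:
        if self._buf is not None:
            end = len(self._buf) if n < 0 else min(self._pos + n, len(self._buf))
            start = min(self._pos, len(self._buf))
            data = bytes(self._buf[start:end])
        else:
            self._file.seek(self._pos)
            data = self._file.read(None if n < 0 else n)
        self._pos += len(data)
        return data

    def write(self, data: bytes) -> int:
        if not self.writable:
            raise PermissionError(f"handle on {self.location} is read-only")
        if self._buf is not None:
            if self._pos > len(self._buf):
                self._buf.extend(b"\x00" * (self._pos - len(self._buf)))
            self._buf[self._pos:self._pos + len(data)] = data
        else:
            self._file.seek(self._pos)
            self._file.write(data)
            self._file.flush()
        self._pos += len(data)
        return len(data)

    def close(self) -> None:
        if self._file is not None:
            self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def open_handle(location, writable: bool = False) -> DataHandle:
    return DataHandle(resolve_location(location), writable)
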