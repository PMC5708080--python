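"""Pluggable image formats: detection by magic bytes then suffix, plus the
read/write front end used by the CLI and module harvesting.

Formats register through the plugin manifest (kind ``format``). Detection
prefers leading magic-byte matches over filename suffixes; ties break by
(priority descending, name ascending). Translator plugins (kind
``translator``) are declared as an extension point; no non-identity
translator ships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from ..containers import Dataset
from ..errors import UnknownFormatError
from .location import DataHandle, Location, open_handle, resolve_location
from .netpbm import read_netpbm, write_pgm, write_ppm


@dataclass(frozen=True)
class FormatDescriptor:
    """A registered image format: identification plus codec callables."""

    name: str
    suffixes: tuple
    magic: tuple          # leading byte patterns
    priority: float
    read: Callable        # read(ctx, handle, chunk_rows=None) -> Dataset
    write: Callable       # write(ctx, dataset, handle) -> bytes written

    def __post_init__(self):
        if not self.suffixes and not self.magic:
            raise ValueError(
                f"format {self.name}: needs at least one suffix or magic")


PGM_FORMAT = FormatDescriptor(
    name="pgm", suffixes=(".pgm",), magic=(b"P2", b"P5"), priority=0.0,
    read=read_netpbm, write=write_pgm)

PPM_FORMAT = FormatDescriptor(
    name="ppm", suffixes=(".ppm",), magic=(b"P6",), priority=0.0,
    read=read_netpbm, write=write_ppm)

BUILTIN_FORMATS = (PGM_FORMAT, PPM_FORMAT)


class IOService:
    """Per-context format registry and data I/O front end."""

    KIND = "service.io"

    def __init__(self, ctx=None):
        self.ctx = ctx
        self._formats: list[FormatDescriptor] = []
        if ctx is not None:
            for f in ctx.plugin_payloads("format"):
                self.register(f)

    def register(self, f: FormatDescriptor) -> int:
        self._formats.append(f)
        return len(self._formats)

    def all(self) -> list[FormatDescriptor]:
        return list(self._formats)

    # -- detection ---------------------------------------------------------

    def detect_format(self, location) -> FormatDescriptor:
        loc = resolve_location(location)
        head = b""
        try:
            with open_handle(loc, writable=False) as handle:
                head = handle.read(16)
        except FileNotFoundError:
            pass
        by_magic = [f for f in self._formats
                    if any(head.startswith(m) for m in f.magic) and head]
        if by_magic:
            return sorted(by_magic, key=lambda f: (-f.priority, f.name))[0]
        spec = loc.spec.lower()
        by_suffix = [f for f in self._formats
                     if any(spec.endswith(s) for s in f.suffixes)]
        if by_suffix:
            return sorted(by_suffix, key=lambda f: (-f.priority, f.name))[0]
        raise UnknownFormatError(
            f"no registered format claims {loc}; registered: "
            f"{[f.name for f in self._formats]}")

    def format_named(self, name: str) -> FormatDescriptor:
        for f in self._formats:
            if f.name == name:
                return f
        raise UnknownFormatError(f"no format named {name!r}")

    def _format_for_write(self, loc: Location,
                          format: Optional[str]) -> FormatDescriptor:
        if format is not None:
            return self.format_named(format)
        spec = loc.spec.lower()
        for f in self._formats:
            if any(spec.endswith(s) for s in f.suffixes):
                return f
        raise UnknownFormatError(
            f"cannot infer a format for {loc}; give one explicitly")

    # -- read / write ------------------------------------------------------

    def read_image(self, location, chunk_rows: int | None = None) -> Dataset:
        loc = resolve_location(location)
        fmt = self.detect_format(loc)
        with open_handle(loc, writable=False) as handle:
            return fmt.read(self.ctx, handle, chunk_rows=chunk_rows)

    def write_image(self, dataset: Dataset, location,
                    format: Optional[str] = None) -> int:
        loc = resolve_location(location)
        fmt = self._format_for_write(loc, format)
        if loc.scheme == "bytes":
            loc.buffer().clear()
        elif loc.scheme == "file":
            import os
            if os.path.exists(loc.path):
                os.truncate(loc.path, 0)
        with open_handle(loc, writable=True) as handle:
            return fmt.write(self.ctx, dataset, handle)


def read_image(ctx, location, chunk_rows: int | None = None) -> Dataset:
    return ctx.io.read_image(location, chunk_rows=chunk_rows)


def write_image(ctx, dataset, location, format: Optional[str] = None) -> int:
    return ctx.io.write_image(dataset, location, format=format)
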