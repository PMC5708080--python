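"""Netpbm codecs: PGM (P2 ascii / P5 binary grayscale) and PPM (P6 color).

Readers produce datasets with shape (height, width) — plus a trailing
CHANNEL extent of 3 for PPM — so row-major iteration (last dimension fastest)
matches raster order. A maxval up to 255 yields uint8 samples, up to 65535
yields uint16 stored big-endian, per the Netpbm convention. Binary rasters
are read in configurable row chunks.

Writers emit the canonical form (single ``\\n`` separators, no comments), so
re-writing an unchanged dataset is byte-identical.
"""

from __future__ import annotations

import numpy as np

from ..containers import ArrayImage, Axis, Dataset, Image
from ..errors import FormatError
from ..types import UINT8, UINT16
from .location import DataHandle

DEFAULT_CHUNK_ROWS = 64


def _read_header_tokens(handle: DataHandle, count: int):
    """Read whitespace-separated header tokens, honoring ``#`` comments."""
    tokens = []
    token = b""
    while len(tokens) < count:
        ch = handle.read(1)
        if not ch:
            raise FormatError("truncated header", offset=handle.position)
        if ch == b"#":
            while ch not in (b"\n", b""):
                ch = handle.read(1)
            continue
        if ch.isspace():
            if token:
                tokens.append(token)
                token = b""
            continue
        token += ch
    return tokens


def _parse_dims(handle: DataHandle, with_maxval: bool):
    tokens = _read_header_tokens(handle, 3 if with_maxval else 2)
    try:
        values = [int(t) for t in tokens]
    except ValueError:
        raise FormatError(f"non-numeric header token in {tokens}",
                          offset=handle.position) from None
    width, height = values[0], values[1]
    maxval = values[2] if with_maxval else 1
    if width < 1 or height < 1:
        raise FormatError(f"bad dimensions {width}x{height}",
                          offset=handle.position)
    if not (0 < maxval < 65536):
        raise FormatError(f"maxval {maxval} outside (0, 65536)",
                          offset=handle.position)
    return width, height, maxval


def _sample_type(maxval: int):
    return UINT8 if maxval <= 255 else UINT16


def read_netpbm(ctx, handle: DataHandle,
                chunk_rows: int | None = None) -> Dataset:
    chunk_rows = chunk_rows or DEFAULT_CHUNK_ROWS
    magic = handle.read(2)
    if magic not in (b"P2", b"P5", b"P6"):
        raise FormatError(f"unsupported netpbm magic {magic!r}", offset=0)
    width, height, maxval = _parse_dims(handle, with_maxval=True)
    t = _sample_type(maxval)
    channels = 3 if magic == b"P6" else 1

    if magic == b"P2":
        text = handle.read(-1).split()
        expected = width * height
        if len(text) < expected:
            raise FormatError(
                f"P2 body has {len(text)} samples, expected {expected}",
                offset=handle.position)
        try:
            flat = np.array([int(v) for v in text[:expected]])
        except ValueError:
            raise FormatError("non-numeric P2 sample",
                              offset=handle.position) from None
        if flat.size and (flat.min() < 0 or flat.max() > maxval):
            raise FormatError("P2 sample outside [0, maxval]",
                              offset=handle.position)
        data = flat.reshape(height, width)
    else:
        bytes_per = 1 if maxval <= 255 else 2
        dtype = ">u1" if bytes_per == 1 else ">u2"
        row_bytes = width * channels * bytes_per
        rows = []
        row = 0
        while row < height:
            n = min(chunk_rows, height - row)
            chunk = handle.read(n * row_bytes)
            if len(chunk) < n * row_bytes:
                raise FormatError(
                    f"truncated raster: wanted {n * row_bytes} bytes, "
                    f"got {len(chunk)}", offset=handle.position)
            rows.append(np.frombuffer(chunk, dtype=dtype).reshape(
                n, width * channels))
            row += n
        data = np.concatenate(rows, axis=0)
        if channels == 3:
            data = data.reshape(height, width, 3)
        else:
            data = data.reshape(height, width)

    shape = (height, width) if channels == 1 else (height, width, 3)
    img = ArrayImage(t, shape)
    img.write_block((0,) * len(shape),
                    data.astype(img._data.dtype))
    axes = [Axis("Y"), Axis("X")] + ([Axis("CHANNEL")] if channels == 3 else [])
    return Dataset(img, axes, name=handle.location.name)


def _writable_geometry(ds: Dataset):
    img = ds.image
    if img.ndim == 2:
        return img.shape[1], img.shape[0], 1
    if img.ndim == 3 and ds.channel_extent() == 3 and img.shape[2] == 3:
        return img.shape[1], img.shape[0], 3
    raise FormatError(
        f"dataset of shape {img.shape} (axes "
        f"{[a.axis_type for a in ds.axes]}) is not representable: need 2D "
        f"grayscale or 2D + CHANNEL extent 3")


def _maxval_for(t) -> int:
    if t.name == UINT8.name:
        return 255
    if t.name == UINT16.name:
        return 65535
    raise FormatError(f"netpbm supports uint8/uint16 samples, not {t.name}")


def write_netpbm(ctx, ds: Dataset, handle: DataHandle,
                 ascii_format: bool = False) -> int:
    width, height, channels = _writable_geometry(ds)
    maxval = _maxval_for(ds.image.sample_type)
    if channels == 3:
        magic = b"P6"
        if ascii_format:
            raise FormatError("PPM has no supported ascii variant here")
    else:
        magic = b"P2" if ascii_format else b"P5"
    header = magic + b"\n" + f"{width} {height}".encode() + b"\n" \
        + str(maxval).encode() + b"\n"
    data = ds.image.to_array()
    written = handle.write(header)
    if ascii_format:
        body = "\n".join(" ".join(str(int(v)) for v in row)
                         for row in data) + "\n"
        written += handle.write(body.encode())
    else:
        dtype = ">u1" if maxval <= 255 else ">u2"
        written += handle.write(np.ascontiguousarray(data).astype(
            dtype).tobytes())
    return written


def write_pgm(ctx, ds, handle, **kw):
    width, height, channels = _writable_geometry(ds)
    if channels != 1:
        raise FormatError("PGM stores 2D grayscale only; use PPM for color")
    return write_netpbm(ctx, ds, handle, **kw)


def write_ppm(ctx, ds, handle, **kw):
    width, height, channels = _writable_geometry(ds)
    if channels != 3:
        raise FormatError("PPM stores 3-channel color; use PGM for grayscale")
    return write_netpbm(ctx, ds, handle, **kw)
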