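"""Reading and writing hyperspectral cubes in the ENVI format.

ENVI stores a cube as a flat binary file plus a small plain-text header
(``key = value`` pairs, lists in braces).  Three interleaves are in use:

* ``bil`` -- band interleaved by line, layout ``(lines, bands, samples)``
* ``bip`` -- band interleaved by pixel, layout ``(lines, samples, bands)``
* ``bsq`` -- band sequential, layout ``(bands, lines, samples)``

The module exposes the cube as an ordered stream of :class:`LineBlock`
objects (one cross-track line at a time, a ``bands x samples`` matrix in
acquisition order) so that a denoiser can run without the whole image in
memory, and an :class:`EnviWriter` that appends one line at a time so the
output file exists incrementally during a streaming run.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "EnviError",
    "TruncatedFileError",
    "HypercubeHeader",
    "LineBlock",
    "read_header",
    "stream_lines",
    "read_cube",
    "read_raw",
    "write_lines",
    "write_cube",
    "EnviWriter",
]

#: ENVI numeric "data type" codes -> numpy dtypes.
ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    6: np.complex64,
    9: np.complex128,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
    15: np.uint64,
}
DTYPE_CODES = {np.dtype(v): k for k, v in ENVI_DTYPES.items()}

INTERLEAVES = ("bil", "bip", "bsq")

_MANDATORY_KEYS = ("lines", "samples", "bands", "interleave", "data type")


class EnviError(ValueError):
    """Malformed ENVI header or inconsistent cube file."""


class TruncatedFileError(EnviError):
    """Cube file smaller than the header promises."""


@dataclass
class HypercubeHeader:
    """Shape and storage metadata of an ENVI cube.

    ``lines`` is the along-track (scan) axis, ``samples`` the cross-track
    axis, ``bands`` the spectral axis.  Indices are 0-based throughout.
    """

    lines: int
    samples: int
    bands: int
    interleave: str = "bil"
    data_type: int = 4
    byte_order: int = 0
    header_offset: int = 0
    wavelengths: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("lines", "samples", "bands"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise EnviError(f"{name} must be a positive integer, got {v!r}")
        self.interleave = str(self.interleave).lower()
        if self.interleave not in INTERLEAVES:
            raise EnviError(f"unknown interleave {self.interleave!r}")
        if self.data_type not in ENVI_DTYPES:
            raise EnviError(f"unsupported ENVI data type code {self.data_type}")
        if self.byte_order not in (0, 1):
            raise EnviError(f"byte order must be 0 or 1, got {self.byte_order}")
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.shape != (self.bands,):
                raise EnviError(
                    f"wavelength list length {wl.size} != bands {self.bands}"
                )
            if not np.all(np.diff(wl) > 0):
                raise EnviError("wavelengths must be strictly increasing")
            self.wavelengths = wl

    @property
    def dtype(self) -> np.dtype:
        base = np.dtype(ENVI_DTYPES[self.data_type])
        return base.newbyteorder(">" if self.byte_order else "<")

    @property
    def line_nbytes(self) -> int:
        return self.bands * self.samples * self.dtype.itemsize

    @property
    def cube_nbytes(self) -> int:
        return self.lines * self.line_nbytes

    def replace(self, **kw) -> "HypercubeHeader":
        d = dict(
            lines=self.lines,
            samples=self.samples,
            bands=self.bands,
            interleave=self.interleave,
            data_type=self.data_type,
            byte_order=self.byte_order,
            header_offset=self.header_offset,
            wavelengths=None if self.wavelengths is None else self.wavelengths.copy(),
            extra=dict(self.extra),
        )
        d.update(kw)
        return HypercubeHeader(**d)


@dataclass
class LineBlock:
    """One cross-track line: ``values`` is a bands x samples matrix."""

    line_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("LineBlock values must be a 2-D bands x samples array")

    @property
    def bands(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# header parsing / writing


def _parse_header_text(text: str) -> dict:
    """Parse ENVI ``key = value`` text into a flat dict of strings.

    Brace-delimited lists may span multiple lines; values keep their raw
    textual form so unknown keys round-trip unchanged.
    """
    body = text
    if body.lstrip().upper().startswith("ENVI"):
        body = body.lstrip()[4:]
    entries: dict = {}
    # fold multi-line brace groups onto single lines
    folded = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in folded.splitlines():
        line = line.strip()
        if not line or line.startswith(";") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        entries[key.strip().lower()] = value.strip()
    return entries


def _parse_brace_list(value: str) -> list:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    return [tok.strip() for tok in inner.split(",") if tok.strip()]


def _header_from_entries(entries: dict) -> HypercubeHeader:
    missing = [k for k in _MANDATORY_KEYS if k not in entries]
    if missing:
        raise EnviError(f"header missing mandatory key(s): {', '.join(missing)}")
    known = {
        "lines",
        "samples",
        "bands",
        "interleave",
        "data type",
        "byte order",
        "header offset",
        "wavelength",
    }
    wl = None
    if "wavelength" in entries:
        wl = np.array([float(x) for x in _parse_brace_list(entries["wavelength"])])
    return HypercubeHeader(
        lines=int(entries["lines"]),
        samples=int(entries["samples"]),
        bands=int(entries["bands"]),
        interleave=entries["interleave"],
        data_type=int(entries["data type"]),
        byte_order=int(entries.get("byte order", 0)),
        header_offset=int(entries.get("header offset", 0)),
        wavelengths=wl,
        extra={k: v for k, v in entries.items() if k not in known},
    )


def _header_text(header: HypercubeHeader) -> str:
    lines = [
        "ENVI",
        f"samples = {header.samples}",
        f"lines = {header.lines}",
        f"bands = {header.bands}",
        f"header offset = {header.header_offset}",
        "file type = ENVI Standard",
        f"data type = {header.data_type}",
        f"interleave = {header.interleave}",
        f"byte order = {header.byte_order}",
    ]
    if header.wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in header.wavelengths)
        lines.append("wavelength = { " + wl + " }")
    for key, value in header.extra.items():
        if key == "file type":
            continue
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def _find_header_path(path: os.PathLike) -> Path:
    p = Path(path)
    if p.suffix.lower() == ".hdr" and p.exists():
        return p
    candidates = [Path(str(p) + ".hdr"), p.with_suffix(".hdr")]
    for c in candidates:
        if c.exists():
            return c
    raise FileNotFoundError(f"no ENVI header found for {p}")


def _find_data_path(path: os.PathLike, hdr_path: Path) -> Path:
    p = Path(path)
    if p.suffix.lower() != ".hdr":
        if p.exists():
            return p
        raise FileNotFoundError(f"cube file not found: {p}")
    stem = Path(str(hdr_path)[: -len(".hdr")])
    candidates = [stem] + [stem.with_suffix(s) for s in (".img", ".raw", ".dat", ".bil")]
    for c in candidates:
        if c.exists() and c != hdr_path:
            return c
    raise FileNotFoundError(f"no cube file found next to header {hdr_path}")


def read_header(path: os.PathLike) -> HypercubeHeader:
    """Parse the ENVI header for *path* (a ``.hdr`` file or a cube with sidecar)."""
    hdr_path = _find_header_path(path)
    return _header_from_entries(_parse_header_text(hdr_path.read_text()))


# ---------------------------------------------------------------------------
# reading


def _open_memmap(data_path: Path, header: HypercubeHeader) -> np.ndarray:
    expected = header.header_offset + header.cube_nbytes
    actual = data_path.stat().st_size
    if actual < expected:
        raise TruncatedFileError(
            f"{data_path}: file has {actual} bytes, header promises {expected}"
        )
    if actual > expected:
        raise EnviError(
            f"{data_path}: file has {actual} bytes, header promises {expected}"
        )
    flat = np.memmap(
        data_path, dtype=header.dtype, mode="r", offset=header.header_offset
    )
    L, P, B = header.lines, header.samples, header.bands
    shapes = {"bil": (L, B, P), "bip": (L, P, B), "bsq": (B, L, P)}
    return flat.reshape(shapes[header.interleave])


def stream_lines(
    path: os.PathLike, header: Optional[HypercubeHeader] = None
) -> Iterator[LineBlock]:
    """Yield the cube at *path* one :class:`LineBlock` at a time, in scan order.

    Memory per step is one line (bands x samples); the full cube is never
    materialised on this path (a read-only memmap backs the file).
    """
    if header is None:
        header = read_header(path)
    p = Path(path)
    if p.suffix.lower() != ".hdr" and p.exists():
        data_path = p
    else:
        data_path = _find_data_path(path, _find_header_path(path))
    mm = _open_memmap(data_path, header)
    for i in range(header.lines):
        if header.interleave == "bil":
            values = np.array(mm[i])  # (B, P)
        elif header.interleave == "bip":
            values = np.array(mm[i].T)
        else:  # bsq
            values = np.array(mm[:, i, :])
        yield LineBlock(i, np.ascontiguousarray(values))


def read_cube(path: os.PathLike, header: Optional[HypercubeHeader] = None):
    """Read a whole cube into a ``(lines, samples, bands)`` array.

    Convenience for batch processing and tests; the streaming path should
    use :func:`stream_lines`.
    """
    if header is None:
        header = read_header(path)
    out = np.empty((header.lines, header.samples, header.bands), dtype=header.dtype)
    for block in stream_lines(path, header):
        out[block.line_index] = block.values.T
    return out, header


def read_raw(
    path: os.PathLike,
    lines: int,
    samples: int,
    bands: int,
    dtype="float32",
    interleave: str = "bil",
) -> Iterator[LineBlock]:
    """Headerless fallback: stream a raw binary cube given an explicit shape."""
    code = DTYPE_CODES[np.dtype(dtype)]
    header = HypercubeHeader(
        lines=lines, samples=samples, bands=bands, interleave=interleave, data_type=code
    )
    data_path = Path(path)
    if not data_path.exists():
        raise FileNotFoundError(str(data_path))
    mm = _open_memmap(data_path, header)
    for i in range(lines):
        if interleave == "bil":
            values = np.array(mm[i])
        elif interleave == "bip":
            values = np.array(mm[i].T)
        else:
            values = np.array(mm[:, i, :])
        yield LineBlock(i, np.ascontiguousarray(values))


# ---------------------------------------------------------------------------
# writing


class EnviWriter:
    """Append-per-line ENVI cube writer.

    The header is written up front so the output is a valid (partial) cube at
    every point of a streaming run.  If the writer is closed before the
    promised number of lines has been written, the header is rewritten with
    the actual count (and, for BSQ, the band blocks are compacted in place).
    Closing after zero lines raises, since a 0-line cube is not representable.
    """

    def __init__(self, path: os.PathLike, header: HypercubeHeader):
        if header.byte_order != 0:
            raise EnviError("writer only emits little-endian (byte order 0) cubes")
        self.header = header.replace(header_offset=0)
        self.data_path = Path(path)
        self.hdr_path = Path(str(path) + ".hdr")
        self._written = 0
        self._closed = False
        self.hdr_path.write_text(_header_text(self.header))
        self._f = open(self.data_path, "w+b")
        if self.header.interleave == "bsq":
            self._f.truncate(self.header.cube_nbytes)

    def write_line(self, block) -> None:
        values = block.values if isinstance(block, LineBlock) else np.asarray(block)
        B, P = self.header.bands, self.header.samples
        if values.shape != (B, P):
            raise EnviError(f"line shape {values.shape} != ({B}, {P})")
        if self._written >= self.header.lines:
            raise EnviError("more lines written than the header promises")
        arr = np.ascontiguousarray(values, dtype=self.header.dtype)
        itemsize = arr.dtype.itemsize
        if self.header.interleave == "bil":
            self._f.write(arr.tobytes())
        elif self.header.interleave == "bip":
            self._f.write(np.ascontiguousarray(arr.T).tobytes())
        else:  # bsq: one seek per band
            L = self.header.lines
            for b in range(B):
                self._f.seek((b * L + self._written) * P * itemsize)
                self._f.write(arr[b].tobytes())
        self._written += 1

    def close(self) -> None:
        if self._closed:
            return
        if self._written == 0:
            self._f.close()
            self._closed = True
            raise EnviError("no lines written; cube is empty")
        if self._written < self.header.lines:
            self._shrink_to_written()
        self._f.close()
        self._closed = True

    def _shrink_to_written(self) -> None:
        n, L = self._written, self.header.lines
        B, P = self.header.bands, self.header.samples
        itemsize = self.header.dtype.itemsize
        row = P * itemsize
        if self.header.interleave == "bsq":
            # compact: band b rows move from offset b*L to b*n; destinations
            # never overtake sources because n < L, so a forward copy is safe
            for b in range(B):
                for i in range(n):
                    self._f.seek((b * L + i) * row)
                    data = self._f.read(row)
                    self._f.seek((b * n + i) * row)
                    self._f.write(data)
            self._f.truncate(B * n * row)
        self.header = self.header.replace(lines=n)
        self.hdr_path.write_text(_header_text(self.header))

    def __enter__(self) -> "EnviWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        # propagate the original exception rather than masking it with the
        # empty-cube error
        if exc_type is not None and self._written == 0:
            self._f.close()
            self._closed = True
            return
        self.close()


def write_lines(
    path: os.PathLike, header: HypercubeHeader, blocks: Iterable
) -> HypercubeHeader:
    """Write *blocks* (LineBlocks or bands x samples arrays) to an ENVI cube.

    Returns the header actually written (line count may be lower than
    promised if the iterable ran short).
    """
    with EnviWriter(path, header) as w:
        for block in blocks:
            w.write_line(block)
    return w.header


def write_cube(
    path: os.PathLike,
    cube: np.ndarray,
    wavelengths=None,
    interleave: str = "bil",
    data_type: int = 4,
) -> HypercubeHeader:
    """Write a ``(lines, samples, bands)`` array as an ENVI cube."""
    cube = np.asarray(cube)
    L, P, B = cube.shape
    header = HypercubeHeader(
        lines=L,
        samples=P,
        bands=B,
        interleave=interleave,
        data_type=data_type,
        wavelengths=wavelengths,
    )
    return write_lines(path, header, (cube[i].T for i in range(L)))
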