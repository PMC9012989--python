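"""Temperature-grid data model, raw file dialect, and grayscale standardization.

A thermal camera frame is a dense 2-D grid of skin/background temperatures in
degrees Celsius. This module defines the in-memory container
(:class:`TemperatureField`), a lossless little-endian integer file dialect for
moving grids between pipeline stages (``.tgrid``), and the adaptive
temperature-window grayscale render used to standardize display intensity
before clustering: the window width ``tfw`` is fixed at 10 °C and the window
start ``tfs`` floats with the hottest pixel, so every frame is drawn with the
same rule regardless of the subject's absolute temperature.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    TemperatureRangeError,
)

__all__ = [
    "TemperatureField",
    "RawGridDialect",
    "RenderParams",
    "read_temperature_grid",
    "write_temperature_grid",
    "auto_render_params",
    "render_grayscale",
    "export_png",
    "export_csv",
]

#: Default frame geometry: 256 rows by 336 columns.
DEFAULT_ROWS = 256
DEFAULT_COLS = 336


@dataclass(frozen=True)
class RawGridDialect:
    """Bit-exact dialect of the raw ``.tgrid`` file.

    Layout: an 8-byte header of ``rows`` then ``cols`` as little-endian
    uint32, followed by ``rows*cols`` little-endian uint16 values in
    row-major order. Each stored integer is ``round(temperature * scale)``,
    so the default ``scale=100`` stores centi-degrees and round-trips any
    in-range temperature to 0.01 °C.
    """

    scale: int = 100

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"dialect scale must be positive, got {self.scale}")


@dataclass
class TemperatureField:
    """A rows x cols grid of temperatures in °C.

    Coordinates are 0-based ``(row, col)`` with the origin at the top-left.
    After background filtering, background cells are exactly 0.0 °C.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise FormatError(f"temperature grid must be non-empty 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FormatError("temperature grid contains non-finite values")
        self.values = arr

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def body_mask(self) -> np.ndarray:
        """Boolean mask of nonzero (non-background) cells."""
        return self.values != 0.0

    def copy(self) -> "TemperatureField":
        return TemperatureField(self.values.copy())


@dataclass(frozen=True)
class RenderParams:
    """Temperature window mapping °C to display intensity.

    ``tfw`` — temperature-forming width (window span, °C, > 0);
    ``tfs`` — temperature-forming start (window lower edge, °C).
    """

    tfw: float
    tfs: float

    def __post_init__(self) -> None:
        if not self.tfw > 0:
            raise ParameterError(f"tfw must be positive, got {self.tfw}")


_HEADER = struct.Struct("<II")


def write_temperature_grid(fld: TemperatureField, path, dialect: RawGridDialect = RawGridDialect()) -> None:
    """Write a field to ``path`` in the raw dialect.

    Raises :class:`TemperatureRangeError` if any ``round(value*scale)`` falls
    outside the uint16 range [0, 65535].
    """
    counts = np.rint(fld.values * dialect.scale)
    if counts.min() < 0 or counts.max() > 65535:
        bad = fld.values.flat[int(np.argmax((counts < 0) | (counts > 65535)))]
        raise TemperatureRangeError(
            f"temperature {bad!r} °C not representable as uint16 at scale {dialect.scale}"
        )
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(fld.rows, fld.cols))
        fh.write(counts.astype("<u2").tobytes())


def read_temperature_grid(path, dialect: RawGridDialect = RawGridDialect()) -> TemperatureField:
    """Read a raw-dialect grid; inverse of :func:`write_temperature_grid`."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER.size)
        if len(header) < _HEADER.size:
            raise FormatError(f"{path}: truncated header ({len(header)} bytes)")
        rows, cols = _HEADER.unpack(header)
        if rows == 0 or cols == 0:
            raise FormatError(f"{path}: non-positive dimensions {rows}x{cols}")
        payload = fh.read()
    expected = rows * cols * 2
    if len(payload) != expected:
        raise FormatError(
            f"{path}: payload is {len(payload)} bytes, expected {expected} for {rows}x{cols}"
        )
    counts = np.frombuffer(payload, dtype="<u2").reshape(rows, cols)
    return TemperatureField(counts.astype(np.float64) / dialect.scale)


def auto_render_params(fld: TemperatureField, tfw: float = 10.0) -> RenderParams:
    """Adaptive render window: ``tfs = max(values) - tfw`` with ``tfw`` fixed.

    Ties every frame's display window to its own hottest pixel so all frames
    are standardized by the same rule. Raises on an all-zero field, which has
    no meaningful maximum.
    """
    if not np.any(fld.values != 0.0):
        raise DegenerateInputError("cannot derive render params from an all-zero field")
    return RenderParams(tfw=tfw, tfs=float(fld.values.max()) - tfw)


def render_grayscale(fld: TemperatureField, params: RenderParams) -> np.ndarray:
    """Map temperatures to gray levels 0-255.

    ``gray = round(255 * clamp((T - tfs)/tfw, 0, 1))`` with round-half-up, so
    the mapping is deterministic across platforms and monotonically
    non-decreasing in T.
    """
    frac = np.clip((fld.values - params.tfs) / params.tfw, 0.0, 1.0)
    # round-half-up, not banker's rounding
    return np.floor(255.0 * frac + 0.5).astype(np.uint8)


def export_png(fld: TemperatureField, path, params: RenderParams | None = None) -> None:
    """Save the grayscale render as a PNG (debug/visualization aid)."""
    import imageio.v3 as iio

    if params is None:
        params = auto_render_params(fld)
    iio.imwrite(path, render_grayscale(fld, params))


def export_csv(fld: TemperatureField, path) -> None:
    """Dump the raw temperatures as CSV for debugging."""
    np.savetxt(path, fld.values, fmt="%.2f", delimiter=",")
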