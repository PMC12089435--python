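"""Fluence maps on a beamlet grid: data model, ASCII I/O, resampling.

The beam's-eye-view fluence map is a 2-D array of non-negative beam
intensities on a regular beamlet grid, by default 1 mm x 1 mm at the
isocenter plane.  ``x`` is the leaf-travel direction, ``y`` the direction
of the bank translation.  Cell ``(i, j)`` (0-based, ``values[j, i]``)
covers the half-open rectangle ``[x0+i*dx, x0+(i+1)*dx) x
[y0+j*dy, y0+(j+1)*dy)``.

A map is either *relative* (unitless, typically normalized to max 1, as a
treatment planning system emits it) or expressed in monitor units (MU,
proportional to beam-on time at fixed dose rate); :func:`scale_to_mu`
converts the former to the latter.

File format: a minimal self-describing ASCII dialect -- ``key = value``
header lines for ``x0 y0 dx dy nx ny units`` followed by ``ny`` rows of
``nx`` whitespace- or comma-separated numbers, bottom row first.  Lines
starting with ``#`` are comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import IO, Iterable

import numpy as np

from .errors import DegenerateInputError, FluenceFormatError, ValidationError

#: on read, intensities below this fraction of the map maximum are clamped
#: to zero so numerical dust never opens a leaf pair
DUST_FRACTION = 1e-9

_HEADER_FIELDS = ("x0", "y0", "dx", "dy", "nx", "ny")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a beamlet grid (isocenter-plane millimetres)."""

    x0: float = 0.0  #: left edge, mm
    y0: float = 0.0  #: bottom edge, mm
    dx: float = 1.0  #: beamlet width along leaf travel, mm
    dy: float = 1.0  #: beamlet height along bank travel, mm
    nx: int = 1
    ny: int = 1

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "dx", "dy"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("nx", "ny"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if not (self.dx > 0 and self.dy > 0):
            raise ValidationError(f"dx and dy must be > 0, got ({self.dx}, {self.dy})")
        if not (self.nx >= 1 and self.ny >= 1):
            raise ValidationError(f"nx and ny must be >= 1, got ({self.nx}, {self.ny})")

    # -- derived coordinates ------------------------------------------------
    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.ny + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.dx * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.dy * (np.arange(self.ny) + 0.5)

    @property
    def x_max(self) -> float:
        return self.x0 + self.nx * self.dx

    @property
    def y_max(self) -> float:
        return self.y0 + self.ny * self.dy

    def close_to(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Spatial co-registration test (same frame, shape and spacing)."""
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass(frozen=True)
class FluenceGrid:
    """A validated fluence map: grid spec + non-negative intensity array.

    ``units`` is ``"relative"`` for unitless TPS output or ``"MU"`` once
    scaled to monitor units.  The value array is copied and made read-only.
    """

    spec: GridSpec
    values: np.ndarray
    units: str = "relative"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (self.spec.ny, self.spec.nx):
            raise ValidationError(
                f"value array shape {arr.shape} does not match grid "
                f"(ny, nx) = ({self.spec.ny}, {self.spec.nx})"
            )
        if not np.all(np.isfinite(arr)):
            j, i = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(f"non-finite fluence at cell (i={i}, j={j})")
        if np.any(arr < 0):
            j, i = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative fluence {arr[j, i]} at cell (i={i}, j={j})"
            )
        if self.units not in ("relative", "MU"):
            raise ValidationError(f"units must be 'relative' or 'MU', got {self.units!r}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def max(self) -> float:
        return float(self.values.max())

    def with_values(self, values: np.ndarray, units: str | None = None) -> "FluenceGrid":
        return FluenceGrid(self.spec, values, self.units if units is None else units)


# ---------------------------------------------------------------------------
# I/O


def read_fluence(source: IO[str] | str) -> FluenceGrid:
    """Parse a fluence map from a text stream (or a string) in the ASCII
    dialect written by :func:`write_fluence`.

    Intensities below ``DUST_FRACTION`` of the map maximum are clamped to
    zero.  Raises :class:`FluenceFormatError` on malformed input and
    :class:`ValidationError` on negative/non-finite values.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    header: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line and not rows:
            key, _, val = line.partition("=")
            header[key.strip().lower()] = val.strip()
        else:
            try:
                rows.append(np.array(line.replace(",", " ").split(), dtype=float))
            except ValueError as exc:
                raise FluenceFormatError(f"unparseable data row: {line!r}") from exc
    if not header and not rows:
        raise FluenceFormatError("empty fluence stream")
    missing = [f for f in _HEADER_FIELDS if f not in header]
    if missing:
        raise FluenceFormatError(f"header missing field(s): {', '.join(missing)}")
    try:
        spec = GridSpec(
            x0=float(header["x0"]),
            y0=float(header["y0"]),
            dx=float(header["dx"]),
            dy=float(header["dy"]),
            nx=int(header["nx"]),
            ny=int(header["ny"]),
        )
    except ValueError as exc:
        raise FluenceFormatError(f"bad header value: {exc}") from exc
    units = header.get("units", "relative")
    if len(rows) != spec.ny:
        raise FluenceFormatError(f"expected {spec.ny} data rows, found {len(rows)}")
    if any(len(r) != spec.nx for r in rows):
        bad = next(j for j, r in enumerate(rows) if len(r) != spec.nx)
        raise FluenceFormatError(
            f"row {bad} has {len(rows[bad])} values, expected nx = {spec.nx}"
        )
    values = np.vstack(rows)
    grid = FluenceGrid(spec, values, units)  # validates sign/finiteness
    if grid.max > 0:
        clamped = np.where(values < DUST_FRACTION * grid.max, 0.0, values)
        grid = FluenceGrid(spec, clamped, units)
    return grid


def write_fluence(grid: FluenceGrid, sink: IO[str]) -> None:
    """Emit ``grid`` in the dialect :func:`read_fluence` accepts.

    Values are printed with 9 significant digits, lossless round-trip at
    well beyond the 6-digit contract.
    """
    s = grid.spec
    sink.write(
        f"x0 = {s.x0!r}\ny0 = {s.y0!r}\ndx = {s.dx!r}\ndy = {s.dy!r}\n"
        f"nx = {s.nx}\nny = {s.ny}\nunits = {grid.units}\n"
    )
    for row in grid.values:
        sink.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def fluence_to_string(grid: FluenceGrid) -> str:
    buf = io.StringIO()
    write_fluence(grid, buf)
    return buf.getvalue()


def write_fluence_csv(grid: FluenceGrid, sink: IO[str]) -> None:
    """Plain CSV export of the value array (bottom row first), for
    spreadsheet inspection; not re-readable by :func:`read_fluence`."""
    for row in grid.values:
        sink.write(",".join(f"{v:.9g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# resampling / scaling


def upsample_rows(grid: FluenceGrid, factor: int) -> FluenceGrid:
    """Replicate each row ``factor`` times and divide ``dy`` accordingly.

    Intensity values are per-beamlet and unchanged, so the integrated
    fluence sum(values)*dx*dy is conserved exactly.  Needed because the
    bank moves in sub-beamlet (0.25 mm) steps on a 1 mm fluence grid.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValidationError(f"upsample factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return grid
    s = grid.spec
    new_spec = replace(s, dy=s.dy / factor, ny=s.ny * factor)
    return FluenceGrid(new_spec, np.repeat(grid.values, factor, axis=0), grid.units)


def scale_to_mu(grid: FluenceGrid, total_mu: float) -> FluenceGrid:
    """Convert a relative map to monitor units so that max(values) == total_mu.

    The maximum-intensity beamlet then requires ``total_mu`` of beam-on
    time, mirroring how a relative optimal fluence map is tied to the
    prescribed field MU.
    """
    if grid.units == "MU":
        raise ValidationError("grid already in MU units")
    if total_mu <= 0:
        raise ValidationError(f"total_mu must be > 0, got {total_mu}")
    if grid.max <= 0:
        raise DegenerateInputError("cannot scale an all-zero fluence map to MU")
    return FluenceGrid(grid.spec, grid.values * (total_mu / grid.max), "MU")


def integrated_fluence(grid: FluenceGrid) -> float:
    """sum(values * dx * dy) -- the conserved quantity under row resampling."""
    return float(grid.values.sum() * grid.spec.dx * grid.spec.dy)
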