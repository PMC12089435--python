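"""Deterministic synthetic optimal fluence maps.

Clinical optimal fluence maps are not bundled with the package, so test
and evaluation inputs are generated: binary or smoothly modulated target
shapes on a 1 mm beamlet grid, with the target's bottom edge placed at a
controlled sub-leaf-width phase ``y_offset`` relative to the 5 mm leaf
boundaries.  That phase is the key randomized parameter -- the whole
benefit of the y-axis bank translation lives within one leaf width of
the target border, so a fair suite must sample every edge placement.

Two regimes mirror the clinical size classes studied with this
technique: ``small`` targets 20-30 mm tall (head & neck / lung scale,
where the bank offset helps most) and ``large`` targets 60-80 mm tall
(liver scale, where the sub-leaf-width effect is diluted).  Suite maps
are modulated ellipses: blob-like cross-sections with smooth intensity
texture are the realistic stand-in for TPS output, while rectangles are
kept as exactly analysable calibration shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .grid import FluenceGrid, GridSpec

#: leaf boundary pitch the y_offset phase is defined against, mm
LEAF_PITCH = 5.0

SHAPES = ("rectangle", "ellipse", "two_lobe", "modulated")

REGIMES = {
    # y extent (mm), x extent (mm)
    "small": {"y_extent": (20.0, 30.0), "x_extent": (30.0, 50.0)},
    "large": {"y_extent": (60.0, 80.0), "x_extent": (60.0, 80.0)},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic optimal fluence map.

    ``y_offset`` shifts the target's bottom edge by that many mm above
    the nearest 5 mm leaf boundary; ``modulation_depth`` in [0, 1)
    multiplies the support by smoothed seeded noise rescaled to
    [1 - depth, 1].  The same (spec, grid) always yields the identical
    map.
    """

    shape: str
    x_extent: float
    y_extent: float
    y_offset: float = 0.0
    modulation_depth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValidationError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.x_extent <= 0 or self.y_extent <= 0:
            raise ValidationError("target extents must be > 0")
        if not 0 <= self.modulation_depth < 1:
            raise ValidationError("modulation_depth must be in [0, 1)")


def _support_mask(spec: FixtureSpec, grid: GridSpec, ylo: float) -> np.ndarray:
    xc = grid.x_centers[None, :]
    yc = grid.y_centers[:, None]
    cx = grid.x0 + grid.nx * grid.dx / 2.0
    cy = ylo + spec.y_extent / 2.0
    a, b = spec.x_extent / 2.0, spec.y_extent / 2.0
    if spec.shape in ("rectangle", "modulated"):
        return (np.abs(xc - cx) < a) & (yc >= ylo) & (yc < ylo + spec.y_extent)
    if spec.shape == "ellipse":
        return ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2 <= 1.0
    # two_lobe: a full-height lobe beside a 60 %-height one, with a gap
    a1 = a * 0.35
    m1 = ((xc - (cx - a * 0.55)) / a1) ** 2 + ((yc - cy) / b) ** 2 <= 1.0
    m2 = ((xc - (cx + a * 0.55)) / a1) ** 2 + ((yc - cy) / (0.6 * b)) ** 2 <= 1.0
    return m1 | m2


def generate_fixture(spec: FixtureSpec, grid: GridSpec) -> FluenceGrid:
    """Render a fixture recipe onto a beamlet grid (relative units, max 1).

    The target is centred in x; its bottom edge sits at the largest 5 mm
    leaf boundary that keeps it vertically centred, plus ``y_offset``.
    Raises if the shape does not fit inside the grid.
    """
    cy = grid.y0 + grid.ny * grid.dy / 2.0
    ylo = LEAF_PITCH * floor((cy - spec.y_extent / 2.0) / LEAF_PITCH) + spec.y_offset
    if (
        spec.x_extent > grid.nx * grid.dx
        or ylo < grid.y0
        or ylo + spec.y_extent > grid.y_max
    ):
        raise ValidationError(
            f"target {spec.x_extent} x {spec.y_extent} mm at ylo={ylo} does not "
            f"fit the grid x:[{grid.x0}, {grid.x_max}] y:[{grid.y0}, {grid.y_max}]"
        )
    mask = _support_mask(spec, grid, ylo)
    values = mask.astype(float)
    if spec.modulation_depth > 0 or spec.shape == "modulated":
        depth = spec.modulation_depth
        rng = np.random.default_rng(spec.seed)
        noise = gaussian_filter(rng.standard_normal(mask.shape), sigma=3.0 / grid.dx)
        lo, hi = noise[mask].min(), noise[mask].max()
        unit = (noise - lo) / (hi - lo) if hi > lo else np.zeros_like(noise)
        values = mask * (1.0 - depth + depth * unit)
    return FluenceGrid(grid, values, "relative")


def worked_rectangle(x_extent: int = 40, value: float = 1.0) -> FluenceGrid:
    """The canonical mis-aligned calibration target: a uniform rectangle
    spanning the full grid width and y in [2.5, 27.5) mm -- 25 mm tall
    with both edges half a leaf width off the 5 mm leaf boundaries, the
    worst case for a conventional x-only MLC and exactly correctable by a
    +2.5 mm bank offset.  The grid starts at y0 = -0.5 so its 1 mm rows
    land on the half-integer target edges."""
    spec = GridSpec(x0=0.0, y0=-0.5, dx=1.0, dy=1.0, nx=int(x_extent), ny=33)
    vals = np.zeros((33, int(x_extent)))
    vals[3:28, :] = value  # row j covers [j - 0.5, j + 0.5): rows 3..27 -> [2.5, 27.5)
    return FluenceGrid(spec, vals, "relative")


def _suite_grid(x_extent: float, y_extent: float) -> GridSpec:
    """A per-map grid with 10 mm x-margins and 15 mm y-margins, centred
    on the origin (inside the fine-resolution 5 mm leaf region)."""
    nx = int(ceil(x_extent)) + 20
    ny = int(ceil(y_extent)) + 30
    return GridSpec(x0=-(nx // 2), y0=-(ny // 2), dx=1.0, dy=1.0, nx=nx, ny=ny)


def generate_suite(
    n: int, regime: str, seed: int = 0
) -> tuple[list[FluenceGrid], list[FixtureSpec]]:
    """Generate ``n`` seeded suite maps for a size regime.

    Extents are drawn uniformly from the regime's ranges, the sub-leaf
    edge phase ``y_offset`` uniformly from [0, 5) mm, and the modulation
    depth uniformly from [0.1, 0.4].  Returns the maps and their recipes
    (for provenance / regeneration).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if regime not in REGIMES:
        raise ValidationError(f"regime must be one of {tuple(REGIMES)}, got {regime!r}")
    r = REGIMES[regime]
    rng = np.random.default_rng(seed)
    grids, specs = [], []
    for _ in range(n):
        spec = FixtureSpec(
            shape="ellipse",
            x_extent=float(rng.uniform(*r["x_extent"])),
            y_extent=float(rng.uniform(*r["y_extent"])),
            y_offset=float(rng.uniform(0.0, LEAF_PITCH)),
            modulation_depth=float(rng.uniform(0.1, 0.4)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
        grids.append(generate_fixture(spec, _suite_grid(spec.x_extent, spec.y_extent)))
    return grids, specs
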