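"""Multileaf collimator geometry, machine configuration, and the mapping
of fluence rows onto leaf pairs.

The collimator is a stack of opposing leaf pairs; pair ``k`` at bank
offset ``s`` blocks everything outside its open interval within the band
``y in [Y_k + s, Y_k + w_k + s)`` where ``Y_k = y_min + sum(w_m, m<k)``.
The default layout is the Varian Millennium-120: 60 pairs, 10 outer pairs
of 10 mm on each side and 40 central pairs of 5 mm, centred so the 5 mm
pairs span -100..+100 mm.

Leaves are modelled with zero transmission: a closed pair delivers
nothing, leakage and rounded-end penumbra are out of model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import yaml

from .errors import ResolutionError, ValidationError
from .grid import FluenceGrid

log = logging.getLogger(__name__)

#: in "max" aggregation a fluence row counts toward a pair when the
#: pair/row overlap is at least this fraction of the row height
MIN_OVERLAP_FRACTION = 0.1


@dataclass(frozen=True)
class MLCGeometry:
    """Leaf-pair widths (bottom to top) and travel limits, in mm."""

    pair_widths: tuple[float, ...]
    y_min: float = -200.0
    x_travel_min: float = -200.0
    x_travel_max: float = 200.0

    def __post_init__(self) -> None:
        if len(self.pair_widths) == 0 or any(w <= 0 for w in self.pair_widths):
            raise ValidationError("all leaf-pair widths must be > 0")
        if self.x_travel_min >= self.x_travel_max:
            raise ValidationError("x_travel_min must be < x_travel_max")
        object.__setattr__(self, "pair_widths", tuple(float(w) for w in self.pair_widths))

    @classmethod
    def millennium120(cls) -> "MLCGeometry":
        """Millennium-120 layout: 10x10 mm, 40x5 mm, 10x10 mm leaf pairs."""
        widths = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
        return cls(pair_widths=widths, y_min=-200.0)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_widths)

    @property
    def min_width(self) -> float:
        return min(self.pair_widths)

    @property
    def y_lower_edges(self) -> np.ndarray:
        """Lower band edges Y_k at zero offset."""
        return self.y_min + np.concatenate(([0.0], np.cumsum(self.pair_widths)[:-1]))

    def to_dict(self) -> dict:
        return {
            "pair_widths": list(self.pair_widths),
            "y_min": self.y_min,
            "x_travel_min": self.x_travel_min,
            "x_travel_max": self.x_travel_max,
        }


@dataclass(frozen=True)
class MachineConfig:
    """Delivery machine parameters.

    dose_rate : MU/min.  max_leaf_speed : mm/s (``inf`` allowed for the
    idealized unconstrained-speed case).  total_mu : MU scaling applied to
    relative fluence maps before sequencing.
    """

    dose_rate: float = 600.0
    max_leaf_speed: float = 25.0
    total_mu: float = 500.0

    def __post_init__(self) -> None:
        if not self.dose_rate > 0:
            raise ValidationError(f"dose_rate must be > 0, got {self.dose_rate}")
        if not self.max_leaf_speed > 0:
            raise ValidationError(f"max_leaf_speed must be > 0, got {self.max_leaf_speed}")
        if not self.total_mu > 0:
            raise ValidationError(f"total_mu must be > 0, got {self.total_mu}")

    @property
    def v_mu(self) -> float:
        """Leaf speed in the MU domain, mm per MU (inf if speed is inf)."""
        return self.max_leaf_speed * 60.0 / self.dose_rate

    def mu_per_step(self, dx: float) -> float:
        """Minimum MU needed to traverse one beamlet of width dx (tau)."""
        v = self.v_mu
        return 0.0 if math.isinf(v) else dx / v

    def to_dict(self) -> dict:
        return {
            "dose_rate": self.dose_rate,
            "max_leaf_speed": self.max_leaf_speed,
            "total_mu": self.total_mu,
        }


def load_config(path: str | Path | IO[str]) -> tuple[MLCGeometry, MachineConfig]:
    """Read geometry + machine configuration from a YAML file.

    Recognized top-level keys: ``geometry`` (pair_widths, y_min,
    x_travel_min, x_travel_max) and ``machine`` (dose_rate,
    max_leaf_speed, total_mu).  Missing keys fall back to the
    Millennium-120 / 600 MU/min defaults.
    """
    if hasattr(path, "read"):
        data = yaml.safe_load(path) or {}
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    gdata = data.get("geometry", {}) or {}
    mdata = data.get("machine", {}) or {}
    default = MLCGeometry.millennium120()
    geometry = MLCGeometry(
        pair_widths=tuple(gdata.get("pair_widths", default.pair_widths)),
        y_min=float(gdata.get("y_min", default.y_min)),
        x_travel_min=float(gdata.get("x_travel_min", default.x_travel_min)),
        x_travel_max=float(gdata.get("x_travel_max", default.x_travel_max)),
    )
    machine = MachineConfig(
        dose_rate=float(mdata.get("dose_rate", 600.0)),
        max_leaf_speed=float(mdata.get("max_leaf_speed", 25.0)),
        total_mu=float(mdata.get("total_mu", 500.0)),
    )
    return geometry, machine


# ---------------------------------------------------------------------------
# geometry queries


def pair_boundaries(geometry: MLCGeometry, offset: float = 0.0) -> np.ndarray:
    """Per-pair ``(y_low, y_high)`` bands at the given bank offset.

    The bank translates rigidly, so every band is shifted by ``offset``;
    the bands are contiguous, ordered and non-overlapping by construction.
    Returns an (n_pairs, 2) array.
    """
    lo = geometry.y_lower_edges + offset
    hi = lo + np.asarray(geometry.pair_widths)
    return np.column_stack([lo, hi])


def aggregate_pair_profiles(
    fluence: FluenceGrid,
    geometry: MLCGeometry,
    offset: float = 0.0,
    mode: str = "max",
) -> np.ndarray:
    """Reduce fluence rows to one 1-D target profile per leaf pair.

    The optimal fluence map is defined on rows finer than the leaf width
    (1 mm rows vs 5 mm leaves), so each pair's sliding-window target must
    be built from the rows its aperture band overlaps at the given bank
    offset.  Two reductions are provided:

    ``max``
        a row counts if its overlap with the band is at least
        ``MIN_OVERLAP_FRACTION`` of the row height; the profile is the
        per-column maximum over counted rows.  A pair therefore opens
        wherever *any* covered row demands fluence -- this over-covers the
        target superiorly/inferiorly, which is exactly the behaviour the
        bank-offset optimization corrects.
    ``coverage_weighted_mean``
        the overlap-length-weighted mean, conserving integrated fluence
        across the reduction (sum_k profile_k * w_k == sum_j values_j * dy
        column-wise).

    Returns an (n_pairs, nx) array; pairs overlapping no nonzero row get
    an all-zero profile.
    """
    if mode not in ("max", "coverage_weighted_mean"):
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    dy = fluence.spec.dy
    if dy > geometry.min_width + 1e-12:
        raise ResolutionError(
            f"fluence row height {dy} mm exceeds the minimum leaf width "
            f"{geometry.min_width} mm; apply upsample_rows first"
        )
    bands = pair_boundaries(geometry, offset)  # (np, 2)
    y_bot = fluence.spec.y_edges[:-1]  # (ny,)
    y_top = fluence.spec.y_edges[1:]
    # overlap length between each pair band and each row: (np, ny)
    ov = np.clip(
        np.minimum(bands[:, 1:2], y_top[None, :]) - np.maximum(bands[:, 0:1], y_bot[None, :]),
        0.0,
        None,
    )
    vals = fluence.values  # (ny, nx)
    if mode == "max":
        counted = ov >= MIN_OVERLAP_FRACTION * dy  # (np, ny)
        profiles = np.zeros((geometry.n_pairs, fluence.spec.nx))
        for k in np.nonzero(counted.any(axis=1))[0]:
            profiles[k] = vals[counted[k]].max(axis=0)
    else:
        widths = np.asarray(geometry.pair_widths)[:, None]
        profiles = (ov @ vals) / widths
    return profiles
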