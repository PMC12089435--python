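"""Sliding-window leaf sequencing.

Converts per-pair 1-D fluence profiles (in MU) into leaf *arrival times*
on the monitor-unit clock and merges all pairs into one synchronized
control-point sequence.

For one pair the open aperture sweeps left to right; the right leaf is
the leading (opening) edge, the left leaf the trailing (closing) edge.
The exposure a point receives equals the MU elapsing between the leading
leaf uncovering it and the trailing leaf covering it, so for a profile
``PHI(i)`` at beamlet centres the arrival MUs obey, with minimum per-
beamlet step ``tau = dx / v_MU`` and ``D = PHI(i+1) - PHI(i)``::

    D >= 0:  R(i+1) = R(i) + tau          L(i+1) = R(i+1) + PHI(i+1)
    D <  0:  L(i+1) = L(i) + tau          R(i+1) = L(i+1) - PHI(i+1)

initialized with ``R(0) = 0``, ``L(0) = PHI(0)``.  Rising fluence slows
the leading leaf (the trailing leaf follows at top speed); falling
fluence slows the trailing leaf.  Both branches collapse to the closed
form ``R(i) = i*tau + cumsum(max(0, -D))`` and ``L = R + PHI``, which is
what the implementation computes; the delivered gap ``L - R`` reproduces
the profile exactly at every beamlet centre by construction.

Multiple pairs share a single global MU clock (one beam, one MU counter):
the field's total MU is the slowest pair's final trailing-leaf arrival,
and pairs finishing early hold at their final position.  Sector-wise bank
offsets are delivered as consecutive sweeps concatenated on the MU clock,
with the bank translation happening during a beam hold (a pair of
control points at the same cumulative MU).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np

from .errors import PlanError, ValidationError
from .grid import FluenceGrid
from .mlc import MachineConfig, MLCGeometry, aggregate_pair_profiles

log = logging.getLogger(__name__)

#: control points closer than this on the MU axis are merged
MU_MERGE_TOL = 1e-6


@dataclass(frozen=True)
class PairTrajectory:
    """Arrival MUs of one pair's leaves at successive beamlet centres.

    ``arrival_right`` is the leading (opening) leaf, ``arrival_left`` the
    trailing (closing) one; ``arrival_left - arrival_right`` is the
    delivered profile.
    """

    arrival_right: np.ndarray
    arrival_left: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.arrival_right, float)
        l = np.asarray(self.arrival_left, float)
        if r.shape != l.shape or r.ndim != 1:
            raise ValidationError("arrival arrays must be 1-D and equally long")
        object.__setattr__(self, "arrival_right", r)
        object.__setattr__(self, "arrival_left", l)

    @property
    def total_mu(self) -> float:
        return float(self.arrival_left[-1])

    @property
    def delivered(self) -> np.ndarray:
        return self.arrival_left - self.arrival_right


@dataclass
class MLCSequence:
    """Synchronized control-point sequence for the whole field.

    ``mu`` is non-decreasing from 0 to ``total_mu``; equal consecutive
    values occur only at sector transitions (beam holds, during which the
    bank offset and leaf positions change with the beam off).  Leaf
    positions are per pair, mm; ``left <= right`` everywhere and a closed
    pair has ``left == right``.  ``bank_offset[i]`` is the offset in
    effect on the interval ``[mu[i], mu[i+1])``.
    """

    mu: np.ndarray  # (n,)
    left: np.ndarray  # (n, n_pairs)
    right: np.ndarray  # (n, n_pairs)
    bank_offset: np.ndarray  # (n,)
    total_mu: float
    geometry: MLCGeometry
    machine: MachineConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.left = np.atleast_2d(np.asarray(self.left, float))
        self.right = np.atleast_2d(np.asarray(self.right, float))
        self.bank_offset = np.asarray(self.bank_offset, float)
        n = self.mu.size
        if self.left.shape != (n, self.geometry.n_pairs) or self.right.shape != self.left.shape:
            raise ValidationError("position arrays must be (n_control_points, n_pairs)")
        if np.any(np.diff(self.mu) < -1e-9):
            raise ValidationError("cumulative MU must be non-decreasing")
        if np.any(self.left > self.right + 1e-9):
            raise ValidationError("left leaf position exceeds right leaf position")

    @property
    def n_control_points(self) -> int:
        return self.mu.size


# ---------------------------------------------------------------------------
# single-pair sequencing


def sequence_pair_profile(
    profile: np.ndarray, dx: float, machine: MachineConfig
) -> PairTrajectory:
    """Sequence one pair's MU profile into leaf arrival times.

    Implements the sliding-window recurrence documented in the module
    docstring via its closed form.  A profile of zeros yields a valid
    closed sweep (``arrival_left == arrival_right``).
    """
    phi = np.asarray(profile, dtype=float)
    if phi.ndim != 1 or phi.size == 0:
        raise ValidationError("profile must be a non-empty 1-D array")
    if np.any(phi < 0) or not np.all(np.isfinite(phi)):
        bad = int(np.argwhere((phi < 0) | ~np.isfinite(phi))[0, 0])
        raise ValidationError(f"invalid profile value {phi[bad]} at beamlet {bad}")
    tau = machine.mu_per_step(dx)
    drop = np.maximum(0.0, -np.diff(phi))
    arrival_right = tau * np.arange(phi.size) + np.concatenate(([0.0], np.cumsum(drop)))
    arrival_left = arrival_right + phi
    return PairTrajectory(arrival_right=arrival_right, arrival_left=arrival_left)


def _merge_mus(mus: np.ndarray, tol: float = MU_MERGE_TOL) -> np.ndarray:
    """Sorted unique MU values with near-duplicates (within tol) collapsed."""
    mus = np.sort(np.asarray(mus, float))
    if mus.size == 0:
        return mus
    keep = np.concatenate(([True], np.diff(mus) > tol))
    return mus[keep]


def synchronize_pairs(
    trajectories: Mapping[int, PairTrajectory],
    geometry: MLCGeometry,
    machine: MachineConfig,
    bank_offset: float,
    x_centers: np.ndarray,
    dx: float | None = None,
) -> MLCSequence:
    """Merge per-pair trajectories (all on the same x grid) onto one
    global MU clock.

    ``trajectories`` maps pair index -> trajectory; pairs without an
    entry are parked closed at ``x_travel_min``.  Control points are
    emitted at every distinct arrival MU (merged within ``MU_MERGE_TOL``),
    with every leaf's position linearly interpolated on its own
    position-vs-MU polyline.

    Each polyline is extended half a beamlet on both sides of the sweep
    (``tau/2`` extra on the MU axis each): the pair starts closed at
    ``first centre - dx/2`` and finishes closed at ``last centre + dx/2``,
    so the aperture genuinely crosses every beamlet centre it must
    expose.  Without the extension the leaves would start and stop
    exactly on the outermost cell centres and strict-containment
    reconstruction would starve those beamlets.  Pairs finishing before
    the global total MU hold closed at the sweep's right edge, and the
    extensions stay inside the outer half-beamlets so consecutive sector
    sweeps never overlap.
    """
    if not trajectories:
        raise ValidationError("at least one pair trajectory is required")
    x_centers = np.asarray(x_centers, float)
    if dx is None:
        dx = float(x_centers[1] - x_centers[0]) if x_centers.size > 1 else 1.0
    for tr in trajectories.values():
        if tr.arrival_right.size != x_centers.size:
            raise ValidationError("trajectory length does not match x grid")
    edge_mu = max(machine.mu_per_step(dx) / 2.0, MU_MERGE_TOL)
    x_ext = np.concatenate(
        ([x_centers[0] - dx / 2.0], x_centers, [x_centers[-1] + dx / 2.0])
    )
    ext: dict[int, tuple[np.ndarray, np.ndarray]] = {
        k: (
            np.concatenate(
                ([0.0], t.arrival_right + edge_mu, [t.arrival_right[-1] + 2 * edge_mu])
            ),
            np.concatenate(
                ([0.0], t.arrival_left + edge_mu, [t.arrival_left[-1] + 2 * edge_mu])
            ),
        )
        for k, t in trajectories.items()
    }
    total = float(max(t.total_mu for t in trajectories.values()) + edge_mu)
    all_mus = np.concatenate([np.concatenate(pair) for pair in ext.values()])
    mus = _merge_mus(np.concatenate([all_mus, [0.0, total]]))
    mus = mus[mus <= total + MU_MERGE_TOL]
    mus[0], mus[-1] = 0.0, total

    n = mus.size
    left = np.full((n, geometry.n_pairs), geometry.x_travel_min)
    right = np.full((n, geometry.n_pairs), geometry.x_travel_min)
    for k, (arr_r, arr_l) in ext.items():
        # np.interp on the (monotone) arrival polyline; holds at the ends
        right[:, k] = np.interp(mus, arr_r, x_ext)
        left[:, k] = np.interp(mus, arr_l, x_ext)
    return MLCSequence(
        mu=mus,
        left=left,
        right=right,
        bank_offset=np.full(n, float(bank_offset)),
        total_mu=total,
        geometry=geometry,
        machine=machine,
    )


# ---------------------------------------------------------------------------
# whole-field sequencing


def _sector_columns(spec, edges: np.ndarray) -> list[np.ndarray]:
    """Column indices per sector; validates that the edges cover the grid."""
    edges = np.asarray(edges, float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise PlanError("sector edges must be a strictly increasing 1-D list")
    if edges[0] > spec.x0 + 1e-9 or edges[-1] < spec.x_max - 1e-9:
        raise PlanError(
            f"sector edges [{edges[0]}, {edges[-1]}] do not cover the fluence "
            f"x-range [{spec.x0}, {spec.x_max}]"
        )
    xc = spec.x_centers
    cols = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        cols.append(np.nonzero((xc >= lo) & (xc < hi))[0])
    return cols


def sequence_field(
    fluence: FluenceGrid,
    geometry: MLCGeometry,
    machine: MachineConfig,
    plan=None,
    aggregation: str = "max",
) -> MLCSequence:
    """Sequence a whole fluence map, optionally with a sector-wise bank
    offset plan.

    ``plan`` is a :class:`~dmlc2d.optimizer.SectorPlan`; ``None`` means
    the conventional technique (a single sector at offset 0).  The map
    must already be in MU units.  Sectors are swept left to right and
    concatenated on the MU clock; at each sector boundary a beam-hold
    control-point pair (zero MU increment) carries the bank translation
    and leaf repositioning.
    """
    if fluence.units != "MU":
        raise ValidationError("fluence must be scaled to MU before sequencing")
    spec = fluence.spec
    if plan is None:
        edges = np.array([spec.x0, spec.x_max])
        offsets = np.array([0.0])
    else:
        edges = np.asarray(plan.sector_edges, float)
        offsets = np.asarray(plan.offsets, float)
        if offsets.size != edges.size - 1:
            raise PlanError("plan must provide one offset per sector")
    cols_per_sector = _sector_columns(spec, edges)

    # pairs engaged anywhere sweep (possibly closed) through every sector;
    # pairs engaged nowhere stay parked at x_travel_min
    profiles = [
        aggregate_pair_profiles(fluence, geometry, s, aggregation) for s in offsets
    ]
    engaged = np.zeros(geometry.n_pairs, bool)
    for prof, cols in zip(profiles, cols_per_sector):
        if cols.size:
            engaged |= (prof[:, cols] > 0).any(axis=1)
    if not engaged.any():
        log.info("all-zero fluence map: emitting a degenerate parked sequence")
        engaged[int(np.argmin(np.abs(geometry.y_lower_edges)))] = True

    pieces: list[MLCSequence] = []
    base = 0.0
    for prof, cols, s in zip(profiles, cols_per_sector, offsets):
        if cols.size == 0:
            continue
        xc = spec.x_centers[cols]
        trajs = {
            int(k): sequence_pair_profile(prof[k, cols], spec.dx, machine)
            for k in np.nonzero(engaged)[0]
        }
        pieces.append(synchronize_pairs(trajs, geometry, machine, s, xc, dx=spec.dx))
    if not pieces:
        raise PlanError("no sector contains any fluence column")

    mus, lefts, rights, offs = [], [], [], []
    for piece in pieces:
        mus.append(piece.mu + base)
        lefts.append(piece.left)
        rights.append(piece.right)
        offs.append(piece.bank_offset)
        base += piece.total_mu
    return MLCSequence(
        mu=np.concatenate(mus),
        left=np.vstack(lefts),
        right=np.vstack(rights),
        bank_offset=np.concatenate(offs),
        total_mu=base,
        geometry=geometry,
        machine=machine,
        meta={
            "aggregation": aggregation,
            "sector_edges": edges.tolist(),
            "offsets": offsets.tolist(),
            "synchronization": "global MU clock, max over pairs",
        },
    )


# ---------------------------------------------------------------------------
# serialization: TSV control-point table + JSON sidecar


def write_sequence(seq: MLCSequence, path: str | Path) -> None:
    """Write the control-point table as TSV plus a ``<path>.json`` sidecar
    with geometry/machine metadata."""
    path = Path(path)
    npairs = seq.geometry.n_pairs
    header = (
        ["mu", "bank_offset"]
        + [f"L{k}" for k in range(npairs)]
        + [f"R{k}" for k in range(npairs)]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(seq.n_control_points):
            row = (
                [f"{seq.mu[i]:.9g}", f"{seq.bank_offset[i]:.9g}"]
                + [f"{v:.9g}" for v in seq.left[i]]
                + [f"{v:.9g}" for v in seq.right[i]]
            )
            fh.write("\t".join(row) + "\n")
    sidecar = {
        "total_mu": seq.total_mu,
        "geometry": seq.geometry.to_dict(),
        "machine": seq.machine.to_dict(),
        "meta": seq.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_sequence(path: str | Path) -> MLCSequence:
    """Read a sequence written by :func:`write_sequence`."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    geometry = MLCGeometry(
        pair_widths=tuple(sidecar["geometry"]["pair_widths"]),
        y_min=sidecar["geometry"]["y_min"],
        x_travel_min=sidecar["geometry"]["x_travel_min"],
        x_travel_max=sidecar["geometry"]["x_travel_max"],
    )
    machine = MachineConfig(**sidecar["machine"])
    table = np.loadtxt(path, skiprows=1)
    table = np.atleast_2d(table)
    npairs = geometry.n_pairs
    return MLCSequence(
        mu=table[:, 0],
        left=table[:, 2 : 2 + npairs],
        right=table[:, 2 + npairs : 2 + 2 * npairs],
        bank_offset=table[:, 1],
        total_mu=sidecar["total_mu"],
        geometry=geometry,
        machine=machine,
        meta=sidecar.get("meta", {}),
    )
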