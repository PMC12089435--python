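"""Sliding-window recurrence, synchronization, and whole-field sequencing."""

import numpy as np
import pytest

from dmlc2d import (
    FluenceGrid,
    GridSpec,
    MachineConfig,
    SectorPlan,
    ValidationError,
    delivery_spec_for,
    reconstruct_fluence,
    scale_to_mu,
    sequence_field,
    sequence_pair_profile,
    synchronize_pairs,
    upsample_rows,
)

PHI = np.array([2.0, 4.0, 4.0, 1.0, 1.0])


def test_hand_recurrence_unconstrained_speed(fast_machine):
    tr = sequence_pair_profile(PHI, 1.0, fast_machine)
    np.testing.assert_allclose(tr.arrival_right, [0, 0, 0, 3, 3])
    np.testing.assert_allclose(tr.arrival_left, [2, 4, 4, 4, 4])
    np.testing.assert_allclose(tr.delivered, PHI)


def test_hand_recurrence_with_speed_limit_tau_2():
    machine = MachineConfig(dose_rate=600.0, max_leaf_speed=5.0)  # v_mu=0.5, tau=2
    tr = sequence_pair_profile(PHI, 1.0, machine)
    assert tr.total_mu == pytest.approx(12.0)
    np.testing.assert_allclose(tr.delivered, PHI)


def test_zero_profile_keeps_pair_closed(machine):
    tr = sequence_pair_profile(np.zeros(7), 1.0, machine)
    np.testing.assert_allclose(tr.delivered, 0.0)


def test_negative_profile_rejected(machine):
    with pytest.raises(ValidationError):
        sequence_pair_profile(np.array([1.0, -0.5]), 1.0, machine)


def test_exactness_monotonicity_and_speed_bound_on_random_profiles(machine):
    """The delivered gap reproduces any non-negative profile exactly, both
    leaves sweep monotonically, and every beamlet step takes >= tau MU."""
    rng = np.random.default_rng(42)
    tau = machine.mu_per_step(1.0)
    for _ in range(100):
        n = int(rng.integers(1, 60))
        phi = rng.uniform(0, 300, n) * (rng.uniform(size=n) > 0.3)
        tr = sequence_pair_profile(phi, 1.0, machine)
        np.testing.assert_allclose(tr.delivered, phi, atol=1e-9)
        assert np.all(np.diff(tr.arrival_right) >= tau - 1e-9)
        assert np.all(np.diff(tr.arrival_left) >= tau - 1e-9)
        assert np.all(tr.arrival_left >= tr.arrival_right - 1e-9)


def test_synchronize_single_pair_total_and_symmetry(geometry, machine):
    xc = np.arange(5) + 0.5
    tr = sequence_pair_profile(PHI, 1.0, machine)
    seq = synchronize_pairs({30: tr, 31: tr}, geometry, machine, 0.0, xc, dx=1.0)
    # shared clock: total is the pair total plus the closing half-beamlet
    assert seq.total_mu == pytest.approx(tr.total_mu + machine.mu_per_step(1.0) / 2)
    # identical pairs move identically at every control point
    np.testing.assert_allclose(seq.left[:, 30], seq.left[:, 31])
    np.testing.assert_allclose(seq.right[:, 30], seq.right[:, 31])


def test_pair_finishing_early_holds_closed(geometry, machine):
    xc = np.arange(5) + 0.5
    short = sequence_pair_profile(np.array([2.0, 4.0, 4.0, 1.0, 1.0]) / 2, 1.0, machine)
    long = sequence_pair_profile(PHI * 2, 1.0, machine)
    seq = synchronize_pairs({20: short, 21: long}, geometry, machine, 0.0, xc, dx=1.0)
    assert seq.total_mu == pytest.approx(long.total_mu + machine.mu_per_step(1.0) / 2)
    after = seq.mu > short.total_mu + machine.mu_per_step(1.0)
    np.testing.assert_allclose(seq.left[after, 20], seq.right[after, 20])


def test_monotone_sweep_and_speed_feasibility_of_control_points(geometry, machine):
    rng = np.random.default_rng(3)
    vals = np.zeros((20, 12))
    vals[5:15] = rng.uniform(0, 40, (10, 12))
    fl = FluenceGrid(GridSpec(x0=0, y0=-10, nx=12, ny=20), vals, "MU")
    seq = sequence_field(fl, geometry, machine)
    dmu = np.diff(seq.mu)
    for pos in (seq.left, seq.right):
        dpos = np.diff(pos, axis=0)
        assert np.all(dpos >= -1e-9)  # never moves in -x
        live = dmu > 1e-9
        speed = dpos[live] / dmu[live, None]
        assert np.all(speed <= machine.v_mu + 1e-6)


def _rect_map(nx=16, ny=30, lo=5, hi=25, value=1.0, y0=0.0):
    vals = np.zeros((ny, nx))
    vals[lo:hi, :] = value
    return FluenceGrid(GridSpec(x0=0, y0=y0, nx=nx, ny=ny), vals, "relative")


def test_leaf_aligned_rectangle_reproduced_exactly(geometry, machine):
    """A uniform rectangle aligned to the 5 mm leaf boundaries is delivered
    with zero error by the conventional technique."""
    fl = scale_to_mu(_rect_map(), machine.total_mu)
    seq = sequence_field(fl, geometry, machine)
    actual = reconstruct_fluence(seq, geometry, delivery_spec_for(fl.spec))
    planned = upsample_rows(fl, 4)
    np.testing.assert_allclose(actual.values, planned.values, atol=1e-6)


def test_eight_equal_offset_sectors_deliver_same_fluence_as_one(geometry, machine):
    rng = np.random.default_rng(9)
    vals = np.zeros((30, 16))
    vals[8:22] = rng.uniform(0, 1, (14, 16))
    fl = scale_to_mu(FluenceGrid(GridSpec(x0=0, y0=-15, nx=16, ny=30), vals), 100.0)
    spec = delivery_spec_for(fl.spec)
    for s in (0.0, 1.25):
        one = SectorPlan(sector_edges=(0.0, 16.0), offsets=(s,))
        eight = SectorPlan(
            sector_edges=tuple(np.linspace(0, 16, 9)), offsets=(s,) * 8
        )
        f_one = reconstruct_fluence(
            sequence_field(fl, geometry, machine, plan=one), geometry, spec
        )
        f_eight = reconstruct_fluence(
            sequence_field(fl, geometry, machine, plan=eight), geometry, spec
        )
        np.testing.assert_allclose(f_eight.values, f_one.values, atol=1e-6)


def test_sector_plan_must_cover_the_grid(geometry, machine):
    from dmlc2d import PlanError

    fl = scale_to_mu(_rect_map(), 100.0)
    bad = SectorPlan(sector_edges=(0.0, 10.0), offsets=(0.0,))
    with pytest.raises(PlanError, match="cover"):
        sequence_field(fl, geometry, machine, plan=bad)


def test_sequencing_requires_mu_units(geometry, machine):
    with pytest.raises(ValidationError, match="MU"):
        sequence_field(_rect_map(), geometry, machine)


def test_sequence_roundtrip_through_files(tmp_path, geometry, machine):
    from dmlc2d import read_sequence, write_sequence

    fl = scale_to_mu(_rect_map(nx=8), 50.0)
    seq = sequence_field(fl, geometry, machine)
    write_sequence(seq, tmp_path / "seq.tsv")
    back = read_sequence(tmp_path / "seq.tsv")
    np.testing.assert_allclose(back.mu, seq.mu)
    np.testing.assert_allclose(back.left, seq.left)
    np.testing.assert_allclose(back.right, seq.right)
    assert back.total_mu == pytest.approx(seq.total_mu)
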