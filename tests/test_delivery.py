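"""Analytic fluence reconstruction vs the brute-force time-stepped oracle."""

import numpy as np
import pytest

from dmlc2d import (
    FluenceGrid,
    GridSpec,
    MachineConfig,
    MLCSequence,
    ValidationError,
    delivery_spec_for,
    generate_suite,
    optimize_sectors,
    reconstruct_fluence,
    scale_to_mu,
    sequence_field,
    simulate_delivery_oracle,
)


def _static_rectangle_sequence(geometry, machine, total_mu=400.0):
    """Aperture held open over x in [0, 20), pairs covering y in [0, 20)."""
    n = geometry.n_pairs
    left = np.full((2, n), geometry.x_travel_min)
    right = np.full((2, n), geometry.x_travel_min)
    lower = geometry.y_lower_edges
    open_pairs = (lower >= 0) & (lower < 20)
    left[:, open_pairs] = 0.0
    right[:, open_pairs] = 20.0
    return MLCSequence(
        mu=np.array([0.0, total_mu]),
        left=left,
        right=right,
        bank_offset=np.zeros(2),
        total_mu=total_mu,
        geometry=geometry,
        machine=machine,
    )


def test_static_open_rectangle_delivers_total_mu_inside_zero_outside(geometry, machine):
    seq = _static_rectangle_sequence(geometry, machine, total_mu=400.0)
    spec = GridSpec(x0=-5, y0=-5, dx=1.0, dy=0.25, nx=30, ny=120)
    actual = reconstruct_fluence(seq, geometry, spec)
    inside = actual.values[
        np.ix_((spec.y_centers > 0) & (spec.y_centers < 20),
               (spec.x_centers > 0) & (spec.x_centers < 20))
    ]
    outside_cols = (spec.x_centers < 0) | (spec.x_centers > 20)
    np.testing.assert_allclose(inside, 400.0)
    np.testing.assert_allclose(actual.values[:, outside_cols], 0.0)
    # static aperture: oracle matches analytic exactly for any step
    orc = simulate_delivery_oracle(seq, geometry, spec, 0.5)
    np.testing.assert_allclose(orc.values, actual.values, atol=1e-9)


def test_sequenced_profile_row_reconstructed_exactly(geometry, machine):
    from dmlc2d import sequence_pair_profile, synchronize_pairs

    phi = np.array([2.0, 4.0, 4.0, 1.0, 1.0])
    tr = sequence_pair_profile(phi, 1.0, machine)
    seq = synchronize_pairs({30: tr}, geometry, machine, 0.0, np.arange(5) + 0.5, dx=1.0)
    spec = GridSpec(x0=0, y0=geometry.y_lower_edges[30], dx=1.0, dy=5.0, nx=5, ny=1)
    np.testing.assert_allclose(reconstruct_fluence(seq, geometry, spec).values[0], phi,
                               atol=1e-9)


def test_zero_mu_sequence_gives_zero_map(geometry, machine):
    seq = _static_rectangle_sequence(geometry, machine)
    seq.mu = np.array([0.0])
    seq.left, seq.right, seq.bank_offset = seq.left[:1], seq.right[:1], seq.bank_offset[:1]
    seq.total_mu = 0.0
    spec = GridSpec(x0=-5, y0=-5, nx=30, ny=30)
    assert reconstruct_fluence(seq, geometry, spec).max == 0.0


def test_mu_step_validation(geometry, machine):
    seq = _static_rectangle_sequence(geometry, machine, total_mu=10.0)
    spec = GridSpec(x0=0, y0=0, nx=5, ny=5)
    with pytest.raises(ValidationError):
        simulate_delivery_oracle(seq, geometry, spec, 0.0)
    with pytest.raises(ValidationError):
        simulate_delivery_oracle(seq, geometry, spec, 10.0)


@pytest.fixture(scope="module")
def sequenced_case(geometry):
    machine = MachineConfig(total_mu=20.0)
    grids, _ = generate_suite(1, "small", seed=5)
    fl = scale_to_mu(grids[0], machine.total_mu)
    plan = optimize_sectors(fl, geometry, machine)
    seq = sequence_field(fl, geometry, machine, plan=plan)
    spec = delivery_spec_for(fl.spec)
    return seq, spec, reconstruct_fluence(seq, geometry, spec)


def test_oracle_converges_to_analytic_within_twice_the_step(geometry, sequenced_case):
    seq, spec, analytic = sequenced_case
    for h in (0.02, 0.01):
        orc = simulate_delivery_oracle(seq, geometry, spec, h)
        assert np.abs(orc.values - analytic.values).max() <= 2 * h


def test_deviation_scales_first_order_with_the_step(geometry, sequenced_case):
    """The max oracle deviation is bounded by twice the MU step at every
    step (so the bound halves as the step halves) and shrinks ~linearly:
    a 4x finer step leaves at most ~1/3 of the deviation."""
    seq, spec, analytic = sequenced_case
    dev = {
        h: np.abs(simulate_delivery_oracle(seq, geometry, spec, h).values
                  - analytic.values).max()
        for h in (0.04, 0.02, 0.01)
    }
    for h, d in dev.items():
        assert d <= 2 * h
    assert dev[0.02] <= dev[0.04]
    assert dev[0.01] <= 0.35 * dev[0.04]


def test_reconstruction_linear_in_mu_and_bounded(geometry, sequenced_case):
    seq, spec, analytic = sequenced_case
    scaled = MLCSequence(
        mu=seq.mu * 3.0, left=seq.left, right=seq.right,
        bank_offset=seq.bank_offset, total_mu=seq.total_mu * 3.0,
        geometry=seq.geometry, machine=seq.machine,
    )
    np.testing.assert_allclose(
        reconstruct_fluence(scaled, geometry, spec).values, 3.0 * analytic.values,
        atol=1e-9,
    )
    assert analytic.values.min() >= 0.0
    assert analytic.values.max() <= seq.total_mu + 1e-9
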