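"""Conformity index, difference metrics, paired statistics, and the
end-to-end conventional-vs-2DDMLC comparison."""

import numpy as np
import pytest
from scipy import stats

from dmlc2d import (
    DegenerateInputError,
    FluenceGrid,
    GridSpec,
    MachineConfig,
    ValidationError,
    compare_suite,
    compare_techniques,
    conformity_index,
    irradiated_area,
    mean_abs_diff_pct,
    mean_intensity,
    out_of_field_area,
    paired_t_test,
)
from dmlc2d.fixtures import worked_rectangle


def _uniform(value, nx=10, ny=10):
    return FluenceGrid(GridSpec(nx=nx, ny=ny), np.full((ny, nx), float(value)), "MU")


def test_irradiated_area_threshold_semantics():
    assert irradiated_area(_uniform(100.0), 0.1, 100.0) == 100.0
    assert irradiated_area(_uniform(0.0), 0.1, 100.0) == 0.0
    half = _uniform(100.0).values.copy()
    half[:5] = 5.0  # 0.05 of reference
    g = FluenceGrid(GridSpec(nx=10, ny=10), half, "MU")
    assert irradiated_area(g, 0.1, 100.0) == 50.0
    assert irradiated_area(g, 0.01, 100.0) == 100.0


def test_conformity_index_identity_scaling_and_arithmetic():
    g = _uniform(10.0)
    assert conformity_index(g, g) == 1.0
    # invariance under uniform rescaling of both maps
    g2 = FluenceGrid(g.spec, g.values * 7.3, "MU")
    assert conformity_index(g2, g2) == 1.0
    # 630 vs 500 mm^2 -> 1.26
    planned = np.zeros((40, 40))
    planned[:25, :20] = 1.0  # 500 cells
    actual = np.zeros((40, 40))
    actual[:30, :21] = 1.0  # 630 cells
    spec = GridSpec(nx=40, ny=40)
    ci = conformity_index(FluenceGrid(spec, actual, "MU"), FluenceGrid(spec, planned, "MU"))
    assert ci == pytest.approx(1.26)
    with pytest.raises(DegenerateInputError):
        conformity_index(g, _uniform(0.0))


def test_mean_intensity_support_and_linearity():
    g = _uniform(0.13)
    assert mean_intensity(g) == pytest.approx(0.13)
    doubled = FluenceGrid(g.spec, g.values * 2, "MU")
    assert mean_intensity(doubled) == pytest.approx(0.26)
    assert mean_intensity(_uniform(0.0)) == 0.0  # empty support, warned
    mask = np.zeros((10, 10), bool)
    mask[0, 0] = True
    assert mean_intensity(g, mask) == pytest.approx(0.13)


def test_mean_abs_diff_pct_identities():
    g = _uniform(10.0)
    assert mean_abs_diff_pct(g, g) == 0.0
    scaled = FluenceGrid(g.spec, g.values * 1.1, "MU")
    assert mean_abs_diff_pct(scaled, g) == pytest.approx(10.0)
    with pytest.raises(DegenerateInputError):
        mean_abs_diff_pct(g, _uniform(0.0))
    with pytest.raises(ValidationError):
        mean_abs_diff_pct(g, _uniform(1.0, nx=3, ny=3))


def test_out_of_field_area_and_threshold_monotonicity():
    g = _uniform(10.0)
    assert out_of_field_area(g, g) == 0.0
    planned = np.zeros((20, 20))
    planned[5:15, :] = 10.0
    actual = np.zeros((20, 20))
    actual[3:17, :] = 10.0
    spec = GridSpec(nx=20, ny=20)
    a, p = FluenceGrid(spec, actual, "MU"), FluenceGrid(spec, planned, "MU")
    assert out_of_field_area(a, p, 0.1) == 4 * 20  # two 2-row bands
    areas = [out_of_field_area(a, p, t) for t in (0.1, 0.5, 0.9, 0.999)]
    assert all(x >= y for x, y in zip(areas, areas[1:]))


def test_paired_t_degenerate_branches_and_reference_value():
    assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)
    t, p = paired_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    assert np.isinf(t) and t < 0 and p == 0.0
    a = [1.1, 1.9, 3.2, 4.1]
    b = [1.0, 2.0, 3.0, 4.0]
    t, p = paired_t_test(a, b)
    # independent closed form: t = mean(d) / (sd(d)/sqrt(n)), df = n-1
    d = np.array(a) - np.array(b)
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p_ref = 2 * stats.t.sf(abs(t_ref), d.size - 1)
    assert t == pytest.approx(t_ref)
    assert p == pytest.approx(p_ref)
    with pytest.raises(ValidationError):
        paired_t_test([1.0], [2.0])


def _aligned_rectangle():
    vals = np.zeros((30, 16))
    vals[5:25, :] = 1.0
    return FluenceGrid(GridSpec(x0=0, y0=0, nx=16, ny=30), vals, "relative")


@pytest.fixture(scope="module")
def machine20():
    return MachineConfig(total_mu=20.0)


def test_compare_leaf_aligned_rectangle_is_perfect_for_both(geometry, machine20):
    rep = compare_techniques(_aligned_rectangle(), geometry, machine20)
    assert rep.ci_conventional == pytest.approx(1.0)
    assert rep.ci_2ddmlc == pytest.approx(1.0)
    assert rep.oof_area_conventional == 0.0
    assert rep.oof_reduction_pct is None  # 0/0, logged


def test_compare_misaligned_rectangle_2ddmlc_wins(geometry, machine20):
    rep = compare_techniques(worked_rectangle(x_extent=16), geometry, machine20)
    assert rep.ci_2ddmlc < rep.ci_conventional
    assert rep.mad_pct_2ddmlc < rep.mad_pct_conventional
    assert rep.oof_reduction_pct == pytest.approx(100.0)


def test_compare_suite_layout_and_paired_p(geometry, machine20):
    from dmlc2d import generate_suite

    maps, _ = generate_suite(4, "small", seed=77)
    df, summary = compare_suite(maps, geometry, machine20)
    assert len(df) == 4
    assert {"ci_conventional", "ci_2ddmlc", "mad_pct_conventional"} <= set(df.columns)
    assert summary["n"] == 4
    assert 0 <= summary["ci"]["p"] <= 1
    assert summary["ci"]["2ddmlc_mean"] <= summary["ci"]["conventional_mean"]
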