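"""Scenario chain and Fickian solver: worked values, linearity, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rpetsafe import ScenarioConfig, chain_concentration, generic_curve, migrate, scale_migration
from rpetsafe.migration import DepletionWarning, _series_release_fraction


def test_chain_concentration_reference_scenario():
    assert chain_concentration(10.0, 0.05, 0.90) == pytest.approx(0.05)
    assert chain_concentration(2.0, 0.05, 0.90) == pytest.approx(0.01)


def test_chain_concentration_identity_and_domain():
    assert chain_concentration(3.7, 1.0, 0.0) == 3.7
    with pytest.raises(ValueError):
        chain_concentration(-1.0, 0.5, 0.5)
    with pytest.raises(ValueError):
        chain_concentration(1.0, 1.5, 0.5)


def test_migration_of_generic_surrogate_matches_published_curve(cfg, piringer):
    result = migrate(0.05, piringer(145.0, cfg.temperature), cfg)
    assert result.migration == pytest.approx(0.0418, rel=0.15)
    assert result.fractional_depletion < 0.05


def test_zero_source_migrates_nothing(cfg, piringer):
    result = migrate(0.0, piringer(145.0, cfg.temperature), cfg)
    assert result.migration == 0.0
    assert result.fractional_depletion == 0.0


@pytest.mark.parametrize("method", ["semi_infinite", "series"])
def test_migration_linear_in_initial_concentration(cfg, piringer, method):
    D = piringer(120.0, cfg.temperature)
    one = migrate(0.02, D, cfg, method=method)
    two = migrate(0.04, D, cfg, method=method)
    assert two.migration == pytest.approx(2.0 * one.migration, rel=1e-12)


def test_square_root_of_time_growth(cfg, piringer):
    D = piringer(100.0, cfg.temperature)
    base = migrate(0.05, D, cfg)
    longer = migrate(0.05, D, cfg.replace(storage_time=4 * cfg.storage_time))
    assert longer.migration == pytest.approx(2.0 * base.migration, rel=1e-12)


def test_migration_increasing_in_time_diffusivity_and_source(cfg, piringer):
    D = piringer(150.0, cfg.temperature)
    ref = migrate(0.05, D, cfg).migration
    assert migrate(0.05, D, cfg.replace(storage_time=400.0)).migration > ref
    assert migrate(0.05, 2 * D, cfg).migration > ref
    assert migrate(0.06, D, cfg).migration > ref


def test_semi_infinite_and_series_agree_in_small_depletion_regime(cfg, piringer):
    for mw in (78.1, 100.0, 145.0, 200.0):
        D = piringer(mw, cfg.temperature)
        semi = migrate(0.05, D, cfg)
        series = migrate(0.05, D, cfg, method="series")
        assert semi.fractional_depletion < 0.06
        assert semi.migration == pytest.approx(series.migration, rel=0.01)


def test_series_mass_conservation_and_monotone_release(cfg):
    D = 1e-10  # fast diffusion so depletion is substantial
    fractions = [
        _series_release_fraction(D, t_days * 86400.0, cfg.wall_thickness)
        for t_days in (1, 10, 50, 200, 1000)
    ]
    assert all(0.0 <= f <= 1.0 for f in fractions)
    assert all(a <= b for a, b in zip(fractions, fractions[1:]))
    result = migrate(0.05, D, cfg, method="series")
    initial_mass_per_l = (
        0.05 * 1e-3 * cfg.pet_density * cfg.wall_thickness * cfg.surface_to_volume * 100 * 1000
    )  # µg available per litre of beverage
    assert result.migration <= initial_mass_per_l * (1 + 1e-9)


def test_series_agrees_with_numerical_pde_solution(cfg):
    # independent route: method-of-lines finite differences on the slab
    from scipy.integrate import solve_ivp

    D, L, t = 2e-11, cfg.wall_thickness, 365 * 86400.0
    n = 200
    dx = L / n
    x_centres = np.linspace(dx / 2, L - dx / 2, n)

    def rhs(_, c):
        flux = np.empty(n + 1)
        flux[1:-1] = -D * np.diff(c) / dx
        flux[-1] = 0.0  # sealed outer face
        flux[0] = -D * (c[0] - 0.0) / (dx / 2)  # zero-concentration contact face
        return -np.diff(flux) / dx

    sol = solve_ivp(rhs, (0, t), np.ones(n), rtol=1e-8, atol=1e-10)
    released_numeric = 1.0 - sol.y[:, -1].mean()
    released_series = _series_release_fraction(D, t, L)
    assert released_series == pytest.approx(released_numeric, rel=0.01)


def test_semi_infinite_warns_when_depletion_degrades(cfg):
    with pytest.warns(DepletionWarning):
        migrate(0.05, 1e-9, cfg)


def test_unit_round_trip_is_invertible(cfg):
    c_p0 = 0.05  # mg/kg polymer
    c_vol = c_p0 * 1e-3 * cfg.pet_density  # mg/cm³
    back = c_vol / (1e-3 * cfg.pet_density)
    assert back == pytest.approx(c_p0, rel=1e-15)
    av_cm2 = cfg.surface_to_volume * 100.0
    assert av_cm2 / 100.0 == pytest.approx(cfg.surface_to_volume, rel=1e-15)


def test_generic_curve_decreasing_and_anchored(cfg, piringer):
    grid = [78.1, 100.0, 145.0, 150.2, 200.0, 250.0]
    curve = generic_curve(grid, piringer, 10.0, cfg)
    values = [m for _, m in curve]
    assert all(a > b for a, b in zip(values, values[1:]))
    by_mw = dict(curve)
    assert by_mw[145.0] == pytest.approx(0.0418, rel=0.15)
    assert by_mw[150.2] == pytest.approx(0.04, rel=0.15)
    assert generic_curve([], piringer, 10.0, cfg) == []


def test_generic_curve_vanishes_at_high_molecular_weight(cfg, piringer):
    (_, head), (_, tail) = generic_curve([145.0, 599.0], piringer, 10.0, cfg)
    assert tail < 0.15 * head


def test_scale_migration_ratios(cfg, piringer):
    ref = migrate(0.05, piringer(145.0, cfg.temperature), cfg)
    assert scale_migration(ref, 1.0, 4.0) == pytest.approx(4 * ref.migration)
    assert scale_migration(ref, 0.05, 1.0) == pytest.approx(ref.migration / 20)
    assert scale_migration(ref, 1.0, 1.0) == ref.migration
    with pytest.raises(ValueError):
        scale_migration(ref, 0.0, 1.0)


@given(
    c=st.floats(min_value=0.0, max_value=100.0),
    fraction=st.floats(min_value=0.0, max_value=1.0),
    cleaning=st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=200, derandomize=True)
def test_chain_never_amplifies(c, fraction, cleaning):
    c_p0 = chain_concentration(c, fraction, cleaning)
    assert 0.0 <= c_p0 <= c


def test_scenario_config_file_round_trip(tmp_path):
    cfg = ScenarioConfig(nonfood_fraction=0.2, storage_time=100.0)
    path = tmp_path / "scenario.json"
    path.write_text(__import__("json").dumps(cfg.to_dict()))
    assert ScenarioConfig.from_file(path) == cfg
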