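"""Exposure arithmetic, routing logic and the whole-table sweep."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from rpetsafe import (
    ScenarioConfig,
    chain_concentration,
    estimate_nonfood_fraction,
    evaluate_all,
    evaluate_substance,
    exposure,
    group_mean,
    migrate,
    safety_factor,
)
from rpetsafe.safety import (
    GENOTOXIC_TTC_THRESHOLD,
    is_genotoxic,
    is_volatile,
)


def test_exposure_reference_values():
    assert exposure(0.00107, 0.75, 5.0) == pytest.approx(0.000161, rel=0.01)
    assert exposure(0.00835, 0.75, 5.0) == pytest.approx(0.00125, rel=0.01)
    assert exposure(0.0, 0.75, 5.0) == 0.0


def test_exposure_domain_errors():
    with pytest.raises(ValueError):
        exposure(1.0, 0.75, 0.0)
    with pytest.raises(ValueError):
        exposure(-1.0, 0.75, 5.0)


def test_safety_factor_reference_values():
    assert safety_factor(0.000161, 0.0025) == pytest.approx(15.5, rel=0.01)
    assert safety_factor(0.00125, 0.0025) == pytest.approx(2.0, rel=0.01)
    assert safety_factor(0.0025, 0.0025) == 1.0
    assert math.isinf(safety_factor(0.0, 0.0025))


@given(
    migration=st.floats(min_value=0.0, max_value=10.0),
    consumption=st.floats(min_value=0.0, max_value=3.0),
    bw=st.floats(min_value=1.0, max_value=100.0),
    k=st.floats(min_value=0.1, max_value=10.0),
)
@settings(max_examples=100, derandomize=True)
def test_exposure_linearity(migration, consumption, bw, k):
    base = exposure(migration, consumption, bw)
    assert exposure(k * migration, consumption, bw) == pytest.approx(k * base, rel=1e-12, abs=1e-300)
    assert exposure(migration, k * consumption, bw) == pytest.approx(k * base, rel=1e-12, abs=1e-300)
    assert exposure(migration, consumption, k * bw) == pytest.approx(base / k, rel=1e-12, abs=1e-300)


def test_corrected_toxicology_beats_raw_flags(survey):
    benzene = survey.find("Benzene", "i")
    assert not benzene.gtc_alert  # the raw decision-tree call missed it
    assert is_genotoxic(benzene)
    benzaldehyde = survey.find("Benzaldehyde", "i")
    assert benzaldehyde.gtc_alert  # spurious raw alert
    assert not is_genotoxic(benzaldehyde)
    ethylacrolein = survey.find("2-Ethylacrolein", "iv")
    assert is_genotoxic(ethylacrolein)


def test_volatility_by_name_and_by_elution_window(survey):
    assert is_volatile(survey.find("Ethanol", "ii"))
    assert is_volatile(survey.find("2-Butanone", "iv"))
    assert not is_volatile(survey.find("Benzene", "i"))  # rt 2.5, identified
    assert is_volatile(survey.find("Unknown 3", "ii"))  # rt 1.7, solvent window
    assert not is_volatile(survey.find("Unknown 9", "iv"))  # rt 6.9


def test_benzene_verdict_matches_worked_example(survey, cfg, piringer):
    benzene = survey.find("Benzene", "i")
    c_mean = group_mean(benzene, survey.categories["i"])
    c_p0 = chain_concentration(c_mean, cfg.nonfood_fraction, cfg.cleaning_efficiency)
    result = migrate(c_p0, piringer(benzene.molecular_weight, cfg.temperature), cfg,
                     substance=benzene.name)
    verdict = evaluate_substance(benzene, result, cfg)
    assert verdict.route == "genotoxic_ttc"
    assert verdict.conclusion == "no_concern"
    assert verdict.exposure == pytest.approx(0.000161, rel=0.15)
    assert verdict.safety_factor == pytest.approx(15.5, rel=0.15)


def test_pooled_unknowns_verdict_matches_worked_example(survey, cfg, piringer):
    report = evaluate_all(survey, "piringer", cfg)
    pooled = next(v for v in report.verdicts if v.substance == "Pooled unknowns (iv)")
    assert pooled.route == "genotoxic_ttc"
    # pooled concentration 1.82 mg/kg (the published example rounds to 2)
    assert pooled.exposure == pytest.approx(0.00125 * 1.82 / 2.0, rel=0.15)
    assert pooled.conclusion == "no_concern"


def test_zero_migration_gives_infinite_margin(survey, cfg):
    from rpetsafe.migration import MigrationResult

    benzene = survey.find("Benzene", "i")
    result = MigrationResult(substance="Benzene", c_p0=0.0, diffusion_coefficient=1e-14,
                             migration=0.0, fractional_depletion=0.0)
    verdict = evaluate_substance(benzene, result, cfg)
    assert verdict.conclusion == "no_concern"
    assert math.isinf(verdict.safety_factor)


def test_whole_table_sweep_under_defaults(survey, cfg):
    report = evaluate_all(survey, "piringer", cfg)
    assert not report.unevaluable
    for v in report.verdicts:
        assert v.conclusion == "no_concern", v
        if v.route != "volatile_excluded":
            assert v.migration < 1.0, (v.substance, v.migration)
    summary = report.summary()
    assert summary["by_conclusion"] == {"no_concern": len(report.verdicts)}


def test_quadrupled_fraction_scales_migrations_exactly(survey, cfg):
    base = evaluate_all(survey, "piringer", cfg)
    hi = evaluate_all(survey, "piringer", cfg.replace(nonfood_fraction=0.20))
    assert len(base.verdicts) == len(hi.verdicts)
    for v5, v20 in zip(base.verdicts, hi.verdicts):
        assert v20.substance == v5.substance
        assert v20.migration == pytest.approx(4.0 * v5.migration, rel=1e-12, abs=1e-300)
        if v5.migration > 0:
            assert v20.safety_factor == pytest.approx(v5.safety_factor / 4.0, rel=1e-12)


def test_concern_is_monotone_in_nonfood_fraction(survey, cfg):
    def concerns(fraction):
        report = evaluate_all(survey, "piringer", cfg.replace(nonfood_fraction=fraction))
        return {v.substance for v in report.verdicts if v.conclusion == "concern"}

    low, high = concerns(0.05), concerns(1.0)
    assert low <= high


def test_empty_table_gives_empty_report(survey, cfg):
    from rpetsafe.tables import ContaminationSurvey

    empty = ContaminationSurvey(categories=dict(survey.categories), records=[])
    report = evaluate_all(empty, "piringer", cfg)
    assert report.verdicts == [] and report.unevaluable == []


def test_feed_stream_fraction_estimate():
    value = estimate_nonfood_fraction(77.0, 4.0)
    assert value == pytest.approx(4.94, abs=0.01)
    assert round(value) == 5
    assert estimate_nonfood_fraction(77.0, 0.0) == 0.0
    assert estimate_nonfood_fraction(50.0, 50.0) == 50.0
    with pytest.raises(ValueError):
        estimate_nonfood_fraction(0.0, 0.0)
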