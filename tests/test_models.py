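"""The six scoring engines against independent brute-force oracles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ohra import (
    ExposureRecord,
    HazardProfile,
    MissingParameterError,
    ParameterError,
    UnknownPhraseError,
    assess_all,
    australian_assess,
    coshh_assess,
    compute_ec,
    epa_hq,
    epa_level,
    icmm_assess,
    romanian_assess,
    singapore_er,
    singapore_hr,
    singapore_risk,
)


def record(hazard, ca, industry="Ship repair", location="Electrowelding", **kw):
    return ExposureRecord(industry=industry, location=location, hazard=hazard, ca=ca, **kw)


# ---------------------------------------------------------------- EPA

def test_epa_hq_is_plain_ratio():
    assert epa_hq(228.31, 100.0) == pytest.approx(2.2831)
    assert epa_hq(50.0, 50.0) == 1.0
    with pytest.raises(ParameterError):
        epa_hq(1.0, 0.0)
    with pytest.raises(ParameterError):
        epa_hq(-1.0, 1.0)


def _interval_oracle(x, bounds):
    """Independent left-closed/right-open interval lookup."""
    for level, (lo, hi) in enumerate(bounds, start=1):
        if lo <= x < hi:
            return level
    raise AssertionError(x)


EPA_BOUNDS = [(0.0, 0.1), (0.1, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, math.inf)]


@pytest.mark.parametrize("hq", [0.0, 0.05, 0.1, 0.3, 0.5, 0.77, 1.0, 1.5, 2.0, 2.5, 100.0])
def test_epa_level_matches_interval_oracle(hq, config):
    assert epa_level(hq, config) == _interval_oracle(hq, EPA_BOUNDS)


def test_epa_level_rejects_negative(config):
    with pytest.raises(ParameterError):
        epa_level(-0.1, config)


@given(cas=st.lists(st.floats(0, 50), min_size=2, max_size=20))
def test_epa_level_monotone_in_concentration(cas, config):
    """Level is nondecreasing in CA for a fixed RfC and exposure pattern."""
    cas = sorted(cas)
    levels = [
        epa_level(epa_hq(compute_ec(record("Benzene", ca)), 30.0), config) for ca in cas
    ]
    assert levels == sorted(levels)


def test_mn_sweep_is_level_5_across_printed_range(config):
    """Manganese at 0.003–28.98 mg/m³ full shift: HQ ≥ 13 ⇒ top level."""
    for ca in (0.003, 0.956, 28.98):
        hq = epa_hq(compute_ec(record("Manganese and inorganic compounds", ca)), 0.05)
        assert epa_level(hq, config) == 5


def test_ethyl_acetate_sweep_is_level_1_across_printed_range(config):
    for ca in (0.0003, 0.002, 0.031):
        hq = epa_hq(compute_ec(record("Ethyl acetate", ca)), 3500.0)
        assert hq <= 0.003
        assert epa_level(hq, config) == 1


# ---------------------------------------------------------------- Singaporean

def test_hr_override_wins(mn_profile, config):
    assert singapore_hr(mn_profile, config) == 4


def test_hr_from_carcinogenicity(benzene_profile, config):
    assert singapore_hr(benzene_profile, config) == 5


def test_hr_without_any_basis_errors(config):
    bare = HazardProfile(name="x", oel_china_twa=1.0, physical_form="solid")
    with pytest.raises(MissingParameterError):
        singapore_hr(bare, config)


@pytest.mark.parametrize(
    "cr,expected", [(0.0, 1), (0.05, 1), (0.1, 2), (0.21, 2), (0.5, 3), (1.0, 4), (2.0, 5), (2.5, 5)]
)
def test_er_bands_left_closed(cr, expected, config):
    assert singapore_er(cr, config) == expected


def test_er_rejects_negative(config):
    with pytest.raises(ParameterError):
        singapore_er(-0.01, config)


def test_singapore_risk_exhaustive_oracle():
    """√(HR×ER) rounded up, capped at 5; symmetric and monotone."""
    for hr in range(1, 6):
        for er in range(1, 6):
            risk = singapore_risk(hr, er)
            assert risk == min(5, math.ceil(math.sqrt(hr * er)))
            assert risk == singapore_risk(er, hr)
            if hr < 5:
                assert singapore_risk(hr + 1, er) >= risk
    assert singapore_risk(4, 2) == 3
    assert singapore_risk(5, 5) == 5
    assert singapore_risk(1, 1) == 1
    with pytest.raises(ParameterError):
        singapore_risk(0, 3)


# ---------------------------------------------------------------- COSHH

def test_coshh_benzene_is_cs4(benzene_profile, config):
    assert coshh_assess(benzene_profile, config=config) == ("CS4", 5)


def test_coshh_mn_is_cs1(mn_profile, config):
    assert coshh_assess(mn_profile, config=config) == ("CS1", 2)


def test_coshh_xylene_level_2(registry, config):
    _, level = coshh_assess(registry["Xylene"], config=config)
    assert level == 2


def test_coshh_gas_treated_as_high_volatility(registry, config):
    _, level = coshh_assess(registry["Nitrogen oxides"], config=config)
    assert level == 4


def test_coshh_unknown_phrase_is_reported(config):
    odd = HazardProfile(
        name="odd", risk_phrases=["R99"], physical_form="liquid", volatility_band="low"
    )
    with pytest.raises(UnknownPhraseError, match="R99"):
        coshh_assess(odd, config=config)


def test_coshh_missing_release_band_errors(config):
    solid = HazardProfile(name="s", risk_phrases=["R36"], physical_form="solid")
    with pytest.raises(MissingParameterError):
        coshh_assess(solid, config=config)


def test_coshh_exhaustive_matrix_oracle(config):
    """Every (band, quantity, release) cell equals an independent lookup."""
    ep_oracle = {
        ("small", "low"): 1, ("small", "medium"): 1, ("small", "high"): 2,
        ("medium", "low"): 1, ("medium", "medium"): 2, ("medium", "high"): 3,
        ("large", "low"): 2, ("large", "medium"): 3, ("large", "high"): 4,
    }
    cs_oracle = {
        "A": [1, 1, 1, 2], "B": [1, 1, 2, 3], "C": [1, 2, 3, 4],
        "D": [2, 3, 4, 4], "E": [4, 4, 4, 4],
    }
    phrase_for = {"A": "R36", "B": "R20", "C": "R23", "D": "R26", "E": "R45"}
    for band, phrase in phrase_for.items():
        for (quantity, release), ep in ep_oracle.items():
            profile = HazardProfile(
                name="probe", risk_phrases=[phrase],
                physical_form="liquid", volatility_band=release,
            )
            cs, level = coshh_assess(profile, quantity_band=quantity, config=config)
            assert cs == f"CS{cs_oracle[band][ep - 1]}"
            assert level == cs_oracle[band][ep - 1] + 1


# ---------------------------------------------------------------- ICMM

def test_icmm_exhaustive_grid_oracle(config):
    """All 75 (consequence, probability, weight) cells against product banding."""

    def oracle(c, l):
        score = c * l
        for bound, level in ((2, 1), (5, 2), (10, 3), (15, 4)):
            if score <= bound:
                return level
        return 5

    for c in range(1, 6):
        for p in range(1, 6):
            for w in (1, 2, 3):
                eff = min(5, max(1, p + w - 2))
                assert icmm_assess(c, p, w, config) == oracle(c, eff)
    assert icmm_assess(5, 5, config=config) == 5
    assert icmm_assess(1, 1, config=config) == 1
    with pytest.raises(ParameterError):
        icmm_assess(6, 1, config=config)
    with pytest.raises(ParameterError):
        icmm_assess(1, 1, 4, config=config)


# ---------------------------------------------------------------- Australian

def test_australian_exhaustive_table_oracle(config):
    """All 125 nomogram cells equal the log-scaled product rule (2 dp)."""
    for l in range(1, 6):
        for e in range(1, 6):
            for s in range(1, 6):
                expected = 1 + 4 * math.log(l * e * s) / math.log(125)
                got = australian_assess(l, e, s, config)
                assert got == pytest.approx(expected, abs=0.005)
    assert australian_assess(5, 5, 5, config) == 5.0
    assert australian_assess(1, 1, 1, config) == 1.0
    with pytest.raises(ParameterError):
        australian_assess(0, 1, 1, config)


# ---------------------------------------------------------------- Romanian

def test_romanian_exhaustive_grid_oracle(config):
    """All 42 severity×probability cells equal ceil(s·p/6) capped at 7."""
    for s in range(1, 8):
        for p in range(1, 7):
            assert romanian_assess(s, p, config) == min(7, math.ceil(s * p / 6))
    assert romanian_assess(7, 6, config) == 7
    assert romanian_assess(1, 1, config) == 1
    with pytest.raises(ParameterError):
        romanian_assess(8, 1, config)
    with pytest.raises(ParameterError):
        romanian_assess(1, 7, config)


def test_romanian_petrol_station_level_1(registry, config):
    """Low-exposure gasoline records map to the bottom of the 7-level grid."""
    recs = [record("Gasoline", ca, industry="Petrol station", location="Oiling")
            for ca in (0.0003, 0.044, 0.491)]
    results, _ = assess_all(recs, registry, ["Romanian"], config)
    assert [r.level for r in results] == [1, 1, 1]


# ---------------------------------------------------------------- orchestration

def test_assess_all_skips_epa_without_rfc(registry, config):
    results, skips = assess_all(
        [record("Silicious dust", 1.0, industry="Mining of soil and sand", location="Discharge")],
        registry, ["EPA"], config,
    )
    assert results == []
    assert len(skips) == 1 and "no RfC" in skips[0].reason


def test_assess_all_scores_mn_with_all_six(registry, config):
    results, skips = assess_all(
        [record("Manganese and inorganic compounds", 0.1)], registry, config=config
    )
    assert len(results) == 6
    assert {r.method for r in results} == {
        "EPA", "COSHH", "Singaporean", "ICMM", "Australian", "Romanian"
    }
    assert skips == []


def test_assess_all_is_deterministic(registry, config):
    recs = [record("Benzene", 0.05), record("Xylene", 0.3)]
    first, _ = assess_all(recs, registry, config=config)
    second, _ = assess_all(recs, registry, config=config)
    assert first == second


def test_assess_all_empty_input_warns(registry, config, caplog):
    with caplog.at_level("WARNING"):
        results, skips = assess_all([], registry, config=config)
    assert results == [] and skips == []
    assert any("empty" in rec.message for rec in caplog.records)


def test_assess_all_unknown_method_rejected(registry, config):
    with pytest.raises(ParameterError):
        assess_all([record("Benzene", 0.05)], registry, ["EPA", "NIOSH"], config)


def test_every_level_lies_on_its_method_scale(registry, config):
    from ohra import default_scales

    scales = default_scales()
    recs = [
        record(h, ca)
        for h in ("Manganese and inorganic compounds", "Benzene", "Xylene", "Ethyl acetate")
        for ca in (0.001, 0.1, 5.0)
    ]
    results, _ = assess_all(recs, registry, config=config)
    for r in results:
        assert scales[r.method].contains(r.level), (r.method, r.level)
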