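"""Salt-to-ion conversion, dilution series, and the factorial input table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutrifuzz.media import (
    MediumFormulation,
    SaltDefinition,
    UnresolvedSaltError,
    dilution_series,
    ion_profile,
    build_factor_table,
    load_ms_media,
    load_salt_registry,
    round_half_up,
    variable_ions,
    MACRO_SALTS,
    MICRO_SALTS,
)


@pytest.mark.parametrize(
    "medium,ion,expected_mM,tol",
    [
        # published concentration anchors: ammonium of the half-macro medium,
        # copper of the half-micro medium, sodium (EDTA + molybdate) of full MS
        ("1/2MSM", "NH4+", 10.31, 0.005),
        ("1/2MSμ", "Cu2+", 0.05e-3, 0.005e-3),
        ("MS", "Na+", 0.2237, 0.0005),
        ("MS", "MoO42-", 1.033e-3, 0.001e-3),
    ],
)
def test_ion_profile_reproduces_reported_concentrations(
    registry, media_by_name, medium, ion, expected_mM, tol
):
    profile = ion_profile(media_by_name[medium], registry)
    assert profile[ion] == pytest.approx(expected_mM, abs=tol)


def test_zero_macro_medium_has_zero_macro_derived_ions(registry, media_by_name):
    profile = ion_profile(media_by_name["0MSM"], registry)
    assert profile["NH4+"] == 0.0
    assert profile["NO3-"] == 0.0
    assert profile["Ca2+"] == 0.0
    assert profile["Mg2+"] == 0.0
    assert profile["H2PO4-"] == 0.0
    # sulfate persists through micronutrient sulfates and the iron source
    assert profile["SO42-"] > 0


def test_unknown_salt_is_reported_by_name(registry):
    bad = MediumFormulation("bad", {"KNO3": 100.0, "unobtainium": 1.0})
    with pytest.raises(UnresolvedSaltError, match="unobtainium"):
        ion_profile(bad, registry)


def test_dilution_series_reproduces_printed_media_table(registry, media_by_name):
    """Exact dilution of full MS reproduces every printed cell of the shipped
    media table after half-up rounding at that cell's printed precision."""
    printed = pd.read_csv(
        __import__("importlib.resources", fromlist=["files"])
        .files("nutrifuzz.data")
        .joinpath("media_table1.csv"),
        dtype=str,
    ).set_index("salt")
    base = media_by_name["MS"]
    for group, salts, suffix in (
        ("macro", MACRO_SALTS, "M"),
        ("micro", MICRO_SALTS, "μ"),
    ):
        series = dilution_series(base, group, [0.5, 0.25, 0.125, 0.0])
        for medium in series:
            assert medium.name in printed.columns
            for salt in salts:
                cell = printed.loc[salt, medium.name]
                decimals = len(cell.split(".")[1]) if "." in cell else 0
                computed = medium.salt_amounts[salt]
                assert round_half_up(computed, decimals) == float(cell), (
                    salt, medium.name, computed, cell,
                )


def test_dilution_leaves_iron_source_and_other_group_untouched(media_by_name):
    base = media_by_name["MS"]
    (half_micro,) = dilution_series(base, "micro", [0.5])
    assert half_micro.salt_amounts["Na2EDTA"] == base.salt_amounts["Na2EDTA"]
    assert half_micro.salt_amounts["FeSO4.7H2O"] == base.salt_amounts["FeSO4.7H2O"]
    assert half_micro.salt_amounts["KNO3"] == base.salt_amounts["KNO3"]
    assert half_micro.salt_amounts["MnSO4.4H2O"] == base.salt_amounts["MnSO4.4H2O"] / 2


def test_dilution_factor_outside_unit_interval_rejected(media_by_name):
    with pytest.raises(ValueError, match="invalid dilution factor"):
        dilution_series(media_by_name["MS"], "macro", [1.5])
    with pytest.raises(ValueError, match="invalid dilution factor"):
        dilution_series(media_by_name["MS"], "macro", [-0.1])


def test_variable_ions_of_design_media(registry, media):
    ions = variable_ions(media, registry)
    assert len(ions) == 16
    assert "Fe2+" not in ions and "EDTA" not in ions
    assert {"K+", "NO3-", "NH4+", "SO42-", "Na+", "MoO42-", "Cu2+", "I-"} <= set(ions)


def test_variable_ions_trivial_cases(registry, media_by_name):
    ms = media_by_name["MS"]
    assert variable_ions([ms, ms], registry) == []
    two = [
        MediumFormulation("a", {"KNO3": 100.0}),
        MediumFormulation("b", {"KNO3": 200.0}),
    ]
    assert set(variable_ions(two, registry)) == {"K+", "NO3-"}
    with pytest.raises(ValueError):
        variable_ions([], registry)


def test_factor_table_full_crossing(registry, media, design_table):
    assert len(design_table) == 3 * 9 * 4
    ion_cols = [c for c in design_table.columns if c not in ("genotype", "medium", "subculture")]
    assert len(ion_cols) == 16
    # full design: every factor cell present exactly once
    counts = design_table.groupby(["genotype", "medium", "subculture"]).size()
    assert (counts == 1).all()


def test_factor_table_small_crossings(registry, media, media_by_name):
    assert len(build_factor_table(["BD"], media[:1], [1], registry)) == 1
    # three media spanning both dilution arms keep all 16 ions varying
    span = [media_by_name[n] for n in ("MS", "1/2MSM", "1/2MSμ")]
    t = build_factor_table(["BD", "BH"], span, [1, 2], registry)
    assert len(t) == 12
    assert len([c for c in t.columns if c not in ("genotype", "medium", "subculture")]) == 16
    # media varying only macronutrients yield only macronutrient-derived ions
    macro_only = build_factor_table(["BD"], media[:3], [1], registry)
    ions = [c for c in macro_only.columns if c not in ("genotype", "medium", "subculture")]
    assert set(ions) == {"K+", "NO3-", "NH4+", "Ca2+", "Cl-", "Mg2+", "SO42-", "H2PO4-"}


def test_factor_table_rejects_duplicate_media(registry, media):
    with pytest.raises(ValueError, match="duplicate"):
        build_factor_table(["BD"], [media[0], media[0]], [1], registry)


amounts = st.dictionaries(
    st.sampled_from([s.name for s in load_salt_registry()]),
    st.floats(0, 5000, allow_nan=False),
    min_size=1,
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(amounts=amounts, lam=st.floats(0, 8, allow_nan=False))
def test_ion_profile_is_linear_and_additive(amounts, lam):
    registry = load_salt_registry()
    medium = MediumFormulation("m", amounts)
    profile = ion_profile(medium, registry)
    scaled = ion_profile(medium.scaled(lam), registry)
    for ion, value in profile.concentrations.items():
        assert scaled[ion] == pytest.approx(lam * value, rel=1e-12, abs=1e-15)
    # additivity: the mixture profile is the sum of single-salt profiles
    parts = [
        ion_profile(MediumFormulation("p", {salt: amount}), registry)
        for salt, amount in amounts.items()
    ]
    for ion, value in profile.concentrations.items():
        assert sum(p[ion] for p in parts) == pytest.approx(value, rel=1e-9, abs=1e-15)


def test_salt_definition_validation():
    with pytest.raises(ValueError):
        SaltDefinition("x", -1.0, (("K+", 1),))
    with pytest.raises(ValueError):
        SaltDefinition("x", 10.0, ())
    with pytest.raises(ValueError):
        SaltDefinition("x", 10.0, (("K+", 0),))
    with pytest.raises(ValueError):
        MediumFormulation("m", {"KNO3": -5.0})
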