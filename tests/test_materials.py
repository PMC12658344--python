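"""Composite registry, stoichiometry and the mixture rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbequiv.materials import (Composite, FormulaError, composite_mu_rho,
                               elemental_fractions, get_composite, linear_mu,
                               load_registry, parse_formula,
                               pure_element_composite, registry_frame)
from pbequiv.physics import load_element_table, mu_rho


@pytest.mark.parametrize("formula,expected", [
    ("Bi2O3", {"Bi": 0.8970, "O": 0.1030}),
    ("W", {"W": 1.0}),
    ("C2H3Cl", {"C": 0.3844, "H": 0.0484, "Cl": 0.5672}),
    ("BaSO4", {"Ba": 0.5884, "S": 0.1374, "O": 0.2742}),
])
def test_parse_formula_stoichiometry(formula, expected):
    got = parse_formula(formula).element_fractions
    assert set(got) == set(expected)
    for sym, frac in expected.items():
        assert got[sym] == pytest.approx(frac, abs=5e-4)
    assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("bad", ["Xx2O3", "W0", "lowercase", ""])
def test_parse_formula_rejects(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_registry_matches_design_table(registry, by_abbr):
    assert len(registry) == 18
    for comp in registry:
        assert comp.components["C2H3Cl"] == pytest.approx(22.0)
        assert sum(comp.components.values()) == pytest.approx(100.0)
    assert by_abbr["Pb-PVC"].density == 3.46
    assert by_abbr["Pb-PVC"].components["Pb"] == 78
    bi_ba = by_abbr["Bi-Ba"]
    assert bi_ba.components == {"BaSO4": 39, "Bi2O3": 39, "C2H3Cl": 22}
    assert bi_ba.density == 2.886
    wsg = by_abbr["W-Sn-Gd"]
    assert wsg.components == {"W": 26, "Sn": 26, "Gd2O3": 26, "C2H3Cl": 22}
    assert wsg.density == 3.288


def test_registry_lookup_normalizes_dashes():
    assert get_composite("Bi–Ba").abbreviation == "Bi-Ba"
    with pytest.raises(KeyError):
        get_composite("unobtainium")


def test_elemental_fractions_conserve_mass(registry):
    for comp in registry:
        fracs = elemental_fractions(comp)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)
    pbpvc = get_composite("Pb-PVC")
    assert elemental_fractions(pbpvc)["Pb"] == pytest.approx(0.78)
    bi_gd = get_composite("Bi-Gd")
    assert elemental_fractions(bi_gd)["Bi"] == pytest.approx(
        0.39 * 0.8970, abs=2e-4)


def test_mixture_rule_single_element_identity():
    lead = pure_element_composite("Pb", 11.35)
    table = load_element_table("Pb")
    for e in (30.0, 60.0, 100.0, 145.0):
        assert composite_mu_rho(lead, e) == pytest.approx(mu_rho(table, e),
                                                          rel=1e-12)
        assert linear_mu(lead, e) == pytest.approx(11.35 * mu_rho(table, e),
                                                   rel=1e-12)


def test_mixture_rule_two_terms():
    pbpvc = get_composite("Pb-PVC")
    pvc = Composite(name="pvc", abbreviation="pvc",
                    components={"C2H3Cl": 100}, density=1.4)
    lead = pure_element_composite("Pb", 11.35)
    e = 100.0
    expected = 0.78 * composite_mu_rho(lead, e) + 0.22 * composite_mu_rho(pvc, e)
    assert composite_mu_rho(pbpvc, e) == pytest.approx(expected, rel=1e-12)


def test_k_edge_discontinuity_propagates():
    for abbr, edge in [("Pb-PVC", 88.005), ("Bi-Gd", 50.239)]:
        comp = get_composite(abbr)
        below = composite_mu_rho(comp, edge - 1e-3)
        above = composite_mu_rho(comp, edge + 1e-3)
        assert above > below * 1.5


@settings(derandomize=True, max_examples=25)
@given(w=st.floats(min_value=0.01, max_value=0.99),
       e=st.floats(min_value=2.0, max_value=149.0))
def test_mixture_rule_is_linear_in_weights(w, e):
    a = get_composite("W-Sn-Gd")
    b = get_composite("Bi-Ba")
    blend_components = {}
    for comp, scale in ((a, w), (b, 1 - w)):
        for formula, pct in comp.components.items():
            blend_components[formula] = (blend_components.get(formula, 0.0)
                                         + scale * pct)
    blend = Composite(name="blend", abbreviation="blend",
                      components=blend_components, density=1.0)
    expected = w * composite_mu_rho(a, e) + (1 - w) * composite_mu_rho(b, e)
    assert composite_mu_rho(blend, e) == pytest.approx(expected, rel=1e-9)


def test_registry_frame_layout(registry):
    df = registry_frame()
    assert len(df) == 18
    assert df["density_g_cm3"].tolist() == [c.density for c in registry]
    filler_cols = ["Pb", "W", "BaSO4", "Sn", "Bi2O3", "Sb2O3", "Gd2O3"]
    assert (df[filler_cols].sum(axis=1) + df["C2H3Cl"]).eq(100).all()
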