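"""Curve fitting, intersection solving and equivalence summaries."""

import numpy as np
import pytest

from pbequiv.equivalence import (FitError, OutOfBracketError, areal_mass,
                                 build_summary, equivalent_thickness,
                                 fit_curve, mass_thickness_scatter,
                                 pb_reference_transmission, rank_by_mass,
                                 solve_t_eq)
from pbequiv.materials import get_composite, linear_mu, pure_element_composite
from pbequiv.synthetic import (NoisyCurveSpec, analytic_t_eq,
                               make_monoenergetic, make_noisy_curve)
from pbequiv.transport import TransmissionCurve, build_curve


def _curve_from_model(model, thicknesses):
    t = np.asarray(thicknesses, float)
    return TransmissionCurve(material="synthetic", kvp=0.0, thicknesses_mm=t,
                             transmission=model(t), stderr=np.zeros_like(t))


def test_single_exponential_recovers_rate_exactly():
    curve = _curve_from_model(lambda t: np.exp(-2.5 * t),
                              (0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0))
    fit = fit_curve(curve, kind="single-exponential")
    assert fit.params["rate_per_mm"] == pytest.approx(2.5, abs=1e-6)
    assert fit.max_abs_log_residual < 1e-9


def test_biexponential_recovery_with_noise():
    spec = NoisyCurveSpec(amplitudes=(0.7, 0.3), rates=(8.0, 1.5),
                          sigma=0.005, seed=123)
    fit = fit_curve(make_noisy_curve(spec), kind="bi-exponential")
    assert fit.params["a1"] == pytest.approx(0.7, rel=0.05)
    assert fit.params["a2"] == pytest.approx(0.3, rel=0.05)
    assert fit.params["b1_per_mm"] == pytest.approx(8.0, rel=0.05)
    assert fit.params["b2_per_mm"] == pytest.approx(1.5, rel=0.05)


def test_interpolant_passes_through_knots(spectra):
    comp = get_composite("Bi-Gd")
    curve = build_curve(spectra[100], comp)
    fit = fit_curve(curve)
    np.testing.assert_allclose(fit(curve.thicknesses_mm), curve.transmission,
                               rtol=1e-12)
    assert float(fit(0.0)) == pytest.approx(1.0, rel=1e-12)


def test_fit_rejects_rising_input():
    t = np.array([0.5, 1.0, 1.5, 2.0])
    rising = TransmissionCurve(material="bad", kvp=0.0, thicknesses_mm=t,
                               transmission=np.array([0.5, 0.6, 0.7, 0.8]),
                               stderr=np.zeros(4))
    with pytest.raises(FitError):
        fit_curve(rising)


def test_solve_identity_and_brackets(spectra):
    comp = get_composite("W-Sb")
    fit = fit_curve(build_curve(spectra[120], comp))
    target = float(fit(1.5))
    assert solve_t_eq(fit, target) == pytest.approx(1.5, abs=1e-6)
    with pytest.raises(OutOfBracketError):
        solve_t_eq(fit, float(fit(3.0)) / 10.0)  # needs > 3 mm


def test_monoenergetic_closed_form_ratio(registry):
    mono = make_monoenergetic(100.0)
    lead = pure_element_composite("Pb", 11.35)
    for comp in registry[:4] + [get_composite("Pb-PVC")]:
        expected = analytic_t_eq(linear_mu(comp, 100.0),
                                 linear_mu(lead, 100.0), 0.5)
        grid = np.geomspace(expected / 4, expected * 1.8, 6)
        res = equivalent_thickness(mono, comp, 0.5, thicknesses_mm=grid)
        assert res.t_eq_mm == pytest.approx(expected, abs=1e-6)


def test_pbpvc_monoenergetic_reference_value():
    # 78 wt% Pb composite at 100 keV against 0.5 mm pure lead: the linear-mu
    # ratio puts the equivalent thickness near 2.08 mm
    pbpvc = get_composite("Pb-PVC")
    lead = pure_element_composite("Pb", 11.35)
    t_eq = analytic_t_eq(linear_mu(pbpvc, 100.0), linear_mu(lead, 100.0), 0.5)
    assert t_eq == pytest.approx(2.08, abs=0.02)


def test_pb_reference_transmission_monotone(spectra):
    s = spectra[100]
    assert pb_reference_transmission(s, 0.0) == 1.0
    t35 = pb_reference_transmission(s, 0.35)
    t50 = pb_reference_transmission(s, 0.5)
    assert 0 < t50 < t35 < 1
    mono = make_monoenergetic(100.0)
    from pbequiv.physics import load_element_table, mu_rho
    expected = np.exp(-mu_rho(load_element_table("Pb"), 100.0) * 11.35 * 0.05)
    assert pb_reference_transmission(mono, 0.5) == pytest.approx(expected,
                                                                 rel=1e-12)


def test_engine_consistency_enforced(spectra):
    with pytest.raises(ValueError):
        pb_reference_transmission(spectra[80], 0.5, engine="magic")


def test_areal_mass_unit_identity():
    comp = get_composite("Pb-PVC")
    assert areal_mass(comp, 0.0) == 0.0
    assert areal_mass(comp, 2.07) == pytest.approx(7.16, abs=0.01)
    wsg = get_composite("W-Sn-Gd")
    assert areal_mass(wsg, 1.62) == pytest.approx(5.33, abs=0.01)


def test_t_eq_grid_insensitivity(spectra):
    comp = get_composite("Bi-Sb")
    coarse = equivalent_thickness(spectra[100], comp, 0.5)
    fine_grid = np.sort(np.concatenate([
        np.asarray([0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]),
        np.asarray([0.15, 0.35, 0.75, 1.25, 1.75, 2.25, 2.75])]))
    fine = equivalent_thickness(spectra[100], comp, 0.5,
                                thicknesses_mm=fine_grid)
    assert fine.t_eq_mm == pytest.approx(coarse.t_eq_mm, rel=0.01)


def test_t_eq_orderings(spectra, registry):
    summary = build_summary(registry[:3], [spectra[80]])
    df = summary.to_frame()
    for mat in df.material.unique():
        t35 = df[(df.material == mat) & (df.pb_target_mm == 0.35)].t_eq_mm.iloc[0]
        t50 = df[(df.material == mat) & (df.pb_target_mm == 0.5)].t_eq_mm.iloc[0]
        assert t50 > t35


def test_richer_filler_reduces_t_eq(spectra):
    from pbequiv.materials import Composite
    w78 = Composite(name="w78", abbreviation="w78",
                    components={"W": 78, "C2H3Cl": 22}, density=3.4)
    w90 = Composite(name="w90", abbreviation="w90",
                    components={"W": 90, "C2H3Cl": 10}, density=3.4)
    r78 = equivalent_thickness(spectra[100], w78, 0.5)
    r90 = equivalent_thickness(spectra[100], w90, 0.5)
    assert r90.t_eq_mm < r78.t_eq_mm


def test_summary_exports(spectra, registry):
    summary = build_summary(registry, [spectra[100]])
    assert len(summary.results) == 18 * 2
    thick = summary.thickness_table()
    assert thick.shape == (18, 2)
    inc = summary.percent_mass_increase()
    assert len(inc) == 18
    ranking = rank_by_mass(summary, 100, 0.5)
    assert len(ranking) == 18
    assert ranking[0][1] <= ranking[-1][1]
    scatter = mass_thickness_scatter(summary)
    assert {"material", "kvp", "pb_target_mm", "t_eq_mm",
            "areal_mass_kg_m2"} <= set(scatter.columns)
    assert scatter.attrs["trend_slope"] > 0
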