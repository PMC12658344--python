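"""Deterministic and Monte Carlo slab transmission."""

import numpy as np
import pytest

from pbequiv.materials import get_composite, pure_element_composite
from pbequiv.synthetic import make_monoenergetic
from pbequiv.transport import (DEFAULT_THICKNESSES_MM, GeometrySpec, MCConfig,
                               build_curve, mc_transmission,
                               narrow_beam_transmission)
from pbequiv.physics import load_element_table, mu_rho


def test_zero_thickness_is_unity(spectra):
    comp = get_composite("W-Sn-Gd")
    assert narrow_beam_transmission(spectra[100], comp, 0.0) == 1.0
    with pytest.raises(ValueError):
        narrow_beam_transmission(spectra[100], comp, -0.1)


def test_monoenergetic_beer_lambert():
    lead = pure_element_composite("Pb", 11.35)
    mono = make_monoenergetic(100.0)
    mu = 11.35 * mu_rho(load_element_table("Pb"), 100.0)
    got = narrow_beam_transmission(mono, lead, 1.0)
    assert got == pytest.approx(np.exp(-mu * 0.1), rel=1e-12)


def test_transmission_invariant_to_spectrum_scale(spectra):
    comp = get_composite("Bi-Ba")
    s = spectra[120]
    t1 = narrow_beam_transmission(s, comp, 1.5)
    t2 = narrow_beam_transmission(s.scaled(1234.5), comp, 1.5)
    assert t1 == pytest.approx(t2, rel=1e-14)
    k1 = narrow_beam_transmission(s, comp, 1.5, weighting="kerma")
    k2 = narrow_beam_transmission(s.scaled(0.001), comp, 1.5, weighting="kerma")
    assert k1 == pytest.approx(k2, rel=1e-14)
    assert k1 != pytest.approx(t1, rel=1e-3)  # the weightings differ


def test_beam_hardening_superadditivity(spectra):
    comp = get_composite("W-Gd")
    s = spectra[100]
    for t1, t2 in [(0.5, 0.5), (1.0, 2.0), (0.2, 1.3)]:
        prod = (narrow_beam_transmission(s, comp, t1)
                * narrow_beam_transmission(s, comp, t2))
        assert narrow_beam_transmission(s, comp, t1 + t2) >= prod
    mono = make_monoenergetic(80.0)
    lhs = narrow_beam_transmission(mono, comp, 1.5)
    rhs = (narrow_beam_transmission(mono, comp, 1.0)
           * narrow_beam_transmission(mono, comp, 0.5))
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_deterministic_curve_shape(spectra):
    comp = get_composite("Bi-Sn")
    curve = build_curve(spectra[80], comp)
    assert len(curve.thicknesses_mm) == 8
    assert tuple(curve.thicknesses_mm) == DEFAULT_THICKNESSES_MM
    assert np.all(np.diff(curve.transmission) < 0)
    assert np.all(curve.stderr == 0)
    # log-transmission convex in thickness (hardening)
    log_t = np.log(curve.transmission)
    second = np.diff(log_t, 2)  # uneven grid, but convexity still shows
    slopes = np.diff(log_t) / np.diff(curve.thicknesses_mm)
    assert np.all(np.diff(slopes) > 0)


def test_mc_same_seed_bit_identical(spectra):
    comp = get_composite("W-Sn")
    cfg = MCConfig(n_histories=50_000, seed=11)
    a = mc_transmission(spectra[100], comp, 1.0, mc=cfg)
    b = mc_transmission(spectra[100], comp, 1.0, mc=cfg)
    assert a == b
    c = mc_transmission(spectra[100], comp, 1.0,
                        mc=MCConfig(n_histories=50_000, seed=12))
    assert c != a


def test_mc_zero_thickness(spectra):
    comp = get_composite("W-Sn")
    t, se = mc_transmission(spectra[100], comp, 0.0,
                            mc=MCConfig(n_histories=10_000, seed=1))
    assert t == 1.0 and se == 0.0


def test_mc_primaries_match_narrow_beam(spectra):
    comp = get_composite("W-Sn-Gd")
    s = spectra[100]
    for thickness in (0.5, 2.0):
        mc_t, rel = mc_transmission(
            s, comp, thickness,
            mc=MCConfig(n_histories=400_000, seed=5, primaries_only=True))
        nb = narrow_beam_transmission(s, comp, thickness)
        assert abs(mc_t - nb) <= 3.0 * rel * mc_t


def test_mc_broad_beam_buildup(spectra):
    comp = get_composite("W-Sn-Gd")
    s = spectra[120]
    broad, rel_b = mc_transmission(s, comp, 2.0,
                                   mc=MCConfig(n_histories=300_000, seed=9))
    prim, rel_p = mc_transmission(
        s, comp, 2.0, mc=MCConfig(n_histories=300_000, seed=9,
                                  primaries_only=True))
    assert broad + 3 * rel_b * broad >= prim  # scatter can only add signal


def test_mc_stderr_scaling(spectra):
    comp = get_composite("Bi-Sn")
    s = spectra[100]
    _, rel_small = mc_transmission(s, comp, 1.0,
                                   mc=MCConfig(n_histories=50_000, seed=2))
    _, rel_big = mc_transmission(s, comp, 1.0,
                                 mc=MCConfig(n_histories=200_000, seed=2))
    assert rel_small / rel_big == pytest.approx(2.0, rel=0.20)


def test_mc_validation_errors(spectra):
    comp = get_composite("Bi-Sn")
    with pytest.raises(ValueError):
        MCConfig(n_histories=0)
    with pytest.raises(ValueError):
        MCConfig(energy_cutoff_kev=0.1)
    with pytest.raises(ValueError):
        GeometrySpec(detector_radius_cm=0)
    with pytest.raises(ValueError):
        mc_transmission(spectra[100], comp, -1.0,
                        mc=MCConfig(n_histories=100, seed=0))


def test_build_curve_mc_engine_records_meta(spectra):
    comp = get_composite("W-Sn")
    curve = build_curve(spectra[100], comp, thicknesses_mm=(0.5, 1.5, 3.0),
                        engine="mc", mc=MCConfig(n_histories=60_000, seed=4))
    assert curve.meta["engine"] == "mc"
    assert curve.meta["n_histories"] == 60_000
    assert np.all(curve.stderr > 0)
    assert np.all(np.diff(curve.transmission) < 0)
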