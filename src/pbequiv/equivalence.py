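"""Lead-equivalent thickness and areal mass of shielding composites.

The procedure mirrors standard lead-equivalence practice: compute the
transmitted fraction of a reference pure-lead slab (0.35 or 0.5 mm,
rho = 11.35 g/cm^3) under a given spectrum, build the composite's
transmission-vs-thickness curve on an eight-point grid, fit a continuous
attenuation curve, and solve for the thickness whose transmission equals
the lead reference.  Areal mass follows as density x thickness -- with
density in g/cm^3 and thickness in mm the product is directly in kg/m^2.

The default fit is a monotone piecewise-cubic interpolant of the
log-transmission points (a polyenergetic curve is not a single exponential
because of beam hardening); single- and bi-exponential least-squares fits
are available for comparison, with residuals reported so the choice is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .materials import Composite, PB_DENSITY, pure_element_composite
from .spectra import Spectrum
from .transport import (DEFAULT_THICKNESSES_MM, GeometrySpec, MCConfig,
                        TransmissionCurve, build_curve,
                        mc_transmission, narrow_beam_transmission)

__all__ = [
    "AttenuationFit",
    "EquivalenceResult",
    "SummaryTable",
    "FitError",
    "OutOfBracketError",
    "PB_TARGETS_MM",
    "pb_reference_transmission",
    "fit_curve",
    "solve_t_eq",
    "areal_mass",
    "equivalent_thickness",
    "build_summary",
    "rank_by_mass",
    "mass_thickness_scatter",
]

#: standard protection levels, mm of pure lead
PB_TARGETS_MM = (0.35, 0.5)

FIT_KINDS = ("log-pchip", "single-exponential", "bi-exponential")


class FitError(ValueError):
    """Attenuation-curve fit failed or input is unusably non-monotone."""


class OutOfBracketError(ValueError):
    """Target transmission lies outside the fitted thickness range."""


@dataclass(frozen=True)
class AttenuationFit:
    """A positive, strictly decreasing fitted transmission curve T(t)."""

    kind: str
    t_min: float
    t_max: float
    params: dict = field(default_factory=dict, compare=False)
    residuals: np.ndarray | None = field(default=None, compare=False)
    _predict: object = field(default=None, repr=False, compare=False)
    source: TransmissionCurve | None = field(default=None, repr=False,
                                             compare=False)

    def __call__(self, thickness_mm):
        t = np.asarray(thickness_mm, dtype=float)
        if np.any(t < self.t_min - 1e-12) or np.any(t > self.t_max + 1e-12):
            raise OutOfBracketError(
                f"thickness {t} mm outside fitted range "
                f"[{self.t_min}, {self.t_max}] mm")
        return self._predict(t)

    @property
    def max_abs_log_residual(self) -> float:
        if self.residuals is None or len(self.residuals) == 0:
            return 0.0
        return float(np.max(np.abs(self.residuals)))


def fit_curve(curve: TransmissionCurve, kind: str = "log-pchip",
              anchor_zero: bool = True) -> AttenuationFit:
    """Fit a continuous attenuation curve through a transmission curve.

    Fitting happens in log-transmission space.  ``anchor_zero`` prepends the
    exact point T(0) = 1, which holds for both engines by construction and
    lets the fit be evaluated down to zero thickness.
    """
    if kind not in FIT_KINDS:
        raise FitError(f"unknown fit kind {kind!r}; expected one of {FIT_KINDS}")
    t = np.asarray(curve.thicknesses_mm, float)
    tr = np.asarray(curve.transmission, float)
    se = np.asarray(curve.stderr, float)
    if len(t) < 3:
        raise FitError("need at least 3 curve points")

    # reject curves that are non-monotone beyond statistical noise
    rises = np.diff(tr) > 0
    if np.any(rises):
        tol = 3.0 * (se[1:] + se[:-1]) * tr[:-1]
        if np.any(np.diff(tr)[rises] > tol[rises]):
            raise FitError("transmission rises with thickness beyond noise "
                           "tolerance; not an attenuation curve")

    if anchor_zero:
        t_fit = np.concatenate([[0.0], t])
        log_fit = np.concatenate([[0.0], np.log(tr)])
    else:
        t_fit, log_fit = t, np.log(tr)

    if kind == "log-pchip":
        if np.any(np.diff(log_fit) >= 0):
            # enforce strict decrease for the interpolant (tiny MC wiggles)
            log_fit = np.minimum.accumulate(log_fit - 1e-15 * np.arange(len(log_fit)))
        interp = PchipInterpolator(t_fit, log_fit, extrapolate=False)
        predict = lambda x: np.exp(interp(x))  # noqa: E731
        resid = np.zeros_like(t)
        params = {"knots_mm": t_fit.tolist()}
    elif kind == "single-exponential":
        slope = np.polyfit(t_fit, log_fit, 1)[0]
        (rate,), _ = curve_fit(lambda x, b: -b * x, t_fit, log_fit,
                               p0=[max(-slope, 1e-6)])
        predict = lambda x: np.exp(-rate * np.asarray(x, float))  # noqa: E731
        resid = np.log(tr) + rate * t
        params = {"rate_per_mm": float(rate)}
    else:  # bi-exponential
        hi = -np.gradient(log_fit, t_fit)[0]
        lo = (log_fit[-2] - log_fit[-1]) / (t_fit[-1] - t_fit[-2])

        def model(x, a1, b1, b2):
            a1 = np.clip(a1, 1e-9, 1.0 - 1e-9)
            return np.log(a1 * np.exp(-b1 * x) + (1 - a1) * np.exp(-b2 * x))

        try:
            popt, _ = curve_fit(model, t_fit, log_fit,
                                p0=[0.5, max(hi, 1e-3), max(lo, 1e-4)],
                                maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise FitError(f"bi-exponential fit failed: {exc}") from exc
        a1, b1, b2 = popt
        a1 = float(np.clip(a1, 1e-9, 1.0 - 1e-9))
        if b1 < b2:  # canonical order: fast component first
            a1, b1, b2 = 1.0 - a1, b2, b1
        predict = lambda x: (a1 * np.exp(-b1 * np.asarray(x, float))  # noqa: E731
                             + (1 - a1) * np.exp(-b2 * np.asarray(x, float)))
        resid = np.log(tr) - model(t, a1, b1, b2)
        params = {"a1": a1, "a2": 1.0 - a1, "b1_per_mm": float(b1),
                  "b2_per_mm": float(b2)}

    # MC consistency: the fit must pass within 3 sigma of every point
    if np.any(se > 0):
        pred = predict(t)
        if np.any(np.abs(pred - tr) > 3.0 * se * tr + 1e-12):
            raise FitError("fitted curve misses a point by more than "
                           "3x its standard error")

    return AttenuationFit(kind=kind, t_min=float(t_fit[0]),
                          t_max=float(t_fit[-1]), params=params,
                          residuals=resid, _predict=predict, source=curve)


def solve_t_eq(fit: AttenuationFit, target_transmission: float) -> float:
    """Thickness (mm) at which the fitted curve reaches ``target_transmission``.

    Bracketed root finding on the fitted range; refuses to extrapolate.
    """
    if not 0 < target_transmission:
        raise ValueError("target transmission must be positive")
    f_lo = float(fit(fit.t_min))
    f_hi = float(fit(fit.t_max))
    if target_transmission > f_lo or target_transmission < f_hi:
        raise OutOfBracketError(
            f"target transmission {target_transmission:.5g} outside the "
            f"fitted range [{f_hi:.5g} at {fit.t_max} mm, {f_lo:.5g} at "
            f"{fit.t_min} mm]; extend the thickness grid instead of "
            "extrapolating")
    root = brentq(lambda x: float(fit(x)) - target_transmission,
                  fit.t_min, fit.t_max, xtol=1e-12, rtol=1e-12)
    return float(root)


def areal_mass(composite: Composite, t_eq_mm: float) -> float:
    """Mass per unit area, kg/m^2 (= density g/cm^3 x thickness mm)."""
    if t_eq_mm < 0:
        raise ValueError("thickness cannot be negative")
    return composite.density * t_eq_mm


def pb_reference_transmission(spectrum: Spectrum, pb_thickness_mm: float,
                              engine: str = "deterministic",
                              weighting: str = "fluence",
                              geometry: GeometrySpec | None = None,
                              mc: MCConfig | None = None) -> float:
    """Transmitted fraction of a pure-lead slab under the same engine."""
    if pb_thickness_mm < 0:
        raise ValueError("lead thickness cannot be negative")
    if pb_thickness_mm == 0:
        return 1.0
    lead = pure_element_composite("Pb", PB_DENSITY)
    if engine == "deterministic":
        return narrow_beam_transmission(spectrum, lead, pb_thickness_mm,
                                        weighting)
    if engine == "mc":
        mc = mc or MCConfig()
        tally = "energy" if weighting == "kerma" else "fluence"
        mc = MCConfig(n_histories=mc.n_histories, seed=mc.seed,
                      coherent_enabled=mc.coherent_enabled,
                      primaries_only=mc.primaries_only,
                      energy_cutoff_kev=mc.energy_cutoff_kev, tally=tally)
        value, _ = mc_transmission(spectrum, lead, pb_thickness_mm,
                                   geometry=geometry, mc=mc)
        return value
    raise ValueError(f"unknown engine {engine!r}")


@dataclass(frozen=True)
class EquivalenceResult:
    """Lead-equivalent thickness of one composite at one spectrum/target."""

    material: str
    kvp: float
    pb_target_mm: float
    target_transmission: float
    t_eq_mm: float
    areal_mass_kg_m2: float
    fit_kind: str = "log-pchip"
    max_abs_log_residual: float = 0.0

    def as_dict(self) -> dict:
        return {"material": self.material, "kvp": self.kvp,
                "pb_target_mm": self.pb_target_mm,
                "target_transmission": self.target_transmission,
                "t_eq_mm": self.t_eq_mm,
                "areal_mass_kg_m2": self.areal_mass_kg_m2,
                "fit_kind": self.fit_kind,
                "max_abs_log_residual": self.max_abs_log_residual}


def equivalent_thickness(spectrum: Spectrum, composite: Composite,
                         pb_target_mm: float,
                         engine: str = "deterministic",
                         weighting: str = "fluence",
                         fit_kind: str = "log-pchip",
                         thicknesses_mm=DEFAULT_THICKNESSES_MM,
                         geometry: GeometrySpec | None = None,
                         mc: MCConfig | None = None) -> EquivalenceResult:
    """Full single-cell pipeline: curve, fit, intersection, areal mass.

    The lead reference and the composite curve always run under the same
    engine and weighting (apples-to-apples contract).
    """
    target = pb_reference_transmission(spectrum, pb_target_mm, engine,
                                       weighting, geometry, mc)
    curve = build_curve(spectrum, composite, thicknesses_mm, engine,
                        weighting, geometry, mc)
    fit = fit_curve(curve, kind=fit_kind)
    t_eq = solve_t_eq(fit, target)
    return EquivalenceResult(
        material=composite.abbreviation, kvp=spectrum.kvp,
        pb_target_mm=pb_target_mm, target_transmission=target,
        t_eq_mm=t_eq, areal_mass_kg_m2=areal_mass(composite, t_eq),
        fit_kind=fit_kind, max_abs_log_residual=fit.max_abs_log_residual)


@dataclass(frozen=True)
class SummaryTable:
    """All material x spectrum x target equivalence results."""

    results: tuple[EquivalenceResult, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.results])

    def thickness_table(self) -> pd.DataFrame:
        """Materials x (kVp, Pb target) matrix of t_eq in mm."""
        df = self.to_frame()
        return df.pivot_table(index="material", columns=["kvp", "pb_target_mm"],
                              values="t_eq_mm").sort_index(
                                  axis=1, ascending=[True, False])

    def mass_table(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot_table(index="material", columns=["kvp", "pb_target_mm"],
                              values="areal_mass_kg_m2").sort_index(
                                  axis=1, ascending=[True, False])

    def percent_mass_increase(self) -> pd.DataFrame:
        """Per material/kVp percent areal-mass growth from 0.35 to 0.5 mm Pb.

        For a fixed material this equals the thickness ratio, so it is also
        the percent thickness increase.
        """
        df = self.to_frame()
        wide = df.pivot_table(index=["material", "kvp"],
                              columns="pb_target_mm",
                              values="areal_mass_kg_m2")
        if not {0.35, 0.5} <= set(wide.columns):
            raise ValueError("percent increase needs both 0.35 and 0.5 mm "
                             "targets in the summary")
        out = ((wide[0.5] - wide[0.35]) / wide[0.35] * 100.0).rename(
            "mass_increase_pct").reset_index()
        return out

    def range_stats(self) -> pd.DataFrame:
        """Min/max equivalent thickness per Pb target across all cells."""
        df = self.to_frame()
        g = df.groupby("pb_target_mm")["t_eq_mm"]
        return pd.DataFrame({"min_mm": g.min(), "max_mm": g.max()})


def build_summary(registry: list[Composite], spectra: list[Spectrum],
                  targets=PB_TARGETS_MM, engine: str = "deterministic",
                  weighting: str = "fluence", fit_kind: str = "log-pchip",
                  thicknesses_mm=DEFAULT_THICKNESSES_MM,
                  geometry: GeometrySpec | None = None,
                  mc: MCConfig | None = None) -> SummaryTable:
    """Evaluate every (material, spectrum, target) cell with one engine."""
    results = []
    for spectrum in spectra:
        for comp in registry:
            for target in targets:
                try:
                    results.append(equivalent_thickness(
                        spectrum, comp, target, engine, weighting, fit_kind,
                        thicknesses_mm, geometry, mc))
                except Exception as exc:
                    raise RuntimeError(
                        f"equivalence failed for material={comp.abbreviation} "
                        f"kvp={spectrum.kvp} target={target} mm: {exc}") from exc
    meta = {"engine": engine, "weighting": weighting, "fit_kind": fit_kind,
            "targets_mm": list(targets),
            "thicknesses_mm": list(np.asarray(thicknesses_mm, float)),
            "kvps": [s.kvp for s in spectra],
            "n_materials": len(registry)}
    return SummaryTable(results=tuple(results), meta=meta)


def rank_by_mass(summary: SummaryTable, kvp: float,
                 pb_target_mm: float) -> list[tuple[str, float]]:
    """Materials ordered lightest-first by areal mass; ties alphabetical."""
    df = summary.to_frame()
    sel = df[(df.kvp == kvp) & (df.pb_target_mm == pb_target_mm)]
    if sel.empty:
        raise ValueError(f"summary has no cells at kvp={kvp}, "
                         f"target={pb_target_mm}")
    sel = sel.sort_values(["areal_mass_kg_m2", "material"])
    return list(zip(sel.material, sel.areal_mass_kg_m2))


def mass_thickness_scatter(summary: SummaryTable) -> pd.DataFrame:
    """Scatter export (thickness vs mass) plus non-lead trend coefficients.

    The returned frame carries one row per cell; the least-squares trend of
    mass on thickness over the non-lead materials is attached as frame
    attributes ``trend_slope`` and ``trend_intercept``.
    """
    df = summary.to_frame()[["material", "kvp", "pb_target_mm", "t_eq_mm",
                             "areal_mass_kg_m2"]].copy()
    nonlead = df[df.material != "Pb-PVC"]
    if len(nonlead) < 2:  # degenerate subset, e.g. a Pb-PVC-only run
        nonlead = df
    slope, intercept = np.polyfit(nonlead.t_eq_mm,
                                  nonlead.areal_mass_kg_m2, 1)
    df.attrs["trend_slope"] = float(slope)
    df.attrs["trend_intercept"] = float(intercept)
    return df
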