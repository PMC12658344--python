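"""Shielding composite definitions and mixture-rule attenuation.

The registry encodes the 18 modelled flexible shields: each is 78 wt%
high-density filler (W, Sn, Bi2O3, BaSO4, Sb2O3, Gd2O3 or Pb, alone or in
equal-weight pairs/triples) bound in 22 wt% PVC, with the bulk density of
the moulded composite given alongside.  Mass attenuation coefficients of a
composite follow the elemental mixture rule

    (mu/rho)_mix(E) = sum_e w_e (mu/rho)_e(E),

with w_e the elemental mass fractions derived from component stoichiometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics import ATOMIC_MASS, load_element_table

__all__ = [
    "Compound",
    "Composite",
    "FormulaError",
    "parse_formula",
    "load_registry",
    "get_composite",
    "pure_element_composite",
    "elemental_fractions",
    "composite_mu_rho",
    "linear_mu",
    "registry_frame",
    "PVC_FORMULA",
    "PB_DENSITY",
]

#: PVC modelled as the pure vinyl chloride repeat unit
PVC_FORMULA = "C2H3Cl"

#: density of the pure-lead reference slab, g/cm^3
PB_DENSITY = 11.35

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Chemical formula could not be parsed."""


@dataclass(frozen=True)
class Compound:
    """A stoichiometric compound with elemental mass fractions."""

    formula: str
    element_fractions: dict[str, float]

    def __post_init__(self):
        total = sum(self.element_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise FormulaError(
                f"{self.formula}: element fractions sum to {total}, not 1")


def parse_formula(formula: str) -> Compound:
    """Elemental mass fractions of a chemical formula, e.g. ``Bi2O3``."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at "
                               f"position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {sym!r} in {formula!r}")
        n = int(num) if num else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
    if pos != len(formula) or not counts:
        raise FormulaError(f"cannot parse formula {formula!r}")
    molar = sum(ATOMIC_MASS[s] * n for s, n in counts.items())
    fracs = {s: ATOMIC_MASS[s] * n / molar for s, n in counts.items()}
    return Compound(formula=formula, element_fractions=fracs)


@dataclass(frozen=True)
class Composite:
    """A named shield material: component weight percents and bulk density."""

    name: str
    abbreviation: str
    components: dict[str, float]  # formula -> weight percent
    density: float  # g/cm^3

    def __post_init__(self):
        total = sum(self.components.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"{self.name}: component weight percents sum "
                             f"to {total}, not 100")
        if self.density <= 0:
            raise ValueError(f"{self.name}: nonpositive density")

    def mass_attenuation(self, energy, component: str = "total"):
        """Mixture-rule mass attenuation coefficient, cm^2/g."""
        return composite_mu_rho(self, energy, component)


def elemental_fractions(composite: Composite) -> dict[str, float]:
    """Elemental mass fractions of a composite (sum to 1)."""
    fracs: dict[str, float] = {}
    for formula, pct in composite.components.items():
        compound = parse_formula(formula)
        for sym, f in compound.element_fractions.items():
            fracs[sym] = fracs.get(sym, 0.0) + pct / 100.0 * f
    return fracs


def composite_mu_rho(composite: Composite, energy, component: str = "total"):
    """Mixture-rule (mu/rho)(E) of a composite, cm^2/g."""
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(np.atleast_1d(e), dtype=float)
    for sym, w in elemental_fractions(composite).items():
        table = load_element_table(sym)
        out = out + w * np.atleast_1d(
            np.asarray(table(e if e.ndim else float(e), component)))
    return float(out[0]) if e.ndim == 0 else out


def linear_mu(composite: Composite, energy, component: str = "total"):
    """Linear attenuation coefficient mu(E) = rho * (mu/rho), 1/cm."""
    return composite.density * composite_mu_rho(composite, energy, component)


# --- registry: the 18 modelled shields ------------------------------------
# (full name, abbreviation, filler weight percents, density g/cm^3);
# every entry carries 22 wt% PVC in addition to the fillers listed.

_REGISTRY_ROWS = [
    ("Bi2O3-BaSO4-PVC",        "Bi-Ba",    {"BaSO4": 39, "Bi2O3": 39}, 2.886),
    ("Bi2O3-Gd2O3-PVC",        "Bi-Gd",    {"Bi2O3": 39, "Gd2O3": 39}, 3.2),
    ("Bi2O3-Gd2O3-BaSO4-PVC",  "Bi-Gd-Ba", {"BaSO4": 26, "Bi2O3": 26, "Gd2O3": 26}, 2.946),
    ("Bi2O3-Sb2O3-PVC",        "Bi-Sb",    {"Bi2O3": 39, "Sb2O3": 39}, 2.986),
    ("Bi2O3-Sb2O3-Gd2O3-PVC",  "Bi-Sb-Gd", {"Bi2O3": 26, "Sb2O3": 26, "Gd2O3": 26}, 3.015),
    ("Bi2O3-Sn-PVC",           "Bi-Sn",    {"Sn": 39, "Bi2O3": 39}, 3.193),
    ("Bi2O3-Sn-Gd2O3-PVC",     "Bi-Sn-Gd", {"Sn": 26, "Bi2O3": 26, "Gd2O3": 26}, 3.152),
    ("Bi2O3-W-BaSO4-PVC",      "Bi-W-Ba",  {"W": 26, "BaSO4": 26, "Bi2O3": 26}, 3.146),
    ("Bi2O3-W-Sb2O3-PVC",      "Bi-W-Sb",  {"W": 26, "Bi2O3": 26, "Sb2O3": 26}, 3.225),
    ("Bi2O3-W-Sn-PVC",         "Bi-W-Sn",  {"W": 26, "Sn": 26, "Bi2O3": 26}, 3.382),
    ("Pb-PVC",                 "Pb-PVC",   {"Pb": 78}, 3.46),
    ("W-BaSO4-PVC",            "W-Ba",     {"W": 39, "BaSO4": 39}, 3.059),
    ("W-Gd2O3-PVC",            "W-Gd",     {"W": 39, "Gd2O3": 39}, 3.414),
    ("W-Gd2O3-BaSO4-PVC",      "W-Gd-Ba",  {"W": 26, "BaSO4": 26, "Gd2O3": 26}, 3.064),
    ("W-Gd2O3-Sb2O3-PVC",      "W-Gd-Sb",  {"W": 26, "Sb2O3": 26, "Gd2O3": 26}, 3.139),
    ("W-Sb2O3-PVC",            "W-Sb",     {"W": 39, "Sb2O3": 39}, 3.172),
    ("W-Sn-PVC",               "W-Sn",     {"W": 39, "Sn": 39}, 3.406),
    ("W-Sn-Gd2O3-PVC",         "W-Sn-Gd",  {"W": 26, "Sn": 26, "Gd2O3": 26}, 3.288),
]


def load_registry() -> list[Composite]:
    """The 18 modelled flexible shields (78 wt% filler, 22 wt% PVC)."""
    out = []
    for name, abbr, fillers, density in _REGISTRY_ROWS:
        components = dict(fillers)
        components[PVC_FORMULA] = 100.0 - sum(fillers.values())
        out.append(Composite(name=name, abbreviation=abbr,
                             components=components, density=density))
    return out


def _normalize(label: str) -> str:
    return label.replace("–", "-").replace("—", "-").lower()


def get_composite(label: str) -> Composite:
    """Look a composite up by abbreviation or full name (dash-insensitive)."""
    want = _normalize(label)
    for comp in load_registry():
        if want in (_normalize(comp.abbreviation), _normalize(comp.name)):
            return comp
    raise KeyError(f"unknown composite {label!r}; known: "
                   + ", ".join(c.abbreviation for c in load_registry()))


def pure_element_composite(symbol: str, density: float) -> Composite:
    """A single-element slab (e.g. the pure-lead reference, rho 11.35)."""
    return Composite(name=f"pure-{symbol}", abbreviation=symbol,
                     components={symbol: 100.0}, density=density)


def registry_frame() -> pd.DataFrame:
    """Registry as a DataFrame mirroring the composition table layout."""
    fillers = ["Pb", "W", "BaSO4", "Sn", "Bi2O3", "Sb2O3", "Gd2O3",
               PVC_FORMULA]
    rows = []
    for comp in load_registry():
        row = {"name": comp.name, "abbreviation": comp.abbreviation}
        for f in fillers:
            row[f] = comp.components.get(f, 0.0)
        row["density_g_cm3"] = comp.density
        rows.append(row)
    return pd.DataFrame(rows)
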