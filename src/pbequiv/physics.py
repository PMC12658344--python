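"""Elemental photon interaction coefficients in the diagnostic energy range.

Vendored plain-text tables give, per element, the mass attenuation
coefficient (cm^2/g) split into photoelectric, incoherent (Compton) and
coherent (Rayleigh) components on a 1--150 keV grid.  Absorption edges are
represented by duplicated grid energies: the first row at an edge energy
holds the below-edge value, the second the above-edge value.  Lookups use
log-log linear interpolation, the standard convention for photon
cross-section tables; an exact edge energy resolves to the above-edge value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ElementTable",
    "AirKermaTable",
    "UnsupportedElementError",
    "EnergyRangeError",
    "load_element_table",
    "load_air_kerma_table",
    "mu_rho",
    "air_muen_rho",
    "SUPPORTED_ELEMENTS",
    "E_MIN_KEV",
    "E_MAX_KEV",
]

E_MIN_KEV = 1.0
E_MAX_KEV = 150.0

#: elements covered by the vendored tables: shield constituents, PVC, air, Al
SUPPORTED_ELEMENTS = (
    "H", "C", "N", "O", "Al", "S", "Cl", "Ar",
    "Sn", "Sb", "Ba", "Gd", "W", "Pb", "Bi",
)

_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Al": 13, "S": 16, "Cl": 17, "Ar": 18,
    "Sn": 50, "Sb": 51, "Ba": 56, "Gd": 64, "W": 74, "Pb": 82, "Bi": 83,
}

#: IUPAC 2021 standard atomic weights, g/mol
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Al": 26.982,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "Sn": 118.710, "Sb": 121.760,
    "Ba": 137.327, "Gd": 157.25, "W": 183.84, "Pb": 207.2, "Bi": 208.980,
}

_COMPONENTS = ("photoelectric", "incoherent", "coherent", "total")


class UnsupportedElementError(KeyError):
    """Requested element has no vendored coefficient table."""


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated 1--150 keV range."""


@dataclass(frozen=True)
class ElementTable:
    """Photon mass attenuation coefficients for one element.

    ``energies`` ascends except for exact duplicates at absorption edges
    (below-edge row first).  ``k_edge`` is None for elements whose K shell
    binds below 1 keV.
    """

    symbol: str
    Z: int
    atomic_mass: float
    energies: np.ndarray
    mu_photoelectric: np.ndarray
    mu_incoherent: np.ndarray
    mu_coherent: np.ndarray
    mu_total: np.ndarray
    k_edge: float | None = None

    def component(self, name: str) -> np.ndarray:
        if name not in _COMPONENTS:
            raise ValueError(f"unknown interaction component {name!r}; "
                             f"expected one of {_COMPONENTS}")
        return getattr(self, f"mu_{name}")

    def __call__(self, energy, component: str = "total"):
        return mu_rho(self, energy, component)


@dataclass(frozen=True)
class AirKermaTable:
    """Mass energy-absorption coefficient of dry air (cm^2/g)."""

    energies: np.ndarray
    muen_over_rho: np.ndarray

    def __call__(self, energy):
        return _loglog_interp(self.energies, self.muen_over_rho,
                              energy, "air mu_en/rho")


def _read_rows(name: str) -> list[list[str]]:
    ref = resources.files("pbequiv.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        return header, list(reader)


@lru_cache(maxsize=None)
def load_element_table(symbol: str) -> ElementTable:
    """Load the vendored coefficient table for one element (cached)."""
    if symbol not in SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(
            f"no vendored photon cross-section table for element {symbol!r}; "
            f"supported: {', '.join(SUPPORTED_ELEMENTS)}")
    header, rows = _read_rows(f"mu_{symbol}.csv")
    assert header == ["energy_keV", "photoelectric", "incoherent",
                      "coherent", "total"], f"bad fixture header for {symbol}"
    arr = np.array(rows, dtype=float)
    k_edge = _k_edges().get(symbol)
    # totals are kept exactly additive in the components so that the mixture
    # rule and interpolation commute; the stored column is a cross-check
    total = arr[:, 1] + arr[:, 2] + arr[:, 3]
    assert np.allclose(total, arr[:, 4], rtol=5e-3), \
        f"inconsistent total column in fixture for {symbol}"
    return ElementTable(
        symbol=symbol,
        Z=_ATOMIC_NUMBER[symbol],
        atomic_mass=ATOMIC_MASS[symbol],
        energies=arr[:, 0],
        mu_photoelectric=arr[:, 1],
        mu_incoherent=arr[:, 2],
        mu_coherent=arr[:, 3],
        mu_total=total,
        k_edge=k_edge,
    )


@lru_cache(maxsize=1)
def _k_edges() -> dict[str, float]:
    header, rows = _read_rows("elements_meta.csv")
    out = {}
    for sym, _z, _a, kedge in rows:
        if kedge:
            out[sym] = float(kedge)
    return out


@lru_cache(maxsize=1)
def load_air_kerma_table() -> AirKermaTable:
    header, rows = _read_rows("air_muen.csv")
    assert header == ["energy_keV", "muen_over_rho"]
    arr = np.array(rows, dtype=float)
    return AirKermaTable(energies=arr[:, 0], muen_over_rho=arr[:, 1])


def _loglog_interp(grid: np.ndarray, values: np.ndarray, energy, what: str):
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if np.any(e < E_MIN_KEV) or np.any(e > E_MAX_KEV):
        bad = e[(e < E_MIN_KEV) | (e > E_MAX_KEV)][0]
        raise EnergyRangeError(
            f"{what}: energy {bad:g} keV outside tabulated range "
            f"[{E_MIN_KEV:g}, {E_MAX_KEV:g}] keV (no extrapolation)")
    # side='right' makes an exact edge energy resolve to the above-edge row
    idx = np.searchsorted(grid, e, side="right")
    idx = np.clip(idx, 1, len(grid) - 1)
    exact = grid[idx - 1] == e
    lo, hi = idx - 1, idx
    with np.errstate(divide="ignore"):
        x0, x1 = np.log(grid[lo]), np.log(grid[hi])
        y0, y1 = np.log(values[lo]), np.log(values[hi])
        span = np.where(x1 > x0, x1 - x0, 1.0)
        frac = (np.log(e) - x0) / span
        out = np.exp(y0 + frac * (y1 - y0))
    out = np.where(exact, values[idx - 1], out)
    return float(out[0]) if scalar else out


def mu_rho(table: ElementTable, energy, component: str = "total"):
    """Mass attenuation coefficient (cm^2/g) at ``energy`` keV.

    Log-log linear interpolation between grid points; tabulated energies
    return the stored value exactly and an exact edge energy returns the
    above-edge value.  The total is the sum of the three interpolated
    components, so additivity holds at every energy, not just on the grid.
    Raises :class:`EnergyRangeError` outside 1--150 keV.
    """
    if component == "total":
        return sum(_loglog_interp(table.energies, table.component(c),
                                  energy, f"{table.symbol} mu/rho")
                   for c in ("photoelectric", "incoherent", "coherent"))
    return _loglog_interp(table.energies, table.component(component),
                          energy, f"{table.symbol} mu/rho")


def air_muen_rho(energy):
    """Mass energy-absorption coefficient of air (cm^2/g) at ``energy`` keV."""
    return load_air_kerma_table()(energy)
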