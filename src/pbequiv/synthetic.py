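"""Synthetic inputs with analytically known answers.

Every pipeline stage can be exercised without external data:

* monoenergetic spectra make narrow-beam attenuation exactly exponential, so
  the lead-equivalent thickness has the closed form
  t_eq = mu_Pb * t_Pb / mu_material (ratio of linear attenuation
  coefficients);
* toy materials with constant or tabulated mu/rho stand in for composites;
* noisy pseudo-simulation curves (multiplicative lognormal noise on a known
  multi-exponential) test fit and intersection recovery the way Monte Carlo
  statistics would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import E_MAX_KEV, E_MIN_KEV
from .spectra import Spectrum
from .transport import TransmissionCurve

__all__ = [
    "ToyMaterial",
    "NoisyCurveSpec",
    "make_monoenergetic",
    "make_noisy_curve",
    "analytic_t_eq",
    "random_toy_materials",
]


@dataclass(frozen=True)
class ToyMaterial:
    """A fictitious material with a prescribed mass attenuation coefficient.

    ``mu_rho`` is either a constant (cm^2/g, flat in energy) or a pair of
    arrays (energies_keV, values) interpolated log-log.  Behaves like a
    composite for all downstream transport/equivalence operations; the whole
    coefficient is booked as photoelectric so analog Monte Carlo treats the
    material as a pure absorber.
    """

    name: str
    mu_rho: float | tuple = 1.0
    density: float = 1.0
    abbreviation: str = ""

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if isinstance(self.mu_rho, (int, float)) and self.mu_rho <= 0:
            raise ValueError("mu/rho must be positive")
        if not self.abbreviation:
            object.__setattr__(self, "abbreviation", self.name)

    def mass_attenuation(self, energy, component: str = "total"):
        e = np.asarray(energy, dtype=float)
        if isinstance(self.mu_rho, (int, float)):
            vals = np.full(np.atleast_1d(e).shape, float(self.mu_rho))
        else:
            grid, mu = (np.asarray(a, float) for a in self.mu_rho)
            vals = np.exp(np.interp(np.log(np.atleast_1d(e)), np.log(grid),
                                    np.log(mu)))
        if component in ("incoherent", "coherent"):
            vals = np.zeros_like(vals)
        elif component not in ("total", "photoelectric"):
            raise ValueError(f"unknown component {component!r}")
        return float(vals[0]) if e.ndim == 0 else vals


def make_monoenergetic(energy_kev: float) -> Spectrum:
    """A spectrum with a single nonzero bin at ``energy_kev``."""
    if not E_MIN_KEV <= energy_kev <= E_MAX_KEV:
        raise ValueError(f"energy {energy_kev} keV outside "
                         f"[{E_MIN_KEV}, {E_MAX_KEV}] keV")
    return Spectrum(kvp=float(np.ceil(energy_kev)),
                    energies=np.array([energy_kev]),
                    fluence=np.array([1.0]))


@dataclass(frozen=True)
class NoisyCurveSpec:
    """A known multi-exponential transmission model plus noise level.

    ``amplitudes`` must sum to 1 (T(0) = 1); ``rates`` are per mm.  The
    default 1% relative noise emulates Monte Carlo tallies converged to
    sub-percent statistics.
    """

    amplitudes: tuple = (1.0,)
    rates: tuple = (1.0,)
    thicknesses_mm: tuple = (0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if len(self.amplitudes) != len(self.rates):
            raise ValueError("amplitudes and rates must pair up")
        if abs(sum(self.amplitudes) - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def model(self, thickness_mm):
        t = np.asarray(thickness_mm, dtype=float)
        a = np.asarray(self.amplitudes)
        b = np.asarray(self.rates)
        return np.sum(a[:, None] * np.exp(-b[:, None] * t[None, :]), axis=0)

    def true_t_eq(self, target_transmission: float) -> float:
        """Root of the noiseless model at ``target_transmission`` (bisection)."""
        from scipy.optimize import brentq
        lo, hi = 0.0, max(self.thicknesses_mm)
        return float(brentq(
            lambda x: self.model(np.array([x]))[0] - target_transmission,
            lo, hi, xtol=1e-14))


def make_noisy_curve(spec: NoisyCurveSpec) -> TransmissionCurve:
    """Seed-deterministic noisy realisation of the spec's true model.

    Noise is multiplicative lognormal (median-unbiased, keeps transmissions
    positive); the curve's stderr field is set to the prescribed sigma.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.thicknesses_mm, dtype=float)
    clean = spec.model(t)
    noisy = clean * np.exp(rng.normal(0.0, spec.sigma, size=len(t))) \
        if spec.sigma > 0 else clean
    return TransmissionCurve(material=f"synthetic({spec.amplitudes},{spec.rates})",
                             kvp=0.0, thicknesses_mm=t, transmission=noisy,
                             stderr=np.full(len(t), spec.sigma),
                             meta={"engine": "synthetic", "seed": spec.seed,
                                   "sigma": spec.sigma})


def analytic_t_eq(material_mu_per_cm: float, pb_mu_per_cm: float,
                  pb_thickness_mm: float) -> float:
    """Closed-form monoenergetic lead equivalence: mu_Pb t_Pb / mu_material."""
    if material_mu_per_cm <= 0 or pb_mu_per_cm <= 0:
        raise ValueError("linear attenuation coefficients must be positive")
    return pb_mu_per_cm * pb_thickness_mm / material_mu_per_cm


def random_toy_materials(n: int, rng=None) -> list[ToyMaterial]:
    """Seedable batch of toy materials spanning realistic mu/rho and density."""
    rng = np.random.default_rng(rng)
    out = []
    for i in range(n):
        mu = float(np.exp(rng.uniform(np.log(0.05), np.log(30.0))))
        rho = float(rng.uniform(0.5, 12.0))
        out.append(ToyMaterial(name=f"toy-{i}", mu_rho=mu, density=rho))
    return out
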