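"""Diagnostic tungsten-anode x-ray spectra.

The analytic tube model combines a Kramers bremsstrahlung continuum,
N(E) dE proportional to (E0 - E)/E, with attenuation by the anode's own
tungsten (self-filtration along the exit path set by the anode angle) and
by the added aluminium filtration, plus the four tungsten K fluorescence
lines when the tube potential exceeds the W K edge (69.5 keV).  Spectra are
relative photon-fluence histograms: every downstream consumer is invariant
to global rescaling.

Vendored reference spectra at 80/100/120 kVp are synthetic fixtures frozen
from this model at its default settings (12 deg anode, 2.5 mm Al total
filtration, 0.5 keV bins); they pin the pipeline inputs and serve as
regression anchors for the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .physics import E_MIN_KEV, load_element_table

__all__ = [
    "TubeConfig",
    "Spectrum",
    "SimilarityReport",
    "SpectrumFormatError",
    "generate_spectrum",
    "read_spectrum",
    "write_spectrum",
    "reference_spectrum",
    "spectrum_similarity",
    "W_K_EDGE_KEV",
    "W_K_LINES",
]

#: K-shell binding energy of tungsten, keV
W_K_EDGE_KEV = 69.525

#: tungsten K fluorescence lines: energy keV -> relative intensity
W_K_LINES = {59.318: 1.00, 57.982: 0.58, 67.244: 0.33, 69.067: 0.09}

_RHO_W = 19.30  # g/cm^3
_RHO_AL = 2.699


class SpectrumFormatError(ValueError):
    """Spectrum file violates the two-column CSV contract."""


@dataclass(frozen=True)
class TubeConfig:
    """X-ray tube settings for the analytic spectrum model.

    ``production_depth_um`` is the effective depth in the anode at which
    bremsstrahlung originates; the exit path through tungsten is
    depth / tan(anode_angle), which hardens the beam (target
    self-filtration).  ``k_line_yield`` scales the characteristic lines
    relative to the continuum; the default puts the K lines near 8% of
    total fluence at 120 kVp, typical of filtered tungsten spectra.
    """

    kvp: float
    anode_angle_deg: float = 12.0
    filtration_mm_al: float = 2.5
    bin_width_kev: float = 0.5
    production_depth_um: float = 0.6
    k_line_yield: float = 1.9

    def __post_init__(self):
        if not 40.0 <= self.kvp <= 150.0:
            raise ValueError(f"kvp {self.kvp} outside supported 40-150 kV")
        if self.anode_angle_deg <= 0:
            raise ValueError("anode angle must be positive")
        if self.filtration_mm_al < 0:
            raise ValueError("filtration cannot be negative")
        if self.bin_width_kev <= 0:
            raise ValueError("bin width must be positive")


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin (normalization-agnostic)."""

    kvp: float
    energies: np.ndarray  # bin centers, keV, ascending
    fluence: np.ndarray

    def __post_init__(self):
        e, f = np.asarray(self.energies, float), np.asarray(self.fluence, float)
        if e.ndim != 1 or e.shape != f.shape:
            raise SpectrumFormatError("energies and fluence must be matching "
                                      "1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise SpectrumFormatError("energies must be strictly ascending")
        if np.any(f < 0):
            raise SpectrumFormatError("fluence must be nonnegative")
        if np.any(f[e > self.kvp] > 0):
            raise SpectrumFormatError("nonzero fluence above the tube "
                                      "potential")
        if not np.any(f > 0):
            raise SpectrumFormatError("spectrum has no positive bin")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        return float(np.sum(self.energies * self.fluence)
                     / np.sum(self.fluence))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.kvp, self.energies, self.fluence * factor)


def generate_spectrum(config: TubeConfig) -> Spectrum:
    """Analytic filtered tungsten spectrum for ``config`` (deterministic)."""
    w = load_element_table("W")
    al = load_element_table("Al")
    bw = config.bin_width_kev
    centers = np.arange(E_MIN_KEV + bw / 2.0, config.kvp, bw)
    mu_w = np.asarray(w(centers, "total")) * _RHO_W
    mu_al = np.asarray(al(centers, "total")) * _RHO_AL
    self_path_cm = (config.production_depth_um * 1e-4
                    / math.tan(math.radians(config.anode_angle_deg)))
    filt = np.exp(-mu_w * self_path_cm
                  - mu_al * config.filtration_mm_al * 0.1)
    kramers = (config.kvp - centers) / centers
    fluence = kramers * filt
    # drop numerically negligible soft-tail bins (fully absorbed by the Al)
    fluence[fluence < 1e-12 * fluence.max()] = 0.0

    if config.kvp > W_K_EDGE_KEV:
        # empirical characteristic yield ~ (kvp/E_K - 1)^1.67
        strength = (config.k_line_yield * np.sum(fluence) * bw / config.kvp
                    * (config.kvp / W_K_EDGE_KEV - 1.0) ** 1.67)
        for e_line, rel in W_K_LINES.items():
            mu_w_l = float(w(e_line, "total")) * _RHO_W
            mu_al_l = float(al(e_line, "total")) * _RHO_AL
            att = math.exp(-mu_w_l * self_path_cm
                           - mu_al_l * config.filtration_mm_al * 0.1)
            idx = int(np.argmin(np.abs(centers - e_line)))
            fluence[idx] += strength * rel * att / bw
    return Spectrum(kvp=config.kvp, energies=centers, fluence=fluence)


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("energy_keV,fluence\n")
        for e, f in zip(spectrum.energies, spectrum.fluence):
            fh.write(f"{e:.12g},{f:.12g}\n")


def read_spectrum(path, kvp: float | None = None) -> Spectrum:
    """Read a two-column ``energy_keV,fluence`` CSV.

    ``kvp`` defaults to the highest energy with nonzero fluence, rounded up.
    """
    raw = np.genfromtxt(path, delimiter=",", skip_header=1)
    if raw.ndim != 2 or raw.shape[1] != 2 or raw.shape[0] < 1:
        raise SpectrumFormatError(f"{path}: expected two-column CSV")
    if np.any(np.isnan(raw)):
        raise SpectrumFormatError(f"{path}: non-numeric rows")
    e, f = raw[:, 0], raw[:, 1]
    if kvp is None:
        kvp = float(math.ceil(e[f > 0].max())) if np.any(f > 0) else float(e.max())
    return Spectrum(kvp=kvp, energies=e, fluence=f)


def reference_spectrum(kvp: int) -> Spectrum:
    """Vendored synthetic reference spectrum at 80, 100 or 120 kVp."""
    if kvp not in (80, 100, 120):
        raise ValueError(f"no vendored reference spectrum at {kvp} kVp")
    ref = resources.files("pbequiv.data").joinpath(
        f"spectrum_ref_{kvp:03d}_synthetic.csv")
    with resources.as_file(ref) as path:
        return read_spectrum(path, kvp=float(kvp))


@dataclass(frozen=True)
class SimilarityReport:
    """Shape agreement between two unit-area spectra on a common grid."""

    nrmse: float              # RMS difference / peak of the reference
    peak_offset_kev: float    # |argmax(a) - argmax(b)|
    mean_energy_diff_kev: float

    def as_dict(self) -> dict[str, float]:
        return {"nrmse": self.nrmse,
                "peak_offset_kev": self.peak_offset_kev,
                "mean_energy_diff_kev": self.mean_energy_diff_kev}


def spectrum_similarity(a: Spectrum, b: Spectrum,
                        grid_kev: float = 0.5) -> SimilarityReport:
    """Compare two spectra after rebinning to a common unit-area grid."""
    lo = max(a.energies.min(), b.energies.min())
    hi = min(a.energies.max(), b.energies.max())
    if hi <= lo:
        raise ValueError("spectra have non-overlapping energy supports")
    grid = np.arange(lo, hi + grid_kev / 2, grid_kev)

    def density(s: Spectrum) -> np.ndarray:
        d = np.interp(grid, s.energies, s.fluence)
        area = np.trapezoid(d, grid)
        return d / area

    pa, pb = density(a), density(b)
    nrmse = float(np.sqrt(np.mean((pa - pb) ** 2)) / pa.max())
    peak = float(abs(grid[np.argmax(pa)] - grid[np.argmax(pb)]))

    def mean_e(d):
        return float(np.trapezoid(grid * d, grid))

    return SimilarityReport(nrmse=nrmse, peak_offset_kev=peak,
                            mean_energy_diff_kev=abs(mean_e(pa) - mean_e(pb)))
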