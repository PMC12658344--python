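# Methods

## Physical model

**Elemental cross sections.** The vendored tables (`src/pbequiv/data/mu_*.csv`)
give photoelectric, incoherent and coherent mass attenuation coefficients
per element on a 1 keV grid over 1–150 keV, with duplicated rows at
absorption edges (below-edge value first; an exact edge energy resolves to
the above-edge value). They are generated once by
`scripts/generate_tables.py`:

- *photoelectric* from the Cromer–Liberman anomalous-scattering calculation
  (via `gemmi`), σ_pe = 2 r_e λ f″(E);
- *incoherent* from the Klein–Nishina differential cross section modulated
  by an incoherent scattering function S(q,Z) = Z·(1 − (F/Z)²);
- *coherent* from the Thomson differential cross section times the squared
  Thomas–Fermi–Molière form factor F(q,Z) (three-Yukawa screening fit).

Totals agree with widely quoted attenuation values (Pb 100 keV 5.549,
water 50 keV 0.2269, Al 50 keV 0.3681 cm²/g, air μ_en/ρ anchors) to within
about 2%; K-edge jump ratios are physical (6.3 for Sn down to 4.7 for Bi).
K and L edges are refined by bisection against the f″ discontinuity. The
source data is not cleanly resolved around the M edges of the heavy
elements (≈1.8–4 keV); residual upturns there are detected and marked as
duplicated edge rows so that interpolation and monotonicity contracts hold,
but coefficients in that region should be considered approximate. This is
irrelevant to the results: after 2.5 mm Al filtration the spectra carry
essentially no fluence below 10 keV. Interpolation is log-log linear, the
standard convention for photon cross-section tables; the *total* is defined
as the sum of the three interpolated components, so additivity holds at
every energy. The hydrogen photoelectric column is floored at 1e-12 cm²/g
where the source underflows to zero (~1e-7 of the H total there).

The air mass energy-absorption coefficient uses the kerma approximation:
photoabsorption transfers the full photon energy (fluorescence escape
neglected — sub-percent for N/O/Ar), incoherent scattering transfers the
Klein–Nishina recoil energy, coherent scattering transfers nothing.
Adequate below 150 keV where radiative losses are negligible.

**Materials.** Each registry composite is 78 wt% filler + 22 wt% PVC with
the bulk density taken as given (measured-or-calculated status of the
source densities is unknown; they are treated as constants, never
recomputed from constituents). PVC is modelled as the pure C₂H₃Cl repeat
unit — no plasticizers or stabilizers, since no formulation is specified.
Mass attenuation follows the elemental mixture rule; this ignores
particle-size, dispersion and porosity effects, which is the standard
idealization for homogeneous composite modelling. The pure-lead reference
uses ρ = 11.35 g/cm³.

**Spectra.** The analytic tube model is a Kramers continuum
N(E) ∝ (E₀ − E)/E attenuated by tungsten self-filtration along the anode
exit path (production depth 0.6 µm, path = depth/tan(anode angle)) and by
the added aluminium, plus the four W K lines (Kα₁ 59.3, Kα₂ 58.0,
Kβ₁ 67.2, Kβ₂ 69.1 keV, relative intensities 1.00/0.58/0.33/0.09) when the
tube potential exceeds the K edge at 69.5 keV; the K-line yield scales as
(E₀/E_K − 1)^1.67 and is normalized to put the lines near 8% of total
fluence at 120 kVp, typical of filtered tungsten spectra. Defaults — 12°
anode angle, 2.5 mm Al total filtration, 0.5 keV bins — are typical IEC
diagnostic tube values; the tube parameters behind the published reference
results are not stated, and no attempt is made to infer them. All consumers
are invariant to global fluence rescaling.

The vendored 80/100/120 kVp reference spectra are **synthetic** fixtures
frozen from this generator at its defaults (`*_synthetic.csv`). An external
cross-model reference (e.g. a SpekPy export) was not available in the build
environment, so the spectrum-similarity check (normalized RMSE, peak
offset, mean-energy difference) acts as a regression anchor for the
generator rather than an independent validation; `validate-spectrum`
remains the tool for comparing user-supplied spectra against the pipeline
inputs.

**Transport.** The default engine is deterministic narrow-beam,
fluence-weighted: lead equivalence is a ratio quantity that is insensitive
to scatter build-up to first order, and the deterministic engine makes the
whole 108-cell summary run in well under a second, bit-reproducibly.
Air-kerma weighting q(E) = E·(μ_en/ρ)_air(E) is available for
energy-deposition-style comparisons.

The analog Monte Carlo engine bounds the geometry sensitivity: point
source, cone illuminating a laterally infinite slab at 100 cm (default
half-width 10 cm sets the cone), detector disc of radius 5 cm a fixed
10 cm behind the slab's back face. Photons sample free paths from the total
linear coefficient; photoelectric events absorb, incoherent events sample
the Klein–Nishina law (Butcher–Messel composition-rejection), coherent
events sample the Thomson angular law — a form-factor-free approximation
that exaggerates large-angle elastic scattering but leaves the tally ratio
nearly unchanged. No electron transport or fluorescence escape: deposited
energy is approximated by kerma, adequate below 150 keV. Transmission is
the ratio of shielded to unshielded detector tallies generated from the
same seed-derived initial states, so T(0) = 1 by construction and results
are bit-reproducible for a fixed seed. Relative standard errors combine
the binomial errors of both passes in quadrature (slightly conservative,
since the passes are correlated). The default 10⁶ histories/point gives
roughly 1% relative error at T ≈ 0.04 and ~1.7 s/point on one CPU; history
counts are a CLI knob. Deterministic and Monte Carlo lead equivalence for
the composites agree within ~1%.

**Curve fitting and intersection.** The default fit is a monotone
piecewise-cubic (PCHIP) interpolant of log-transmission with the exact
anchor T(0) = 1 — a polyenergetic curve is not a single exponential
(beam hardening makes log T convex in thickness), so an interpolant is the
faithful continuous curve through deterministic points. Single- and
bi-exponential least-squares fits in log space are provided as options
with residual reporting, reproducing the exponential-decay-fitting
convention used for simulated attenuation curves; on noisy synthetic
curves the matching exponential model averages the noise and recovers
intersections within 2%, while the interpolant follows each noisy knot and
is held to the per-point noise level. Monte Carlo curves must be monotone
within 3× their standard errors and the fitted curve must pass within 3σ
of every point. Roots are solved by Brent bracketing on the fitted range
(relative tolerance 1e-12); targets outside the range raise instead of
extrapolating — the 3 mm grid maximum comfortably exceeds every computed
equivalent thickness (max ≈ 2.8 mm). Intersecting the fitted curve versus
linear interpolation of log-points differs by well under 1% on the default
grid (the grid-refinement test bounds this).

## Synthetic-data generators

`make_monoenergetic` yields single-bin spectra for which narrow-beam
attenuation is exactly exponential and the lead equivalence has the closed
form t_eq = μ_Pb t_Pb / μ_material — the end-to-end oracle used across the
registry and for random toy materials. `ToyMaterial` carries a constant or
tabulated μ/ρ, booked entirely as photoelectric so the Monte Carlo engine
treats it as a pure absorber. `make_noisy_curve` applies multiplicative
lognormal noise (median-unbiased, keeps transmissions positive) to a known
multi-exponential; the default σ = 0.01 mirrors sub-percent Monte Carlo
tally statistics. All generators are seed-deterministic. What these do
*not* emulate: correlated tally noise, detector energy response, and real
tube-spectrum uncertainty — so passing the synthetic suites demonstrates
algorithmic correctness, not agreement with any particular measured
apron.

## Problem sizes and numerical choices

The full summary is 18 materials × 3 spectra × 2 targets = 108 cells,
deterministic, < 1 s. Monte Carlo cross-checks use 10⁶ histories/point
(the package's desk-scale default; production simulation codes use orders
of magnitude more) on one material across the three spectra. Energy range
is fixed at 1–150 keV (covers 120 kVp with margin); no extrapolation is
permitted in energy or thickness. Ranking ties break alphabetically.
Degenerate inputs (zero thickness, zero-width cones, empty non-lead subsets
for the scatter trend) are handled explicitly.

## Known limitations

- Cross-section accuracy is ~2% against standard tabulations (better where
  it matters, worse near edges and below 5 keV); lead-equivalence ratios
  benefit from partial cancellation of systematic errors.
- The tube model is a filtered-Kramers approximation; mean energies run a
  few keV soft of full physics-based spectrum codes, which biases
  equivalent thicknesses of K-edge-rich composites slightly low relative
  to results computed with harder spectra.
- Narrow-beam default ignores build-up; the Monte Carlo engine shows the
  effect on t_eq is ~1% for this geometry.
- No uncertainty propagation from Monte Carlo standard errors into t_eq
  confidence intervals; no formal IEC 61331-1 conformance logic.
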