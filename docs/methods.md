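# Methods

## Stopping power and ranges

Electronic stopping follows the Bethe–Bloch formula per ion and medium,

S/ρ = K (Z/A)ₘ z*²/β² [ ½ ln(2 mₑc² β²γ² W_max / I²) − β² − δ/2 ],

with K = 0.307075 MeV·cm²/mol, the exact kinematic maximum energy
transfer W_max (including the 2γmₑ/M term, so helium/proton LET ratios
deviate slightly from pure z² = 4), the Sternheimer density-effect
correction δ built generically from the plasma energy
ħωₚ = 28.816 √(ρ·Z/A) eV, and a Barkas-type effective charge
z* = Z(1 − exp(−125 β Z^{−2/3})) for partially stripped slow ions.
Mean excitation energies: water 75 eV, polyethylene 57.4 eV, aluminum
166 eV, bone surrogate 91.9 eV. Protons use the physical proton mass;
heavier ions use A·931.494 MeV.

Neglected: shell corrections, Bloch/Mott higher-order terms, nuclear
stopping, straggling. Consequences: a few-percent softness below
~10 MeV/n, and a systematic −1.5 to −2.5% on the highest-Z LETs
(⁴⁸Ti, ⁵⁶Fe), still inside the 3% accuracy contract of the engine
against the published 33-row beam table. LET here is the unrestricted
electronic stopping power (L∞).

CSDA ranges integrate A/(S·ρ) dE on a 1600-point logarithmic grid from a
0.1 MeV/n cutoff (cached per ion–medium pair); the sub-cutoff remainder
uses a local S ∝ E^−0.8 power law and contributes ≪ 0.01 cm. Range–energy
inversion interpolates the cached table in log–log; the degrader solver
(energy_after_thickness) is the forward inverse of that table, so
composition of thicknesses is consistent to ≲ 0.1 MeV/n.

## Reference field

The shielded-tissue field is carried as four spectra (H, He, neutrons on
the energy axis; Z ≥ 3 on the LET axis) plus the two annual component
doses an accelerator cannot deliver (π/EM cascades 15.5 mGy/yr, neutron
heavy target fragments 1.1 mGy/yr). Absorbed dose uses
D[Gy] = 1.602·10⁻⁹ Φ[cm⁻²] L[keV/μm]/ρ; hydrogen-group dose is evaluated
with proton stopping power (the group folds in deuterons and tritons;
neutron-induced Z ≤ 2 recoils are already inside the H/He spectra, which
is why the neutron spectrum contributes no beam and no track count). All
integrals are trapezoids in ln(abscissa) — the spectra span decades — and
self-converge to <0.5% against a 10× refined grid. Dose equivalent weights
dD/dL by the ICRP-60 quality factor: Q = 1 below 10 keV/μm,
0.32L − 2.2 on [10, 100], 300/√L above. (The standard's two upper pieces
meet with a 0.2-unit step at L = 100: 29.8 vs 30.0; the implementation
reproduces the published coefficients rather than forcing continuity.)
Solar maximum divides all fluxes by the single factor 1.85.

### Synthetic generator

`synth_field` stands in for the shielded-spectrum data product. Shapes:
lognormal flux densities in energy for H and He (the broad shielded peak;
log-width 0.9, support 1–2500 MeV/n) and a single power law in LET for
the HZE group (support 2–1000 keV/μm, hence monotone decreasing above
200). Calibration is exact by construction: component fluxes are scaled
so annual doses integrate to the reference values (86 / 22.5 / 8.9
mGy/yr), and the one remaining shape parameter per group (lognormal
median; power-law index) is solved with Brent's method so the
fluence-weighted mean LET matches the dose-to-fluence ratio implied by
the reference track counts per 100 μm² cell nucleus (126 H, 7 He, 0.5
HZE per year). The seed drives a small (2%) smooth flux perturbation,
renormalized afterwards, so seeds give distinct but physically equivalent
fields. What the generator does **not** emulate: the spectral fine
structure of the real field (ion-specific LET singularities, neutron
elastic edges), correlations between components, and anything above
2500 MeV/n — so tests passing on it validate the pipeline's integrals
and binning, not the fidelity of any specific transport-code spectrum.

## Beam selection

Proton and helium representatives are the ten degraded energies
(20–79.9 MeV/n, kept as printed facility constants; a pure log-spaced
generator with step (100/20)^{1/10} ≈ 1.175 is provided as the documented
approximation) plus 100, 150, 250, 1000 MeV/n direct. Bin edges:
geometric means of adjacent representatives, 0 lower edge (sub-20 MeV/n
fluence cannot penetrate the 2-mm cage wall and is credited to the
20 MeV/n beam), 50 GeV/n upper edge. HZE beams (¹²C 1000, ¹⁶O 350,
²⁸Si 600, ⁴⁸Ti 1000, ⁵⁶Fe 600 MeV/n) get five LET bins on [2, 200]
keV/μm with geometric-mean interior edges computed from this package's
own LETs — the carbon/oxygen edge lands at 12.8 keV/μm. Bins are
half-open [lower, upper), which makes binned fluence conserve the total
integral identically. Per-beam dose = bin fluence × LET(representative) ×
fluence-to-dose constant; a single factor then rescales the 33 doses to
the target (the π/EM and neutron components are dropped first), so
normalization is exact for any field and the dose *fractions* depend only
on spectral shape. The commissioned 33-row table and the simplified
5-ion table are also available as data (`canonical_table`,
`simplified_field`), linearly rescalable to any target dose.

## Delivery planning

The binary filter is the doubling set {0.1, 0.2, …, 12.8} cm of
ρ = 0.93 g/cm³ polyethylene: greedy decomposition reaches every 0.1 cm
lattice point up to 25.5 cm, so any target is met within half the
resolution. The commissioned delivery order is stored as data and
validated against its design rules (light ions open the sequence, no two
heavy-ion beams adjacent, degraded beams grouped in pairs); non-canonical
tables get a rule-respecting heuristic order flagged in provenance. A
"switch" is one accelerator ion–energy setting, counting the first
beam's setup — the only convention that yields 21 for the printed
sequence — with degraded beams keyed to their 100 MeV/n parent.
Fractionation divides every beam dose into n equal daily fractions on
the first d days of each week (default 6; the seventh day is the
facility contingency day), flags fractions below the 0.1 mGy deliverable
minimum, and supports the alternating two-group HZE scheme (heavy ions
on alternate exposure days at doubled fraction, totals preserved
exactly).

## Phantom dosimetry

The phantom is synthetic: an atlas-extent capsule body (half-width
1.2 cm, dorsoventral half-height 1.0 cm, 28.9 g at soft-tissue density)
with a skin shell, a dorsal spine plus skull shell in a bone surrogate
(ρ = 1.5), low-density lungs (ρ = 0.3) and ten ellipsoidal organs placed
from rodent anatomy; the seed jitters organ centers by ≤0.5 mm. The rat
is the mouse scaled by 3.15 in linear dimension. (Published mass for the
scaled rat is 754 g; pure 3.15³ scaling of 28 g gives ≈875 g — the two
are inconsistent, and the linear factor is primary here, giving ~900 g
for this phantom.) Default working resolution 0.5 mm (mouse).

Transport is straight-line CSDA ray-casting along the axis-aligned
directions of the geometry (pseudoisotropic 6 or lateral 2, equal
fluence split), each ray first crossing the 2-mm polyethylene cage wall.
Per-beam fluence is set so a water-equivalent entrance region receives
the beam's nominal dose at the *nominal* beam energy — the free-field
calibration at the target plane, as a reference chamber would see it —
and each voxel then receives Φ·ΔE/(ρ·Δx) with ΔE the exact CSDA energy
loss across the voxel from the cached range tables (this captures the
Bragg terminus in the stopping voxel and makes the scored map agree with
an independent per-column energy audit to <10⁻⁶). Media enter through
density and a mass-stopping ratio to water taken at 100 MeV/n (the ratio
is nearly energy-independent above ~10 MeV/n).

**Known, quantified limitation.** Without nuclear interactions the
interior of the mouse cannot fully recover the ~14% of the table dose
carried by the 20–32 MeV/n degraded beams, which stop in the outer few
millimetres: the 6-direction 500 mGy run gives an organ average of
≈466 mGy (soft organs 457–489, skin 489, skeleton 435) versus the ≈501
reported by full Monte Carlo transport — secondary/nuclear buildup,
deliberately out of scope here, supplies the difference. The qualitative
signatures are reproduced: skeleton ~7% below soft tissue (lower mass
stopping power of bone), 99.8% of voxels within 15% of the mean for the
mouse, a flank-to-midline gradient for the 2-direction rat and none for
the 6-direction mouse, and exact linearity in table dose. Organ means
from this module are therefore homogeneity diagnostics, not absolute
dosimetry.

## Numerical choices

Range tables: 1600-point log grid, trapezoid cumulative integration,
log–log interpolation (range is a near power law in energy). Spectrum
integrals: trapezoids in ln x with edge clipping; bin integrals share the
interpolant with the total, making fluence conservation exact. Generator
root-finding: Brent on [20, 2000] MeV/n (median) and [1.2, 4.0]
(power-law index), tolerances 10⁻³ MeV/n and 10⁻⁶. Beam-dose
normalization uses math.fsum; schedules store per-day doses as floats
(conservation <10⁻¹² relative) and round only for display. Degenerate
inputs: zero-dose beams are carried (with a warning at design time for
empty bins), beams stopping in the cage wall contribute zero dose with a
warning, and all CSV readers use exact (round-trip) float parsing so
write→read is bit-identical.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on synthetic or
built-in inputs: the 160-point synthetic field, the 33-beam tables, the
0.5 mm mouse (~10⁶ voxels, ≈4 s for the full 33-beam, 6-direction run)
and 1 mm unit-test phantoms. The complete suite runs in well under a
minute on one CPU.
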