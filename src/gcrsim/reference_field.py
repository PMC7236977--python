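"""The shielded-tissue GCR reference field: containers, synthesis, integrals.

The reference radiation field is the one seen by the blood-forming organs
(BFO) of a female phantom behind 20 g/cm^2 of aluminum at solar minimum.
It is carried as four spectra — differential flux versus kinetic energy for
the hydrogen, helium and neutron groups, and differential flux versus LET
for the heavy-ion (Z >= 3, "HZE") group — plus the annual component doses
of the two parts of the field (pi/EM cascades and heavy neutron target
fragments) that an accelerator simulator does not reproduce.

A synthetic generator emulates the qualitative shape of the shielded
spectra (broad peaked energy spectra for H/He, a steeply falling LET
spectrum for HZE) and calibrates itself so that both the annual component
doses and the mean track counts per cell nucleus match the published
integral characterization of the reference field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from gcrsim import ion_physics
from gcrsim.ion_physics import WATER, ion, mass_stopping_power

# Fluence-to-dose constant: D[Gy] = FLUENCE_TO_GY * Phi[cm^-2] * LET[keV/um] / rho[g/cm^3]
FLUENCE_TO_GY = 1.602e-9
SOLAR_MAX_SCALE = 1.85  # divide solar-minimum flux by this for solar maximum

# Annual integral characterization of the reference field (solar minimum):
# component doses in mGy/yr and mean traversals per 100 um^2 cell nucleus.
REFERENCE_COMPONENT_DOSES = {
    "pi_em": 15.5,
    "neutron": 1.1,  # heavy target fragments from neutron interactions
    "hydrogen": 86.0,
    "helium": 22.5,
    "hze": 8.9,
}
REFERENCE_TRACKS_PER_CELL = {"hydrogen": 126.0, "helium": 7.0, "hze": 0.5}
DEFAULT_NUCLEUS_CROSS_SECTION = 100.0  # um^2


@dataclass(frozen=True)
class Spectrum:
    """A differential spectrum on an energy (MeV/n) or LET (keV/um) abscissa.

    ``flux`` is particles / (cm^2 yr unit-abscissa).
    """

    abscissa_kind: str  # "energy" | "let"
    grid: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        flux = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "flux", flux)
        if self.abscissa_kind not in ("energy", "let"):
            raise ValueError(f"abscissa_kind must be 'energy' or 'let', got {self.abscissa_kind!r}")
        if grid.size < 4:
            raise ValueError("spectrum needs at least 4 grid points")
        if grid.size != flux.size:
            raise ValueError("grid and flux lengths differ")
        if np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
            raise ValueError("grid must be strictly increasing and positive")
        if np.any(flux < 0) or not np.all(np.isfinite(flux)):
            raise ValueError("flux must be finite and non-negative")

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.abscissa_kind, self.grid, self.flux * factor)


def integral_fluence(spec: Spectrum, lower: float | None = None, upper: float | None = None) -> float:
    """Integral fluence (cm^-2 yr^-1) of ``spec`` over [lower, upper).

    Trapezoid rule on the log-transformed abscissa (the spectra span
    decades); the interval is clipped to the tabulated grid.
    """
    return _integral(spec, np.ones_like(spec.grid), lower, upper)


def _integral(spec: Spectrum, weight: np.ndarray, lower=None, upper=None) -> float:
    """integral flux(x) * weight(x) dx via trapezoids in ln(x)."""
    x, f = spec.grid, spec.flux * np.asarray(weight)
    lo = x[0] if lower is None else max(lower, x[0])
    hi = x[-1] if upper is None else min(upper, x[-1])
    if lo >= hi:
        return 0.0
    # restrict to the clipped interval, linear interpolation of x*f in ln x
    lx = np.log(x)
    g = x * f  # integrand against d(ln x)
    pts = np.unique(np.concatenate([lx[(lx > math.log(lo)) & (lx < math.log(hi))],
                                    [math.log(lo), math.log(hi)]]))
    gi = np.interp(pts, lx, g)
    return float(np.trapezoid(gi, pts))


@dataclass(frozen=True)
class QualityFactorModel:
    """ICRP-60 quality factor Q(L), L in keV/um.

    Q = 1 for L < 10; 0.32 L - 2.2 for 10 <= L <= 100; 300 / sqrt(L) above.
    """

    slope: float = 0.32
    intercept: float = -2.2
    high_coeff: float = 300.0

    def q(self, let) -> np.ndarray:
        L = np.asarray(let, dtype=float)
        out = np.ones_like(L)
        mid = (L >= 10.0) & (L <= 100.0)
        out = np.where(mid, self.slope * L + self.intercept, out)
        out = np.where(L > 100.0, self.high_coeff / np.sqrt(L), out)
        return out

    def __call__(self, let):
        res = self.q(let)
        return float(res) if np.ndim(let) == 0 else res


ICRP60 = QualityFactorModel()


@dataclass(frozen=True)
class ReferenceField:
    hydrogen: Spectrum
    helium: Spectrum
    neutron: Spectrum
    hze_let: Spectrum
    component_doses: dict = field(default_factory=dict)  # stored mGy/yr (pi/EM, neutron)
    solar_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.hydrogen.abscissa_kind != "energy" or self.helium.abscissa_kind != "energy":
            raise ValueError("hydrogen and helium spectra must be on the energy axis")
        if self.hze_let.abscissa_kind != "let":
            raise ValueError("hze spectrum must be on the LET axis")
        if any(v < 0 for v in self.component_doses.values()):
            raise ValueError("component doses must be non-negative")

    def to_solar_maximum(self) -> "ReferenceField":
        """Scale the solar-minimum field to solar maximum (flux / 1.85)."""
        return self.scaled(1.0 / SOLAR_MAX_SCALE)

    def scaled(self, factor: float) -> "ReferenceField":
        return ReferenceField(
            self.hydrogen.scaled(factor), self.helium.scaled(factor),
            self.neutron.scaled(factor), self.hze_let.scaled(factor),
            {k: v * factor for k, v in self.component_doses.items()},
            solar_scale=self.solar_scale * factor,
        )


@dataclass(frozen=True)
class CellTraversalEstimate:
    sigma: float  # cell-nucleus cross section, um^2
    tracks_per_year: dict  # ion group -> mean traversals per nucleus per year


# --- Dose integrals -------------------------------------------------------

def _group_let(group: str, energies: np.ndarray) -> np.ndarray:
    """LET in water of the representative ion for an energy-axis group.

    The hydrogen group (protons + deuterons + tritons folded together) is
    evaluated with proton stopping power; helium with alphas.
    """
    rep = ion("1H") if group == "hydrogen" else ion("4He")
    s = mass_stopping_power(rep, energies, WATER)
    return s * WATER.density * ion_physics.MEV_PER_G_TO_KEV_PER_UM


def integrate_dose(field_: ReferenceField) -> dict:
    """Annual absorbed dose per component, mGy/yr.

    The H and He energy spectra are converted pointwise with the LET of
    the group-representative ion; the HZE spectrum is integrated directly
    on its LET abscissa. The pi/EM and neutron-fragment components are not
    represented spectrally and are passed through from the stored values.
    """
    doses = {}
    for name in ("hydrogen", "helium"):
        spec: Spectrum = getattr(field_, name)
        let = _group_let(name, spec.grid)
        doses[name] = 1e3 * FLUENCE_TO_GY * _integral(spec, let) / WATER.density
    doses["hze"] = 1e3 * FLUENCE_TO_GY * _integral(field_.hze_let, field_.hze_let.grid) / WATER.density
    for name in ("pi_em", "neutron"):
        doses[name] = field_.component_doses.get(name, 0.0)
    doses["total"] = sum(doses.values())
    return doses


def tracks_per_cell(field_: ReferenceField, sigma: float = DEFAULT_NUCLEUS_CROSS_SECTION) -> CellTraversalEstimate:
    """Mean annual traversals of a cell nucleus of area ``sigma`` um^2.

    Per charged-particle group: total integral fluence times the nucleus
    cross section. The neutron group carries no track count (its charged
    recoils are already folded into the H/He spectra).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sigma_cm2 = sigma * 1e-8  # um^2 -> cm^2
    tracks = {
        "hydrogen": integral_fluence(field_.hydrogen) * sigma_cm2,
        "helium": integral_fluence(field_.helium) * sigma_cm2,
        "hze": integral_fluence(field_.hze_let) * sigma_cm2,
    }
    return CellTraversalEstimate(sigma=sigma, tracks_per_year=tracks)


def dose_equivalent(field_: ReferenceField, q: QualityFactorModel = ICRP60) -> dict:
    """Annual dose equivalent per component, mSv/yr: integral Q(L) dD/dL.

    Only the spectrally represented charged components are weighted; the
    pi/EM and neutron-fragment stored doses are excluded (no LET
    distribution is carried for them).
    """
    out = {}
    for name in ("hydrogen", "helium"):
        spec: Spectrum = getattr(field_, name)
        let = _group_let(name, spec.grid)
        out[name] = 1e3 * FLUENCE_TO_GY * _integral(spec, let * q.q(let)) / WATER.density
    L = field_.hze_let.grid
    out["hze"] = 1e3 * FLUENCE_TO_GY * _integral(field_.hze_let, L * q.q(L)) / WATER.density
    out["total"] = sum(out.values())
    return out


def normalized_dose_distribution(component_doses: dict | None = None, target_dose: float = 500.0) -> dict:
    """Renormalize annual component doses to a delivered target dose.

    The pi/EM and neutron heavy-fragment components are excluded (an
    accelerator simulator does not deliver them); the remaining charged
    components are rescaled so that they sum to ``target_dose`` mGy.
    """
    doses = dict(component_doses or REFERENCE_COMPONENT_DOSES)
    groups = {k: v for k, v in doses.items()
              if k not in ("pi_em", "neutron", "total")}
    total = sum(groups.values())
    if total <= 0:
        raise ValueError("charged-component doses sum to zero")
    out = {k: v / total * target_dose for k, v in groups.items()}
    out.update({"pi_em": 0.0, "neutron": 0.0})
    return out


# --- Synthetic field generator -------------------------------------------

@dataclass(frozen=True)
class SynthFieldParams:
    """Calibration targets and shape parameters of the synthetic field.

    Defaults are the integral characterization of the reference field:
    annual component doses (mGy/yr) and mean track counts per 100 um^2
    nucleus. The spectral shapes are a lognormal flux density in energy
    for H/He (the broad shielded-spectrum peak) and a single power law in
    LET for the HZE group; the lognormal median and the power-law index
    are solved so that the fluence implied by the dose normalization
    reproduces the track-count targets.
    """

    doses: tuple = tuple(REFERENCE_COMPONENT_DOSES.items())
    tracks: tuple = tuple(REFERENCE_TRACKS_PER_CELL.items())
    sigma: float = DEFAULT_NUCLEUS_CROSS_SECTION  # um^2
    log_width: float = 0.9  # lognormal sigma of the H/He energy spectra
    energy_range: tuple = (1.0, 2500.0)  # MeV/n
    let_range: tuple = (2.0, 1000.0)  # keV/um, HZE spectrum support
    n_points: int = 160
    noise: float = 0.02  # relative flux jitter applied before renormalization


def _lognormal_shape(grid: np.ndarray, median: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((np.log(grid) - math.log(median)) / sigma) ** 2) / grid


def _solve_group_median(group: str, params: SynthFieldParams, mean_let_target: float) -> float:
    """Median energy whose fluence-weighted mean LET equals the target."""
    grid = np.geomspace(*params.energy_range, params.n_points)

    def mean_let(median: float) -> float:
        spec = Spectrum("energy", grid, _lognormal_shape(grid, median, params.log_width))
        return _integral(spec, _group_let(group, grid)) / integral_fluence(spec)

    return brentq(lambda m: mean_let(m) - mean_let_target, 20.0, 2000.0, xtol=1e-3)


def _solve_hze_index(params: SynthFieldParams, mean_let_target: float) -> float:
    grid = np.geomspace(*params.let_range, params.n_points)

    def mean_let(p: float) -> float:
        spec = Spectrum("let", grid, grid ** (-p))
        return _integral(spec, grid) / integral_fluence(spec)

    return brentq(lambda p: mean_let(p) - mean_let_target, 1.2, 4.0, xtol=1e-6)


def synth_field(params: SynthFieldParams | None = None, seed: int = 0) -> ReferenceField:
    """Deterministic synthetic stand-in for the shielded reference field.

    The generator self-normalizes: each charged component's integrated
    annual dose matches its requested value (exactly, up to the shared
    integration rule), and the spectral shape parameters are solved so
    that the implied track counts per cell nucleus match their targets.
    ``seed`` drives a small smooth flux jitter, re-normalized afterwards,
    so distinct seeds give distinct but equivalent fields.
    """
    params = params or SynthFieldParams()
    doses = dict(params.doses)
    tracks = dict(params.tracks)
    if any(doses[k] <= 0 for k in ("hydrogen", "helium", "hze")):
        raise ValueError("requested charged-component doses must be positive")
    rng = np.random.default_rng(seed)
    sigma_cm2 = params.sigma * 1e-8

    def jitter(n: int) -> np.ndarray:
        if params.noise == 0:
            return np.ones(n)
        # smooth low-order perturbation so spectra stay physically smooth
        x = np.linspace(0, 1, n)
        coeff = rng.normal(0.0, params.noise, 4)
        return np.exp(sum(c * np.sin((k + 1) * math.pi * x) for k, c in enumerate(coeff)))

    specs = {}
    for group in ("hydrogen", "helium"):
        # target fluence-weighted mean LET = D / (k * Phi)
        phi = tracks[group] / sigma_cm2
        mean_let_target = (doses[group] * 1e-3 / FLUENCE_TO_GY) / phi
        median = _solve_group_median(group, params, mean_let_target)
        grid = np.geomspace(*params.energy_range, params.n_points)
        flux = _lognormal_shape(grid, median, params.log_width) * jitter(params.n_points)
        spec = Spectrum("energy", grid, flux)
        let = _group_let(group, grid)
        scale = doses[group] / (1e3 * FLUENCE_TO_GY * _integral(spec, let))
        specs[group] = spec.scaled(scale)

    phi_hze = tracks["hze"] / sigma_cm2
    mean_let_target = (doses["hze"] * 1e-3 / FLUENCE_TO_GY) / phi_hze
    p = _solve_hze_index(params, mean_let_target)
    lgrid = np.geomspace(*params.let_range, params.n_points)
    lflux = lgrid ** (-p) * jitter(params.n_points)
    hze = Spectrum("let", lgrid, lflux)
    hze = hze.scaled(doses["hze"] / (1e3 * FLUENCE_TO_GY * _integral(hze, lgrid)))

    # neutron spectrum: evaporation-like bump around 1 MeV, carried for
    # completeness only (no beam, no track count; its charged recoils are
    # already inside the H/He spectra)
    ngrid = np.geomspace(0.1, 1000.0, 80)
    nflux = _lognormal_shape(ngrid, 1.0, 1.2) * 1e7

    return ReferenceField(
        hydrogen=specs["hydrogen"], helium=specs["helium"],
        neutron=Spectrum("energy", ngrid, nflux), hze_let=hze,
        component_doses={"pi_em": doses.get("pi_em", 0.0),
                         "neutron": doses.get("neutron", 0.0)},
    )


# --- Serialization --------------------------------------------------------

_COMPONENT_KIND = {"hydrogen": "energy", "helium": "energy",
                   "neutron": "energy", "hze": "let"}
_UNITS = {"energy": "MeV/n", "let": "keV/um"}


def write_field(field_: ReferenceField, path: str | Path) -> None:
    """Write the field as a single CSV: component, abscissa, unit, flux.

    Stored component doses are carried on pseudo-rows with component
    ``dose:<name>``.
    """
    rows = []
    for name, attr in (("hydrogen", "hydrogen"), ("helium", "helium"),
                       ("neutron", "neutron"), ("hze", "hze_let")):
        spec: Spectrum = getattr(field_, attr)
        unit = _UNITS[spec.abscissa_kind]
        for x, f in zip(spec.grid, spec.flux):
            rows.append((name, repr(float(x)), unit, repr(float(f))))
    for name, v in field_.component_doses.items():
        rows.append((f"dose:{name}", repr(float(v)), "mGy/yr", "0"))
    df = pd.DataFrame(rows, columns=["component", "abscissa", "unit", "flux"])
    df.to_csv(path, index=False)


def load_field(path: str | Path, format: str | None = None) -> ReferenceField:
    """Load a reference field from CSV (native layout) or XLSX.

    CSV columns: ``component, abscissa, unit, flux`` with components
    hydrogen / helium / neutron / hze and optional ``dose:<name>`` rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        return _load_xlsx(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"component", "abscissa", "unit", "flux"} - set(df.columns)
    if missing:
        raise ValueError(
            f"missing columns {sorted(missing)}; expected header "
            "component,abscissa,unit,flux"
        )
    specs, doses = {}, {}
    for name, sub in df.groupby("component", sort=False):
        if str(name).startswith("dose:"):
            doses[str(name)[5:]] = float(sub["abscissa"].iloc[0])
            continue
        if name not in _COMPONENT_KIND:
            raise ValueError(f"unknown component {name!r}")
        kind = _COMPONENT_KIND[name]
        grid = sub["abscissa"].astype(float).to_numpy()
        flux = sub["flux"].astype(float).to_numpy()
        order = np.argsort(grid)
        specs[name] = Spectrum(kind, grid[order], flux[order])
    for required in ("hydrogen", "helium", "neutron", "hze"):
        if required not in specs:
            raise ValueError(f"component {required!r} absent from {path}")
    return ReferenceField(
        hydrogen=specs["hydrogen"], helium=specs["helium"],
        neutron=specs["neutron"], hze_let=specs["hze"],
        component_doses=doses,
    )


_XLSX_ALIASES = {
    "hydrogen": ("hydrogen", "proton", "h "),
    "helium": ("helium", "alpha", "he "),
    "neutron": ("neutron",),
    "hze": ("hze", "z>=3", "z >= 3", "heavy"),
}


def _load_xlsx(path: Path) -> ReferenceField:
    """Best-effort loader for a spectra workbook (e.g. a supplementary file).

    Sheets and columns are discovered by fuzzy header matching: a sheet
    contributes a component when its name or a column header contains one
    of the component aliases, with a numeric abscissa/flux column pair.
    """
    book = pd.read_excel(path, sheet_name=None)
    specs: dict[str, Spectrum] = {}
    for sheet, df in book.items():
        df = df.dropna(how="all")
        text = " ".join([sheet.lower()] + [str(c).lower() for c in df.columns])
        for comp, aliases in _XLSX_ALIASES.items():
            if comp in specs or not any(a in text for a in aliases):
                continue
            num = df.apply(pd.to_numeric, errors="coerce").dropna(axis=1, how="all")
            num = num.dropna(how="any")
            if num.shape[1] < 2 or num.shape[0] < 4:
                continue
            grid = num.iloc[:, 0].to_numpy(float)
            flux = num.iloc[:, 1].to_numpy(float)
            order = np.argsort(grid)
            grid, flux = grid[order], np.clip(flux[order], 0, None)
            keep = np.concatenate([[True], np.diff(grid) > 0])
            specs[comp] = Spectrum(_COMPONENT_KIND[comp], grid[keep], flux[keep])
    missing = set(_COMPONENT_KIND) - set(specs)
    if missing:
        raise ValueError(f"could not locate spectra for {sorted(missing)} in {path}")
    return ReferenceField(
        hydrogen=specs["hydrogen"], helium=specs["helium"],
        neutron=specs["neutron"], hze_let=specs["hze"],
        component_doses={"pi_em": REFERENCE_COMPONENT_DOSES["pi_em"],
                         "neutron": REFERENCE_COMPONENT_DOSES["neutron"]},
    )
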