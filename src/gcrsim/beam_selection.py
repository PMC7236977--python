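"""Discrete beam selection: reference field -> ordered ion-energy-dose table.

The continuous shielded reference field is approximated by 33 monoenergetic
beams: protons and helium at 4 direct accelerator energies (100, 150, 250,
1000 MeV/n) plus ten degraded energies between 20 and 100 MeV/n produced by
a polyethylene binary filter from the 100 MeV/n beam, and five heavy-ion
(HZE) beams — 12C 1000, 16O 350, 28Si 600, 48Ti 1000, 56Fe 600 MeV/n.

Proton and helium intensities come from integrating the reference energy
spectra over energy bins assigned to each monoenergetic beam; HZE
intensities come from integrating the heavy-ion LET spectrum over five
log-spaced LET bins. Per-beam doses are then rescaled by a single factor so
the table sums to the target dose (the pi/EM and neutron-fragment
components of the field are dropped before rescaling, since an accelerator
does not deliver them).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gcrsim.ion_physics import POLYETHYLENE, WATER, Ion, csda_range, ion, stopping_power
from gcrsim.reference_field import (
    FLUENCE_TO_GY,
    ReferenceField,
    Spectrum,
    integral_fluence,
)

# Canonical beam energies (MeV/n). The ten degraded energies are the
# facility's printed constants; a pure log-spaced generator between 20 and
# 100 MeV/n gives a slightly different step ratio (1.175 vs the printed
# ~1.166), so the list is data and log_spaced_energies() a documented
# approximation.
DEGRADED_ENERGIES = (20.0, 23.3, 27.2, 31.7, 37.0, 43.2, 50.3, 58.7, 68.5, 79.9)
DIRECT_ENERGIES = (100.0, 150.0, 250.0, 1000.0)
HZE_BEAMS = (("12C", 1000.0), ("16O", 350.0), ("28Si", 600.0),
             ("48Ti", 1000.0), ("56Fe", 600.0))

ENERGY_BIN_FLOOR = 0.0  # MeV/n, lower edge of the lowest bin
ENERGY_BIN_CEILING = 50000.0  # MeV/n (50 GeV/n), upper edge of the top bin
LET_BIN_FLOOR = 2.0  # keV/um, lowest LET of Z=3 ions in water
LET_BIN_CEILING = 200.0  # keV/um
DEGRADER_INCIDENT_ENERGY = 100.0  # MeV/n


def log_spaced_energies(n: int = 10, lo: float = 20.0, hi: float = 100.0) -> np.ndarray:
    """Ten log-spaced degraded energies on [lo, hi); approximates the
    canonical printed list (which is kept as data)."""
    return np.geomspace(lo, hi, n + 1)[:-1]


@dataclass(frozen=True)
class EnergyBin:
    lower: float
    upper: float
    representative_energy: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("bin lower edge must be below upper edge")


@dataclass(frozen=True)
class LETBin:
    lower: float
    upper: float
    representative_ion_energy: tuple  # (Ion, MeV/n)

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("bin lower edge must be below upper edge")


@dataclass(frozen=True)
class Delivery:
    mode: str  # "direct" | "degraded"
    incident_energy: float | None = None  # MeV/n, degraded beams only
    filter_cm: float | None = None  # cm polyethylene


DIRECT = Delivery("direct")


@dataclass(frozen=True)
class Beam:
    ion: Ion
    energy: float  # MeV/n
    let_water: float  # keV/um
    range_water: float  # cm
    dose: float  # mGy
    delivery: Delivery = DIRECT
    fraction_dose: float | None = None  # mGy/day when scheduled

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("beam dose must be non-negative")

    @property
    def booster_key(self) -> tuple:
        """The accelerator (Booster) ion-energy setting delivering this beam.

        Degraded beams share their 100 MeV/n parent's setting, as does the
        direct 100 MeV/n beam itself.
        """
        if self.delivery.mode == "degraded":
            return (self.ion.symbol, self.delivery.incident_energy)
        return (self.ion.symbol, self.energy)


@dataclass(frozen=True)
class BeamTable:
    beams: tuple
    target_dose: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = math.fsum(b.dose for b in self.beams)
        if self.target_dose > 0 and abs(total - self.target_dose) > 1e-6 * self.target_dose:
            raise ValueError(
                f"beam doses sum to {total}, expected target {self.target_dose}"
            )

    @property
    def total_dose(self) -> float:
        return math.fsum(b.dose for b in self.beams)

    def scaled(self, target_dose: float) -> "BeamTable":
        f = target_dose / self.total_dose
        return BeamTable(
            tuple(replace(b, dose=b.dose * f) for b in self.beams),
            target_dose, dict(self.provenance, scaled_from=self.target_dose),
        )


def _make_beam(ion_: Ion, energy: float, dose: float) -> Beam:
    res = stopping_power(ion_, energy, WATER)
    rng = csda_range(ion_, energy, WATER)
    if energy < DEGRADER_INCIDENT_ENERGY and ion_.symbol in ("1H", "4He"):
        t = (csda_range(ion_, DEGRADER_INCIDENT_ENERGY, POLYETHYLENE)
             - csda_range(ion_, energy, POLYETHYLENE))
        delivery = Delivery("degraded", DEGRADER_INCIDENT_ENERGY, t)
    else:
        delivery = DIRECT
    return Beam(ion_, energy, res.let, rng, dose, delivery)


# --- Bin construction -----------------------------------------------------

def make_energy_bins(
    discrete_energies=DIRECT_ENERGIES, degraded_energies=DEGRADED_ENERGIES
) -> list[EnergyBin]:
    """Energy bins for the proton/helium monoenergetic representatives.

    Interior edges are geometric means of adjacent representative
    energies; the lowest edge is 0 MeV/n (so sub-20 MeV/n fluence, which
    cannot penetrate the animal housing, is credited to the 20 MeV/n
    beam) and the highest edge is 50 GeV/n.
    """
    reps = list(degraded_energies) + list(discrete_energies)
    if any(b <= a for a, b in zip(reps, reps[1:])):
        raise ValueError("beam energies must be strictly increasing")
    edges = [ENERGY_BIN_FLOOR]
    for a, b in zip(reps, reps[1:]):
        edges.append(math.sqrt(a * b))
    edges.append(ENERGY_BIN_CEILING)
    return [EnergyBin(lo, hi, rep) for lo, hi, rep in zip(edges, edges[1:], reps)]


def make_let_bins(hze_beams=HZE_BEAMS) -> list[LETBin]:
    """Five log-spaced LET bins tiling [2, 200] keV/um for the HZE beams.

    Interior edges are geometric means of the LETs (computed in water) of
    adjacent beams; the outer edges are fixed at 2 and 200 keV/um.
    """
    beams = [(ion(sym) if isinstance(sym, str) else sym, e) for sym, e in hze_beams]
    lets = [stopping_power(i, e, WATER).let for i, e in beams]
    if any(b <= a for a, b in zip(lets, lets[1:])):
        raise ValueError("HZE beam LETs must be strictly increasing")
    edges = [LET_BIN_FLOOR]
    for a, b in zip(lets, lets[1:]):
        edges.append(math.sqrt(a * b))
    edges.append(LET_BIN_CEILING)
    return [LETBin(lo, hi, (i, e)) for lo, hi, (i, e) in zip(edges, edges[1:], beams)]


# --- Beam table design ----------------------------------------------------

def design_beams(
    field_: ReferenceField,
    energies: tuple | None = None,
    hze_beams=HZE_BEAMS,
    target_dose: float = 500.0,
) -> BeamTable:
    """Convert a reference field into the discrete beam dose table.

    Per-bin fluence is the spectrum integral over the (half-open) bin;
    per-beam dose is fluence x LET(representative) x the fluence-to-dose
    constant. Protons and helium are binned on the energy axis, HZE on
    the LET axis. All doses are then rescaled by one factor so the table
    sums to ``target_dose`` (dropping the pi/EM and neutron components).

    ``energies``, when given, is a (direct, degraded) pair of energy lists.
    """
    if target_dose <= 0:
        raise ValueError("target_dose must be positive")
    ebins = make_energy_bins(*energies) if energies else make_energy_bins()
    lbins = make_let_bins(hze_beams)

    beams: list[Beam] = []
    for group, sym in (("hydrogen", "1H"), ("helium", "4He")):
        spec: Spectrum = getattr(field_, group)
        ion_ = ion(sym)
        for b in ebins:
            fluence = integral_fluence(spec, b.lower if b.lower > 0 else None, b.upper)
            if fluence == 0.0:
                warnings.warn(f"empty {group} bin [{b.lower:g}, {b.upper:g}) MeV/n; "
                              "beam carries zero dose")
            let = stopping_power(ion_, b.representative_energy, WATER).let
            dose = 1e3 * FLUENCE_TO_GY * fluence * let / WATER.density
            beams.append(_make_beam(ion_, b.representative_energy, dose))
    for b in lbins:
        ion_, energy = b.representative_ion_energy
        fluence = integral_fluence(field_.hze_let, b.lower, b.upper)
        if fluence == 0.0:
            warnings.warn(f"empty LET bin [{b.lower:g}, {b.upper:g}) keV/um; "
                          "beam carries zero dose")
        let = stopping_power(ion_, energy, WATER).let
        dose = 1e3 * FLUENCE_TO_GY * fluence * let / WATER.density
        beams.append(_make_beam(ion_, energy, dose))

    raw_total = math.fsum(b.dose for b in beams)
    if raw_total <= 0:
        raise ValueError("reference field yields zero dose in every bin")
    f = target_dose / raw_total
    scaled = tuple(replace(b, dose=b.dose * f) for b in beams)
    return BeamTable(scaled, target_dose,
                     provenance={"kind": "full", "raw_total_mGy": raw_total,
                                 "normalization": f})


# --- Canonical printed designs -------------------------------------------

# The as-commissioned 33-beam table normalized to 500 mGy:
# (ion, E MeV/n, dose mGy). LET and range are recomputed on construction.
_CANONICAL_DOSES = (
    # ten degraded + four direct proton beams
    ("1H", 20.0, 30.4), ("1H", 23.3, 6.7), ("1H", 27.2, 7.4), ("1H", 31.7, 8.0),
    ("1H", 37.0, 8.7), ("1H", 43.2, 9.3), ("1H", 50.3, 10.0), ("1H", 58.7, 10.6),
    ("1H", 68.5, 11.1), ("1H", 79.9, 11.2), ("1H", 100.0, 27.2),
    ("1H", 150.0, 35.0), ("1H", 250.0, 68.9), ("1H", 1000.0, 123.6),
    # ten degraded + four direct helium beams
    ("4He", 20.0, 11.0), ("4He", 23.3, 2.1), ("4He", 27.2, 2.2), ("4He", 31.7, 2.3),
    ("4He", 37.0, 2.5), ("4He", 43.2, 2.6), ("4He", 50.3, 2.7), ("4He", 58.7, 2.7),
    ("4He", 68.5, 2.7), ("4He", 79.9, 2.7), ("4He", 100.0, 6.1),
    ("4He", 150.0, 7.5), ("4He", 250.0, 16.4), ("4He", 1000.0, 24.9),
    # five HZE beams
    ("12C", 1000.0, 11.7), ("16O", 350.0, 15.4), ("28Si", 600.0, 8.1),
    ("48Ti", 1000.0, 4.5), ("56Fe", 600.0, 4.1),
)

# The simplified 5-ion (6-beam) mixed field, printed doses at 500 mGy in
# delivery order.
_SIMPLIFIED_DOSES = (
    ("1H", 1000.0, 174.1), ("28Si", 600.0, 5.7), ("4He", 250.0, 90.2),
    ("16O", 350.0, 29.1), ("56Fe", 600.0, 5.1), ("1H", 250.0, 195.9),
)


def canonical_table(target_dose: float = 500.0) -> BeamTable:
    """The as-commissioned 33-beam design, rescaled to ``target_dose`` mGy.

    The printed per-beam doses sum to 500.3 mGy (rounding of the published
    rows); a single factor rescales them to the requested target.
    """
    raw = math.fsum(d for _, _, d in _CANONICAL_DOSES)
    f = target_dose / raw
    beams = tuple(_make_beam(ion(sym), e, d * f) for sym, e, d in _CANONICAL_DOSES)
    return BeamTable(beams, target_dose,
                     provenance={"kind": "canonical", "printed_total_mGy": raw})


def simplified_field(target_dose: float = 500.0) -> BeamTable:
    """The simplified 5-ion mixed field (six beams, protons twice).

    Dose proportions follow the printed 500 mGy design, scaled linearly
    to ``target_dose``; the delivery order is as printed (protons first
    and last, carrying the majority of the dose).
    """
    if target_dose <= 0:
        raise ValueError("target_dose must be positive")
    raw = math.fsum(d for _, _, d in _SIMPLIFIED_DOSES)
    f = target_dose / raw
    beams = tuple(_make_beam(ion(sym), e, d * f) for sym, e, d in _SIMPLIFIED_DOSES)
    return BeamTable(beams, target_dose,
                     provenance={"kind": "simplified", "printed_total_mGy": raw})


def group_dose_shares(table: BeamTable) -> dict:
    """Fraction of the table dose delivered by H, He and the HZE group."""
    shares = {"hydrogen": 0.0, "helium": 0.0, "hze": 0.0}
    for b in table.beams:
        if b.ion.Z == 1:
            shares["hydrogen"] += b.dose
        elif b.ion.Z == 2:
            shares["helium"] += b.dose
        else:
            shares["hze"] += b.dose
    total = table.total_dose
    return {k: v / total for k, v in shares.items()}


# --- Serialization --------------------------------------------------------

_CSV_COLUMNS = ["ion", "Z", "A", "energy_MeV_n", "LET_keV_um", "range_cm",
                "dose_mGy", "fraction_dose_mGy_day", "delivery",
                "incident_MeV_n", "filter_cm"]


def write_table(table: BeamTable, path: str | Path) -> None:
    rows = []
    for b in table.beams:
        rows.append({
            "ion": b.ion.symbol, "Z": b.ion.Z, "A": b.ion.A,
            "energy_MeV_n": b.energy, "LET_keV_um": b.let_water,
            "range_cm": b.range_water, "dose_mGy": repr(b.dose),
            "fraction_dose_mGy_day": "" if b.fraction_dose is None else repr(b.fraction_dose),
            "delivery": b.delivery.mode,
            "incident_MeV_n": "" if b.delivery.incident_energy is None else repr(b.delivery.incident_energy),
            "filter_cm": "" if b.delivery.filter_cm is None else repr(b.delivery.filter_cm),
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_table(path: str | Path) -> BeamTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"beam table missing columns {sorted(missing)}")
    beams = []
    for _, r in df.iterrows():
        if r["delivery"] == "degraded":
            delivery = Delivery("degraded", float(r["incident_MeV_n"]), float(r["filter_cm"]))
        else:
            delivery = DIRECT
        frac = r["fraction_dose_mGy_day"]
        beams.append(Beam(
            Ion(str(r["ion"]), int(r["Z"]), int(r["A"])),
            float(r["energy_MeV_n"]), float(r["LET_keV_um"]),
            float(r["range_cm"]), float(r["dose_mGy"]), delivery,
            None if pd.isna(frac) else float(frac),
        ))
    total = math.fsum(b.dose for b in beams)
    return BeamTable(tuple(beams), total, provenance={"kind": "loaded", "path": str(path)})
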