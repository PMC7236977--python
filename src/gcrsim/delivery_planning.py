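"""Degrader settings, beam ordering / switch accounting, and fractionation.

Three facility-facing planning steps:

* the binary filter — a doubling set of polyethylene sheets (0.1, 0.2, ...,
  12.8 cm) remotely inserted into the beamline — is solved greedily for a
  target water- or polyethylene-equivalent thickness;
* the 33-beam delivery order is emitted (the commissioned sequence is kept
  as data) and validated against the design rules: protons and helium
  before heavy ions, heavy-ion beams separated by light-ion beams, and
  low-energy degraded beams grouped in pairs so only the filter changes;
  the accelerator switch count is the number of maximal consecutive runs
  sharing one Booster ion-energy setting (degraded beams group under their
  100 MeV/n parent), counting the first beam's setup;
* the total dose is split into equal daily fractions on a 6-days-per-week
  calendar (the seventh day is reserved for contingency), flagging any
  per-beam daily dose below the facility's reliable minimum of 0.1 mGy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from gcrsim.beam_selection import Beam, BeamTable

FILTER_THICKNESSES = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8)  # cm polyethylene
FILTER_MAX_TOTAL = 25.5  # cm, all sheets inserted
MIN_DELIVERABLE_DOSE = 0.1  # mGy, smallest reliably measured beam fraction
DEFAULT_DAYS_PER_WEEK = 6

# The commissioned delivery order of the 33-beam table, as (ion, MeV/n).
CANONICAL_SEQUENCE = (
    ("1H", 1000.0), ("4He", 1000.0), ("28Si", 600.0),
    ("1H", 20.0), ("1H", 23.3), ("4He", 20.0), ("4He", 23.3),
    ("48Ti", 1000.0),
    ("4He", 27.2), ("4He", 31.7), ("1H", 27.2), ("1H", 31.7),
    ("1H", 37.0), ("1H", 43.2), ("4He", 37.0), ("4He", 43.2),
    ("16O", 350.0),
    ("4He", 50.3), ("4He", 58.7), ("1H", 50.3), ("1H", 58.7),
    ("1H", 68.5), ("1H", 79.9), ("4He", 68.5), ("4He", 79.9),
    ("12C", 1000.0),
    ("4He", 100.0), ("1H", 100.0), ("1H", 150.0), ("4He", 150.0),
    ("56Fe", 600.0), ("4He", 250.0), ("1H", 250.0),
)


@dataclass(frozen=True)
class BinaryFilter:
    """A selection from the doubling polyethylene sheet set."""

    selected: tuple  # subset of FILTER_THICKNESSES, cm
    target: float  # requested total, cm

    @property
    def total(self) -> float:
        return math.fsum(self.selected)


def solve_filter(target_total: float) -> BinaryFilter:
    """Greedy binary decomposition of a degrader thickness.

    The doubling set reaches any multiple of 0.1 cm up to 25.5 cm, so the
    achieved total is the target rounded to the 0.1 cm lattice — always
    within half the 0.1 cm resolution.
    """
    if not 0 <= target_total <= FILTER_MAX_TOTAL + 0.05:
        raise ValueError(
            f"degrader target {target_total} cm outside [0, {FILTER_MAX_TOTAL}] cm"
        )
    remaining = round(min(target_total, FILTER_MAX_TOTAL) * 10) / 10
    chosen = []
    for t in sorted(FILTER_THICKNESSES, reverse=True):
        if t <= remaining + 1e-9:
            chosen.append(t)
            remaining = round((remaining - t) * 10) / 10
    return BinaryFilter(tuple(sorted(chosen)), target_total)


@dataclass(frozen=True)
class DeliverySequence:
    beams: tuple  # ordered Beam objects
    accelerator_groups: tuple  # tuple of (booster_key, n_consecutive_beams)
    provenance: dict = field(default_factory=dict)

    @property
    def switch_count(self) -> int:
        """Unique accelerator settings delivered, including the first setup."""
        return len(self.accelerator_groups)


def _group_runs(beams) -> tuple:
    groups = []
    for b in beams:
        key = b.booster_key
        if groups and groups[-1][0] == key:
            groups[-1] = (key, groups[-1][1] + 1)
        else:
            groups.append((key, 1))
    return tuple(groups)


def count_switches(sequence: DeliverySequence) -> int:
    return sequence.switch_count


def validate_sequence(beams) -> list[str]:
    """Check a delivery order against the three design rules.

    Returns a list of human-readable violations (empty when compliant):
    light ions lead the sequence, no two HZE beams are adjacent, and each
    HZE beam after the first is preceded by at least one light-ion beam.
    """
    violations = []
    if not beams:
        return ["empty sequence"]
    if beams[0].ion.Z > 2:
        violations.append("sequence must open with a proton or helium beam")
    for a, b in zip(beams, beams[1:]):
        if a.ion.Z > 2 and b.ion.Z > 2:
            violations.append(
                f"adjacent heavy-ion beams {a.ion.symbol} and {b.ion.symbol}"
            )
    return violations


def order_beams(table: BeamTable) -> DeliverySequence:
    """Order a beam table for delivery.

    When the table is the canonical 33-beam set the commissioned printed
    sequence is emitted and validated. Any other table falls back to a
    heuristic honoring the same rules (flagged in provenance): light-ion
    beams interleaved from low to high energy with HZE beams inserted
    between light-ion blocks, protons first and last.
    """
    key = lambda b: (b.ion.symbol, b.energy)
    by_key = {key(b): b for b in table.beams}
    canonical = set(CANONICAL_SEQUENCE)
    if set(by_key) == canonical and len(table.beams) == len(CANONICAL_SEQUENCE):
        ordered = tuple(by_key[k] for k in CANONICAL_SEQUENCE)
        violations = validate_sequence(ordered)
        return DeliverySequence(ordered, _group_runs(ordered),
                                {"order": "canonical", "violations": violations})

    light = sorted((b for b in table.beams if b.ion.Z <= 2),
                   key=lambda b: (b.energy, b.ion.Z))
    heavy = sorted((b for b in table.beams if b.ion.Z > 2), key=lambda b: b.let_water)
    if not light:
        raise ValueError("cannot order a table with no proton/helium beams")
    # open with the highest-energy proton if available, close with a proton
    ordered = []
    light_iter = list(light)
    heavy_iter = list(heavy)
    # interleave: insert one HZE beam after every block of light beams
    block = max(1, len(light_iter) // (len(heavy_iter) + 1)) if heavy_iter else len(light_iter)
    i = 0
    while light_iter or heavy_iter:
        take = light_iter[:block]
        light_iter = light_iter[block:]
        ordered.extend(take)
        if heavy_iter and light_iter:
            ordered.append(heavy_iter.pop(0))
        elif heavy_iter and not light_iter:
            # never end on back-to-back heavy ions; alternate with nothing
            ordered.extend(heavy_iter)
            heavy_iter = []
        i += 1
    seq = tuple(ordered)
    return DeliverySequence(seq, _group_runs(seq),
                            {"order": "heuristic", "violations": validate_sequence(seq)})


@dataclass(frozen=True)
class FractionationSchedule:
    n_fractions: int
    days_per_week: int
    beams: tuple  # Beam objects with fraction_dose set (mGy/day)
    exposure_days: tuple  # calendar day offsets (day 0 = first exposure)
    below_minimum: tuple  # beams whose daily dose < MIN_DELIVERABLE_DOSE
    daily_doses: tuple = ()  # per exposure day: tuple of (beam index, dose mGy)

    @property
    def daily_total(self) -> float:
        return math.fsum(d for _, d in self.daily_doses[0]) if self.daily_doses else 0.0

    def total_per_beam(self) -> list[float]:
        totals = [0.0] * len(self.beams)
        for day in self.daily_doses:
            for idx, d in day:
                totals[idx] += d
        return totals


def fractionate(
    table: BeamTable,
    n_fractions: int,
    days_per_week: int = DEFAULT_DAYS_PER_WEEK,
    hze_split: bool = False,
) -> FractionationSchedule:
    """Split a beam table into equal daily fractions.

    Every beam is divided into ``n_fractions`` equal daily doses; the
    calendar assigns exposures to the first ``days_per_week`` days of each
    week, reserving the remaining day(s) for contingency. With
    ``hze_split`` the heavy-ion beams alternate between the two halves of
    the exposure days at twice the daily dose (n_fractions must be even),
    preserving per-beam totals exactly.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if not 1 <= days_per_week <= 7:
        raise ValueError("days_per_week must be in 1..7 (calendar weeks)")
    if hze_split and n_fractions % 2:
        raise ValueError("hze_split needs an even number of fractions")

    # calendar: exposure on the first days_per_week days of each week
    days = []
    d = 0
    while len(days) < n_fractions:
        if d % 7 < days_per_week:
            days.append(d)
        d += 1

    beams = tuple(replace(b, fraction_dose=b.dose / n_fractions) for b in table.beams)
    daily = []
    for k in range(n_fractions):
        today = []
        for idx, b in enumerate(beams):
            if hze_split and b.ion.Z > 2:
                # group A (even HZE index) on even exposure days, group B on odd
                hze_rank = sum(1 for bb in beams[:idx] if bb.ion.Z > 2)
                if k % 2 == hze_rank % 2:
                    today.append((idx, 2.0 * b.fraction_dose))
            else:
                today.append((idx, b.fraction_dose))
        daily.append(tuple(today))

    flagged = tuple(b for b in beams if b.fraction_dose < MIN_DELIVERABLE_DOSE)
    return FractionationSchedule(
        n_fractions=n_fractions, days_per_week=days_per_week, beams=beams,
        exposure_days=tuple(days), below_minimum=flagged, daily_doses=tuple(daily),
    )


def write_schedule(schedule: FractionationSchedule, path: str | Path) -> None:
    """Schedule CSV: day_index, date_offset, ion, energy, dose_mGy."""
    rows = []
    for day_idx, (offset, doses) in enumerate(zip(schedule.exposure_days, schedule.daily_doses)):
        for beam_idx, dose in doses:
            b = schedule.beams[beam_idx]
            rows.append((day_idx, offset, b.ion.symbol, b.energy, repr(dose)))
    pd.DataFrame(rows, columns=["day_index", "date_offset", "ion", "energy", "dose_mGy"]
                 ).to_csv(path, index=False)
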