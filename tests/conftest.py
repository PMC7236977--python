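"""Shared fixtures: canonical designs, synthetic field, coarse phantoms."""

import pytest

from gcrsim import beam_selection, phantom_dose, reference_field

# The published 33-row beam definition (ion, E MeV/n, LET keV/um in water,
# CSDA range cm in water, dose mGy at the 500 mGy normalization) used as
# the reference battery for the stopping-power engine.
TABLE3_ROWS = [
    ("1H", 150.0, 0.54, 15.9, 35.0), ("1H", 250.0, 0.39, 38.1, 68.9),
    ("1H", 1000.0, 0.22, 326.6, 123.6),
    ("4He", 150.0, 2.17, 16.0, 7.5), ("4He", 250.0, 1.56, 38.3, 16.4),
    ("4He", 1000.0, 0.88, 327.8, 24.9),
    ("12C", 1000.0, 7.95, 110.13, 11.7), ("16O", 350.0, 20.8, 16.95, 15.4),
    ("28Si", 600.0, 50.2, 22.73, 8.1), ("48Ti", 1000.0, 109.5, 32.53, 4.5),
    ("56Fe", 600.0, 175.1, 13.09, 4.1),
    # degraded proton sub-table (from 100 MeV/n incident on the binary filter)
    ("1H", 20.0, 2.59, 0.43, 30.4), ("1H", 23.3, 2.29, 0.56, 6.7),
    ("1H", 27.2, 2.02, 0.75, 7.4), ("1H", 31.7, 1.79, 0.98, 8.0),
    ("1H", 37.0, 1.58, 1.3, 8.7), ("1H", 43.2, 1.39, 1.72, 9.3),
    ("1H", 50.3, 1.23, 2.26, 10.0), ("1H", 58.7, 1.09, 2.99, 10.6),
    ("1H", 68.5, 0.97, 3.95, 11.1), ("1H", 79.9, 0.86, 5.2, 11.2),
    ("1H", 100.0, 0.73, 7.76, 27.2),
    # degraded helium sub-table
    ("4He", 20.0, 10.34, 0.43, 11.0), ("4He", 23.3, 9.14, 0.57, 2.1),
    ("4He", 27.2, 8.06, 0.75, 2.2), ("4He", 31.7, 7.12, 0.99, 2.3),
    ("4He", 37.0, 6.29, 1.31, 2.5), ("4He", 43.2, 5.56, 1.73, 2.6),
    ("4He", 50.3, 4.92, 2.28, 2.7), ("4He", 58.7, 4.36, 3.01, 2.7),
    ("4He", 68.5, 3.86, 3.97, 2.7), ("4He", 79.9, 3.43, 5.23, 2.7),
    ("4He", 100.0, 2.9, 7.81, 6.1),
]


@pytest.fixture(scope="session")
def canonical500():
    return beam_selection.canonical_table(500.0)


@pytest.fixture(scope="session")
def field0():
    return reference_field.synth_field(seed=0)


@pytest.fixture(scope="session")
def mouse_coarse():
    """1 mm working-resolution mouse for transport unit tests."""
    return phantom_dose.make_phantom("mouse", seed=0, voxel_mm=1.0)
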