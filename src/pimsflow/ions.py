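"""Single-ion tables.

An ion table is a :class:`pandas.DataFrame` with one row per detected ion and
columns ``ion_id, mz, stori_slope, scan_index, line_index`` plus, once charge
assignment has run, nullable ``charge`` and ``neutral_mass`` columns.  Tables
are serialized as plain TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import M_PROTON
from .errors import InvalidInputError

ION_COLUMNS = ["ion_id", "mz", "stori_slope", "scan_index", "line_index"]
TRUTH_COLUMNS = ["ion_id", "source_id", "true_charge", "true_isotope"]


def neutral_mass_from_mz(mz, charge):
    """Neutral mass from m/z and charge: ``mass = m/z * z - z * M_proton``."""
    mz = np.asarray(mz, dtype=float)
    z = np.asarray(charge, dtype=float)
    return mz * z - z * M_PROTON


def mz_from_neutral_mass(mass, charge):
    """m/z of a protonated ion: ``(mass + z * M_proton) / z``."""
    mass = np.asarray(mass, dtype=float)
    z = np.asarray(charge, dtype=float)
    return (mass + z * M_PROTON) / z


def validate_ion_table(ions: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ION_COLUMNS if c not in ions.columns]
    if missing:
        raise InvalidInputError(f"ion table lacks columns: {missing}")
    if len(ions) and (ions["mz"] <= 0).any():
        raise InvalidInputError("ion m/z values must be positive")
    return ions


def write_ion_table(ions: pd.DataFrame, path) -> None:
    validate_ion_table(ions)
    ions.to_csv(path, sep="\t", index=False)


def read_ion_table(path) -> pd.DataFrame:
    ions = pd.read_csv(path, sep="\t")
    validate_ion_table(ions)
    if "charge" in ions.columns:
        ions["charge"] = ions["charge"].astype("Int64")
    return ions


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
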