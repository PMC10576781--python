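"""Intact-mass-tag annotation of observed proteoform masses.

Each database protein expands into eleven candidates: the unmodified mass,
four single modifications (initiator-Met loss, water loss, monoacetylation,
monophosphorylation) and their six unordered pairwise combinations.
Observed masses can first be recalibrated against anchor proteoforms of
known mass (a linear ppm-drift model), then matched against the candidate
set within a ppm tolerance (default ±1.5 ppm).  Monoisotopic masses are
assumed throughout, consistent with the survey mass convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .constants import MOD_DELTAS
from .errors import InsufficientAnchorsError, InvalidInputError

MOD_NAMES = ("met_loss", "water_loss", "acetyl", "phospho")


@dataclass(frozen=True)
class CandidateMass:
    """One database protein with a (possibly empty) modification set."""

    accession: str
    base_mass: float
    mod_set: tuple[str, ...]
    candidate_mass: float


@dataclass(frozen=True)
class IMTMatch:
    """A candidate matching an observed mass within tolerance."""

    query: str
    observed_mass: float
    candidate: CandidateMass
    ppm_error: float


def expand_candidates(db) -> list[CandidateMass]:
    """Expand (accession, base_mass) records into 11 candidates each.

    ``db`` is an iterable of ``(accession, base_mass)`` pairs or a DataFrame
    with ``accession`` and ``monoisotopic_mass`` columns.
    """
    if isinstance(db, pd.DataFrame):
        records = list(zip(db["accession"], db["monoisotopic_mass"]))
    else:
        records = list(db)
    mod_sets: list[tuple[str, ...]] = [()]
    mod_sets += [(m,) for m in MOD_NAMES]
    mod_sets += [tuple(pair) for pair in combinations(MOD_NAMES, 2)]
    out = []
    for acc, base in records:
        base = float(base)
        if base <= 0:
            raise InvalidInputError(f"{acc}: base mass must be positive")
        for mods in mod_sets:
            out.append(
                CandidateMass(
                    accession=str(acc),
                    base_mass=base,
                    mod_set=mods,
                    candidate_mass=base + sum(MOD_DELTAS[m] for m in mods),
                )
            )
    return out


class CandidateIndex:
    """Sorted-mass index over candidates for tolerance queries."""

    def __init__(self, candidates: list[CandidateMass]):
        self.candidates = sorted(candidates, key=lambda c: (c.candidate_mass, c.accession, c.mod_set))
        self._masses = np.array([c.candidate_mass for c in self.candidates])

    def query(self, observed: float, tolerance_ppm: float) -> list[CandidateMass]:
        lo = observed / (1.0 + tolerance_ppm * 1e-6)
        hi = observed / (1.0 - tolerance_ppm * 1e-6)
        a = np.searchsorted(self._masses, lo, side="left")
        b = np.searchsorted(self._masses, hi, side="right")
        return self.candidates[a:b]


def ppm_error(observed: float, candidate_mass: float) -> float:
    return 1e6 * (observed - candidate_mass) / candidate_mass


def imt_match(
    observed: float,
    candidates: list[CandidateMass] | CandidateIndex,
    tolerance_ppm: float = 1.5,
    query: str = "",
) -> list[IMTMatch]:
    """All candidates within ±``tolerance_ppm`` of an observed mass.

    Sorted by absolute ppm error (ties: accession, then modification set);
    deterministic.
    """
    if tolerance_ppm <= 0:
        raise InvalidInputError("tolerance_ppm must be positive")
    index = candidates if isinstance(candidates, CandidateIndex) else CandidateIndex(candidates)
    hits = [
        IMTMatch(
            query=query,
            observed_mass=observed,
            candidate=c,
            ppm_error=ppm_error(observed, c.candidate_mass),
        )
        for c in index.query(observed, tolerance_ppm)
        if abs(ppm_error(observed, c.candidate_mass)) <= tolerance_ppm
    ]
    hits.sort(key=lambda h: (abs(h.ppm_error), h.candidate.accession, h.candidate.mod_set))
    return hits


@dataclass
class RecalibrationResult:
    """Corrected masses plus the fitted drift model and anchor residuals."""

    corrected: np.ndarray
    intercept_ppm: float
    slope_ppm_per_da: float
    anchor_residuals_ppm: np.ndarray


def recalibrate(observed_masses, anchors) -> RecalibrationResult:
    """Correct a systematic ppm drift using anchors of known mass.

    ``anchors`` is a sequence of ``(observed, true)`` pairs.  The drift is
    modeled as ``ppm(mass) = a + b * mass`` fit by least squares (a constant
    offset when all anchor masses coincide) and inverted on the observed
    masses.  Anchor residuals are reported so a lack of fit (for example a
    nonlinear drift) is visible rather than hidden.
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise InsufficientAnchorsError("recalibration needs at least two anchors")
    obs = np.array([a[0] for a in anchors], dtype=float)
    true = np.array([a[1] for a in anchors], dtype=float)
    drift = 1e6 * (obs - true) / true
    if np.ptp(obs) < 1e-9:
        a, b = float(drift.mean()), 0.0
    else:
        b, a = np.polyfit(obs, drift, 1)
    masses = np.asarray(observed_masses, dtype=float)
    corrected = masses / (1.0 + (a + b * masses) * 1e-6)
    anchor_corr = obs / (1.0 + (a + b * obs) * 1e-6)
    residuals = 1e6 * (anchor_corr - true) / true
    return RecalibrationResult(
        corrected=corrected,
        intercept_ppm=float(a),
        slope_ppm_per_da=float(b),
        anchor_residuals_ppm=residuals,
    )


def read_protein_db(path) -> pd.DataFrame:
    """Read a protein database as TSV or FASTA.

    TSV needs ``accession`` and ``monoisotopic_mass`` columns (``name``
    optional).  For FASTA, monoisotopic masses are computed from the
    sequences with standard residue masses.
    """
    path = str(path)
    if path.endswith((".fasta", ".fa", ".faa")):
        from pyteomics import fasta, mass

        records = []
        for header, seq in fasta.read(path):
            acc = header.split()[0]
            records.append(
                {
                    "accession": acc,
                    "name": header,
                    "monoisotopic_mass": mass.calculate_mass(sequence=seq, monoisotopic=True),
                }
            )
        return pd.DataFrame(records)
    df = pd.read_csv(path, sep="\t")
    missing = {"accession", "monoisotopic_mass"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"protein DB lacks columns: {sorted(missing)}")
    return df


def match_table(matches: list[IMTMatch]) -> pd.DataFrame:
    """Flatten matches for TSV export."""
    return pd.DataFrame(
        [
            {
                "query": h.query,
                "observed_mass": h.observed_mass,
                "accession": h.candidate.accession,
                "mod_set": "+".join(h.candidate.mod_set) or "unmodified",
                "candidate_mass": h.candidate.candidate_mass,
                "ppm_error": h.ppm_error,
            }
            for h in matches
        ],
        columns=["query", "observed_mass", "accession", "mod_set", "candidate_mass", "ppm_error"],
    )
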