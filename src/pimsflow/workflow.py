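"""End-to-end helpers chaining the survey stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .spectrum import (
    MassSpectrumEstimate,
    ProteoformFeature,
    assign_charge,
    build_mass_spectrum,
    pick_features,
)


@dataclass
class SurveyResult:
    """Charge-assigned ions, the mass-domain spectrum and picked features."""

    ions: pd.DataFrame
    spectrum: MassSpectrumEstimate
    features: list[ProteoformFeature]


def run_survey(
    ions: pd.DataFrame,
    calib_slope: float,
    n_votes: int = 25,
    vote_agreement: float = 0.8,
    slope_uncertainty_cv: float = 0.005,
    bandwidth: float | str = "auto",
    rel_abundance_threshold: float = 0.01,
    min_ion_count: int = 1,
    seed: int = 0,
) -> SurveyResult:
    """Charge-assign ions, build the KDE spectrum, and pick features."""
    assigned = assign_charge(
        ions,
        calib_slope,
        n_votes=n_votes,
        vote_agreement=vote_agreement,
        slope_uncertainty_cv=slope_uncertainty_cv,
        seed=seed,
    )
    spectrum = build_mass_spectrum(assigned, bandwidth=bandwidth)
    features = pick_features(
        spectrum,
        assigned,
        rel_abundance_threshold=rel_abundance_threshold,
        min_ion_count=min_ion_count,
    )
    return SurveyResult(ions=assigned, spectrum=spectrum, features=features)
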