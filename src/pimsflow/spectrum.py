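"""From single ions to a mass-domain spectrum with picked proteoform features.

The survey data product of an individual-ion line scan is built in three
stages:

1. :func:`assign_charge` — each ion's charge-proportional readout slope is
   compared against the instrument's charge calibration slope through a
   bootstrap voting scheme: the slope is resampled at its estimated relative
   uncertainty, each resample votes for an integer charge, and the charge is
   accepted only when the modal vote share clears an agreement threshold.
   The neutral mass of an accepted ion is ``m/z * z - z * M_proton``.
2. :func:`build_mass_spectrum` — a Gaussian kernel density estimate over the
   neutral masses, each ion contributing unit area, evaluated on a uniform
   mass grid.
3. :func:`pick_features` — iterative peak picking: take the global density
   maximum, characterize the proteoform envelope under it (monoisotopic mass,
   major isotope comb, member ions within ±10 ppm of the comb), mask the
   envelope region, repeat until remaining maxima fall below a user-defined
   fraction of the first maximum.

Reported feature masses are monoisotopic: the apex of a picked peak is an
isotopologue centroid, and the isotope index of that apex is inferred by
comparing the ion-mass centroid of the envelope with the averagine mean
offset.  This convention is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .constants import ISOTOPE_SPACING
from .errors import EmptySpectrumError, InvalidInputError
from .ions import neutral_mass_from_mz, validate_ion_table
from .isotopes import (
    envelope_support,
    envelope_sigma,
    isotope_distribution,
    major_isotope_indices,
    mean_offset,
    most_abundant_offset,
)

MASS_CONVENTION = "monoisotopic"


def assign_charge(
    ions: pd.DataFrame,
    calib_slope: float,
    n_votes: int = 25,
    vote_agreement: float = 0.8,
    slope_uncertainty_cv: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign integer charges by bootstrap voting on the calibrated slope.

    Returns a copy of the ion table with nullable-integer ``charge`` and
    float ``neutral_mass`` columns; ions whose modal vote share falls below
    ``vote_agreement`` are left unassigned (NA).
    """
    if calib_slope <= 0:
        raise InvalidInputError("calib_slope must be positive")
    if n_votes < 1:
        raise InvalidInputError("n_votes must be >= 1")
    validate_ion_table(ions)
    out = ions.copy()
    n = len(out)
    if n == 0:
        out["charge"] = pd.array([], dtype="Int64")
        out["neutral_mass"] = np.array([], dtype=float)
        return out

    rng = np.random.default_rng(seed)
    slopes = out["stori_slope"].to_numpy(dtype=float)
    if slope_uncertainty_cv > 0:
        votes = slopes[:, None] * (
            1.0 + rng.normal(0.0, slope_uncertainty_cv, (n, n_votes))
        )
    else:
        votes = np.repeat(slopes[:, None], n_votes, axis=1)
    z_votes = np.maximum(1, np.rint(votes / calib_slope)).astype(np.int64)

    zmax = int(z_votes.max())
    offsets = np.arange(n, dtype=np.int64)[:, None] * (zmax + 1)
    tallies = np.bincount(
        (z_votes + offsets).ravel(), minlength=n * (zmax + 1)
    ).reshape(n, zmax + 1)
    mode = tallies.argmax(axis=1)
    share = tallies.max(axis=1) / n_votes

    accepted = share >= vote_agreement
    charge = pd.array(np.where(accepted, mode, 0), dtype="Int64")
    charge[~accepted] = pd.NA
    out["charge"] = charge
    mass = neutral_mass_from_mz(out["mz"].to_numpy(), mode.astype(float))
    out["neutral_mass"] = np.where(accepted, mass, np.nan)
    return out


@dataclass
class MassSpectrumEstimate:
    """Kernel density estimate of the neutral-mass spectrum.

    ``density`` has units of ions/Da; ``density.sum() * grid_step`` equals
    the number of contributing ions.
    """

    mass_grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    grid_step: float
    n_ions: int

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.grid_step)


def auto_bandwidth(masses: np.ndarray) -> float:
    """Default KDE bandwidth: ``max(0.2 Da, 5 ppm * median mass)``.

    Resolves the 1.00235 Da isotope comb below roughly 30 kDa and lets it
    merge smoothly above.
    """
    return max(0.2, 5e-6 * float(np.median(masses)))


def build_mass_spectrum(
    ions: pd.DataFrame,
    bandwidth: float | str = "auto",
    grid_step: float | None = None,
) -> MassSpectrumEstimate:
    """Gaussian-KDE mass-domain spectrum of the charge-assigned ions."""
    if "neutral_mass" not in ions.columns:
        raise InvalidInputError("run assign_charge first: no neutral_mass column")
    masses = ions["neutral_mass"].to_numpy(dtype=float)
    masses = masses[np.isfinite(masses)]
    if masses.size == 0:
        raise EmptySpectrumError("no charge-assigned ions to build a spectrum from")
    bw = auto_bandwidth(masses) if bandwidth == "auto" else float(bandwidth)
    if bw <= 0:
        raise InvalidInputError("bandwidth must be positive")
    step = bw / 4.0 if grid_step is None else float(grid_step)

    pad = 5.0 * bw
    lo = np.floor((masses.min() - pad) / step) * step
    hi = masses.max() + pad
    n_grid = int(np.ceil((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n_grid)

    idx = np.clip(np.rint((masses - lo) / step).astype(int), 0, n_grid - 1)
    counts = np.bincount(idx, minlength=n_grid).astype(float)

    half = int(np.ceil(5.0 * bw / step))
    x = step * np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / bw) ** 2)
    kernel /= kernel.sum() * step

    density = fftconvolve(counts, kernel, mode="same")
    np.clip(density, 0.0, None, out=density)
    return MassSpectrumEstimate(
        mass_grid=grid, density=density, bandwidth=bw, grid_step=step,
        n_ions=int(masses.size),
    )


@dataclass
class ProteoformFeature:
    """A picked mass-domain feature and its supporting ions."""

    feature_id: str
    monoisotopic_mass: float
    isotope_masses: np.ndarray
    isotope_indices: np.ndarray
    ion_count: int
    member_ion_ids: np.ndarray
    relative_abundance: float = np.nan
    isotope_fit_score: float = np.nan
    apex_mass: float = np.nan


def default_mask_halfwidth(mass: float) -> float:
    """Pad added around a picked envelope when masking the density.

    2.5 Da below 30 kDa; above, three quarters of the expected isotope
    envelope FWHM.
    """
    if mass < 30_000.0:
        return 2.5
    return 0.75 * 2.3548 * envelope_sigma(mass) * ISOTOPE_SPACING


def envelope_mask_bounds(
    apex_mass: float, mask_halfwidth: float | None = None
) -> tuple[float, float]:
    """Mass interval masked after picking a peak whose apex sits at ``apex_mass``.

    The interval covers the modeled averagine envelope around the apex
    (isotopologues down to 0.5% of the envelope maximum) padded by the mask
    half-width on both sides, so that residual isotope peaks of an already
    picked proteoform cannot be re-picked as new features.
    """
    hw = default_mask_halfwidth(apex_mass) if mask_halfwidth is None else mask_halfwidth
    k_apex = most_abundant_offset(apex_mass)
    mono = apex_mass - k_apex * ISOTOPE_SPACING
    k_lo, k_hi = envelope_support(apex_mass, frac=0.005)
    lo = mono + (k_lo - 0.5) * ISOTOPE_SPACING - hw
    hi = mono + (k_hi + 0.5) * ISOTOPE_SPACING + hw
    return lo, hi


def _parabolic_apex(grid: np.ndarray, density: np.ndarray, i: int) -> float:
    if 0 < i < grid.size - 1:
        y0, y1, y2 = density[i - 1], density[i], density[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                return float(grid[i] + delta * (grid[1] - grid[0]))
    return float(grid[i])


def _members_in_windows(
    sorted_masses: np.ndarray, windows: np.ndarray, ppm_tol: float
) -> np.ndarray:
    """Indices (into the sorted ion-mass array) falling within ±ppm of any window center."""
    hits = []
    for w in windows:
        tol = ppm_tol * 1e-6 * w
        a = np.searchsorted(sorted_masses, w - tol, side="left")
        b = np.searchsorted(sorted_masses, w + tol, side="right")
        if b > a:
            hits.append(np.arange(a, b))
    if not hits:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(hits))


def _characterize_peak(
    apex: float,
    sorted_masses: np.ndarray,
    ppm_tol: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Monoisotopic mass, major isotope indices and masses under an apex.

    The apex sits on some isotopologue of the comb.  Its index is chosen so
    that the resulting monoisotopic mass is consistent with the ion-mass
    centroid of the envelope minus the averagine mean isotope offset; the
    centroid picks the integer index, the apex fixes the comb phase.
    """
    dist = isotope_distribution(apex)
    k_apex0 = int(np.argmax(dist))
    mono0 = apex - k_apex0 * ISOTOPE_SPACING
    k_lo, k_hi = envelope_support(apex, frac=0.001)
    lo = mono0 + (k_lo - 0.5) * ISOTOPE_SPACING
    hi = mono0 + (k_hi + 0.5) * ISOTOPE_SPACING
    a = np.searchsorted(sorted_masses, lo, side="left")
    b = np.searchsorted(sorted_masses, hi, side="right")
    if b > a:
        centroid = float(sorted_masses[a:b].mean())
        mono_est = centroid - mean_offset(apex) * ISOTOPE_SPACING
        k_apex = int(np.rint((apex - mono_est) / ISOTOPE_SPACING))
        k_apex = max(0, k_apex)
    else:
        k_apex = k_apex0
    mono = apex - k_apex * ISOTOPE_SPACING
    ks = major_isotope_indices(max(mono, 1.0))
    iso_masses = mono + ks * ISOTOPE_SPACING
    return mono, ks, iso_masses


def pick_features(
    spectrum: MassSpectrumEstimate,
    ions: pd.DataFrame,
    rel_abundance_threshold: float = 0.01,
    mask_halfwidth: float | None = None,
    ppm_tol: float = 10.0,
    max_features: int = 1000,
    min_ion_count: int = 1,
) -> list[ProteoformFeature]:
    """Iteratively pick proteoform features from the mass-domain density.

    Picking stops when the remaining global maximum falls below
    ``rel_abundance_threshold`` times the first maximum.  Member ions are
    those within ±``ppm_tol`` of any of the feature's major isotope masses;
    ``relative_abundance`` is each feature's ion count divided by the largest
    feature ion count.  Peaks attracting fewer than ``min_ion_count`` member
    ions (noise coincidences) are masked but not reported.
    """
    if not 0 < rel_abundance_threshold <= 1:
        raise InvalidInputError("rel_abundance_threshold must be in (0, 1]")
    mass = ions["neutral_mass"].to_numpy(dtype=float)
    ok = np.isfinite(mass)
    order = np.argsort(mass[ok], kind="mergesort")
    sorted_masses = mass[ok][order]
    sorted_ids = ions.loc[ok, "ion_id"].to_numpy()[order]

    work = spectrum.density.copy()
    grid = spectrum.mass_grid
    first_max = work.max()
    if first_max <= 0:
        return []
    cutoff = rel_abundance_threshold * first_max

    feats: list[ProteoformFeature] = []
    while len(feats) < max_features:
        i = int(np.argmax(work))
        if work[i] < cutoff or work[i] <= 0:
            break
        apex = _parabolic_apex(grid, work, i)
        mono, ks, iso_masses = _characterize_peak(apex, sorted_masses, ppm_tol)
        members = _members_in_windows(sorted_masses, iso_masses, ppm_tol)
        if members.size:
            # Refine the comb phase from the member ions' exact masses: the
            # KDE apex is quantized to the grid, the ion masses are not.
            mm = sorted_masses[members]
            k_of = np.rint((mm - mono) / ISOTOPE_SPACING)
            mono = float(np.mean(mm - k_of * ISOTOPE_SPACING))
            iso_masses = mono + ks * ISOTOPE_SPACING
            members = _members_in_windows(sorted_masses, iso_masses, ppm_tol)
        lo, hi = envelope_mask_bounds(apex, mask_halfwidth)
        hw = default_mask_halfwidth(apex) if mask_halfwidth is None else mask_halfwidth
        lo = min(lo, apex - hw)
        hi = max(hi, apex + hw)
        work[(grid >= lo) & (grid <= hi)] = 0.0
        if members.size >= min_ion_count:
            feats.append(
                ProteoformFeature(
                    feature_id=f"f{len(feats):04d}",
                    monoisotopic_mass=mono,
                    isotope_masses=iso_masses,
                    isotope_indices=ks,
                    ion_count=int(members.size),
                    member_ion_ids=sorted_ids[members],
                    apex_mass=apex,
                )
            )

    if feats:
        top = max(f.ion_count for f in feats)
        for f in feats:
            f.relative_abundance = f.ion_count / top
            f.isotope_fit_score = isotope_fit_score(f, ions, ppm_tol=ppm_tol)
    return feats


def isotope_fit_score(
    feature: ProteoformFeature, ions: pd.DataFrame, ppm_tol: float = 10.0
) -> float:
    """Cosine similarity between observed and averagine isotope intensities.

    A simplified envelope-fit check in the spirit of THRASH-style isotope
    confirmation: the per-isotope member-ion counts of the feature are
    compared against the theoretical averagine intensities at the feature
    mass.  Deterministic; returns a value in [0, 1].
    """
    mass = ions["neutral_mass"].to_numpy(dtype=float)
    ok = np.isfinite(mass)
    sorted_masses = np.sort(mass[ok], kind="mergesort")
    observed = np.empty(feature.isotope_masses.size)
    for j, w in enumerate(feature.isotope_masses):
        tol = ppm_tol * 1e-6 * w
        a = np.searchsorted(sorted_masses, w - tol, side="left")
        b = np.searchsorted(sorted_masses, w + tol, side="right")
        observed[j] = b - a
    if observed.sum() == 0:
        raise InvalidInputError(f"{feature.feature_id}: feature has no member ions")
    dist = isotope_distribution(max(feature.monoisotopic_mass, 1.0))
    theory = np.array(
        [dist[k] if 0 <= k < dist.size else 0.0 for k in feature.isotope_indices]
    )
    if theory.sum() == 0 or np.linalg.norm(theory) == 0:
        return 0.0
    cos = float(
        observed @ theory / (np.linalg.norm(observed) * np.linalg.norm(theory))
    )
    return float(np.clip(cos, 0.0, 1.0))


FEATURE_COLUMNS = [
    "feature_id",
    "monoisotopic_mass",
    "ion_count",
    "relative_abundance",
    "isotope_fit_score",
    "isotope_masses",
    "isotope_indices",
]


def features_to_table(features: list[ProteoformFeature]) -> pd.DataFrame:
    """Serialize features to a flat table (isotope lists are ';'-joined)."""
    rows = [
        {
            "feature_id": f.feature_id,
            "monoisotopic_mass": f.monoisotopic_mass,
            "ion_count": f.ion_count,
            "relative_abundance": f.relative_abundance,
            "isotope_fit_score": f.isotope_fit_score,
            "isotope_masses": ";".join(f"{m:.6f}" for m in f.isotope_masses),
            "isotope_indices": ";".join(str(int(k)) for k in f.isotope_indices),
        }
        for f in features
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def features_from_table(table: pd.DataFrame) -> list[ProteoformFeature]:
    feats = []
    for row in table.itertuples(index=False):
        feats.append(
            ProteoformFeature(
                feature_id=row.feature_id,
                monoisotopic_mass=float(row.monoisotopic_mass),
                isotope_masses=np.array([float(x) for x in str(row.isotope_masses).split(";")]),
                isotope_indices=np.array([int(x) for x in str(row.isotope_indices).split(";")]),
                ion_count=int(row.ion_count),
                member_ion_ids=np.array([], dtype=object),
                relative_abundance=float(row.relative_abundance),
                isotope_fit_score=float(row.isotope_fit_score),
            )
        )
    return feats


def write_feature_table(features: list[ProteoformFeature], path) -> None:
    features_to_table(features).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[ProteoformFeature]:
    return features_from_table(pd.read_csv(path, sep="\t"))


def write_spectrum_tsv(spectrum: MassSpectrumEstimate, path) -> None:
    """Two-column TSV (mass, density) with the mass convention in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# mass_convention={MASS_CONVENTION}\n")
        fh.write(f"# bandwidth_da={spectrum.bandwidth:.6g}\tn_ions={spectrum.n_ions}\n")
        fh.write("mass\tdensity\n")
        for m, d in zip(spectrum.mass_grid, spectrum.density):
            fh.write(f"{m:.6f}\t{d:.8g}\n")
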