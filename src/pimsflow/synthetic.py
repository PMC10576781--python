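"""Ground-truth-labeled synthetic single-ion data.

The generator emulates denaturing-electrospray individual-ion line scans:
each proteoform contributes ions whose per-scan counts are Poisson with mean
proportional to a spatial abundance profile, whose charges follow a rounded
Gaussian charge envelope, whose isotopologue indices follow the averagine
envelope at the proteoform mass, and whose charge-readout slopes carry
multiplicative Gaussian noise around ``calib_slope * z``.  Background ions
are uniform in m/z and in scan index with uniformly distributed slopes.

Every dataset carries per-ion truth labels so downstream stages (charge
assignment, feature picking, target selection, allocation, LFQ, imaging) can
be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ISOTOPE_SPACING
from .errors import InvalidInputError
from .geometry import ScanGeometry
from .ions import ION_COLUMNS, TRUTH_COLUMNS, mz_from_neutral_mass
from .isotopes import isotope_distribution


@dataclass
class ProteoformSpec:
    """Ground-truth description of one simulated proteoform.

    ``spatial_profile`` holds one nonnegative weight per scan index (one line)
    or a ``(n_lines, scans_per_line)`` array for multi-line images; it is
    normalized internally, so only relative values matter.  ``class_effect``
    optionally maps a sample-class label to a multiplicative abundance factor
    for two-class quantitation simulations.
    """

    id: str
    monoisotopic_mass: float
    total_ion_budget: int
    charge_mu: float
    charge_sigma: float
    spatial_profile: np.ndarray
    class_effect: dict | None = None

    def __post_init__(self):
        self.spatial_profile = np.asarray(self.spatial_profile, dtype=float)
        if self.monoisotopic_mass <= 0:
            raise InvalidInputError(f"{self.id}: monoisotopic_mass must be > 0")
        if self.total_ion_budget < 0:
            raise InvalidInputError(f"{self.id}: total_ion_budget must be >= 0")
        if (self.spatial_profile < 0).any():
            raise InvalidInputError(f"{self.id}: spatial_profile must be nonnegative")
        total = self.spatial_profile.sum()
        if self.total_ion_budget > 0 and not (np.isfinite(total) and total > 0):
            raise InvalidInputError(
                f"{self.id}: spatial_profile must sum to a finite positive value"
            )


@dataclass
class SyntheticDataset:
    """An ion table, its per-ion truth labels, and the scan geometry."""

    ions: pd.DataFrame
    truth: pd.DataFrame
    geometry: ScanGeometry


def _profile_matrix(spec: ProteoformSpec, geometry: ScanGeometry) -> np.ndarray:
    prof = spec.spatial_profile
    if prof.ndim == 1:
        if prof.size != geometry.scans_per_line:
            raise InvalidInputError(
                f"{spec.id}: profile length {prof.size} != scans_per_line"
            )
        prof = np.tile(prof, (geometry.n_lines, 1))
    elif prof.shape != (geometry.n_lines, geometry.scans_per_line):
        raise InvalidInputError(f"{spec.id}: profile shape {prof.shape} mismatch")
    return prof


def simulate_line_scan(
    specs: list[ProteoformSpec],
    geometry: ScanGeometry,
    noise_ion_rate: float = 1.0,
    calib_slope: float = 1.0,
    slope_noise_cv: float = 0.005,
    seed: int = 0,
    noise_mz_range: tuple[float, float] = (400.0, 2500.0),
    noise_charge_range: tuple[float, float] = (0.5, 40.0),
) -> SyntheticDataset:
    """Simulate a single-ion line-scan (or multi-line image) acquisition.

    Fully reproducible for a given ``seed``.  Noise ions carry
    ``source_id = "noise"`` and ``true_charge = 0`` in the truth table.
    """
    if calib_slope <= 0:
        raise InvalidInputError("calib_slope must be positive")
    if noise_ion_rate < 0 or slope_noise_cv < 0:
        raise InvalidInputError("rates and noise levels must be nonnegative")
    rng = np.random.default_rng(seed)

    mzs, slopes, scans, lines = [], [], [], []
    src, t_charge, t_iso = [], [], []

    for spec in specs:
        prof = _profile_matrix(spec, geometry)
        lam = spec.total_ion_budget * prof / prof.sum() if spec.total_ion_budget else 0 * prof
        counts = rng.poisson(lam)
        n = int(counts.sum())
        if n == 0:
            continue
        line_idx, scan_idx = np.nonzero(counts)
        reps = counts[line_idx, scan_idx]
        lines.append(np.repeat(line_idx, reps))
        scans.append(np.repeat(scan_idx, reps))
        z = np.maximum(1, np.rint(rng.normal(spec.charge_mu, spec.charge_sigma, n))).astype(int)
        dist = isotope_distribution(spec.monoisotopic_mass)
        iso = rng.choice(dist.size, size=n, p=dist / dist.sum())
        mass = spec.monoisotopic_mass + iso * ISOTOPE_SPACING
        mzs.append(mz_from_neutral_mass(mass, z))
        slopes.append(calib_slope * z * (1.0 + rng.normal(0.0, slope_noise_cv, n)))
        src.append(np.full(n, spec.id, dtype=object))
        t_charge.append(z)
        t_iso.append(iso)

    n_scans = geometry.n_lines * geometry.scans_per_line
    n_noise = int(rng.poisson(noise_ion_rate * n_scans))
    if n_noise:
        flat = rng.integers(0, n_scans, n_noise)
        lines.append(flat // geometry.scans_per_line)
        scans.append(flat % geometry.scans_per_line)
        mzs.append(rng.uniform(*noise_mz_range, n_noise))
        slopes.append(calib_slope * rng.uniform(*noise_charge_range, n_noise))
        src.append(np.full(n_noise, "noise", dtype=object))
        t_charge.append(np.zeros(n_noise, dtype=int))
        t_iso.append(np.full(n_noise, -1))

    if mzs:
        ions = pd.DataFrame(
            {
                "mz": np.concatenate(mzs),
                "stori_slope": np.concatenate(slopes),
                "scan_index": np.concatenate(scans).astype(int),
                "line_index": np.concatenate(lines).astype(int),
                "source_id": np.concatenate(src),
                "true_charge": np.concatenate(t_charge).astype(int),
                "true_isotope": np.concatenate(t_iso).astype(int),
            }
        )
        ions = ions.sort_values(
            ["line_index", "scan_index", "mz"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        ions = pd.DataFrame(
            columns=["mz", "stori_slope", "scan_index", "line_index",
                     "source_id", "true_charge", "true_isotope"]
        )
    ions.insert(0, "ion_id", [f"ion{i:07d}" for i in range(len(ions))])
    truth = ions[TRUTH_COLUMNS].copy()
    return SyntheticDataset(ions=ions[ION_COLUMNS].copy(), truth=truth, geometry=geometry)


def gaussian_profile(
    scans_per_line: int, center_frac: float, width_frac: float, baseline: float = 0.02
) -> np.ndarray:
    """Smooth single-bump spatial profile over one line (arbitrary units)."""
    x = np.arange(scans_per_line)
    c = center_frac * scans_per_line
    w = max(1.0, width_frac * scans_per_line)
    return baseline + np.exp(-0.5 * ((x - c) / w) ** 2)


def survey_specs(
    n_features: int = 113,
    seed: int = 0,
    scans_per_line: int = 2000,
    max_budget: int = 6000,
    min_rel_abundance: float = 0.015,
    mass_ranges: tuple = ((4_000.0, 17_000.0, 0.78), (17_000.0, 50_000.0, 0.22)),
    min_separation: float = 0.004,
) -> list[ProteoformSpec]:
    """Proteoform roster emulating a tissue survey line scan.

    Masses are drawn log-uniformly within low/high mass strata (most
    proteoforms below 17 kDa, a minority up to 50 kDa, mirroring typical
    denatured tissue surveys), with a minimum relative mass separation that
    keeps isotope envelopes from interleaving.  Ion budgets are log-uniform
    between ``min_rel_abundance`` and 1 times ``max_budget``; charge
    envelopes center near mass/900 as seen for denatured electrosprayed
    proteins.
    """
    rng = np.random.default_rng(seed)
    masses: list[float] = []
    counts = [int(round(f * n_features)) for *_, f in mass_ranges]
    counts[0] += n_features - sum(counts)
    for (lo, hi, _), k in zip(mass_ranges, counts):
        drawn = attempts = 0
        while drawn < k:
            attempts += 1
            if attempts > 100_000:
                raise InvalidInputError(
                    "cannot place that many separated masses in the range"
                )
            m = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if all(abs(m - other) > min_separation * m for other in masses):
                masses.append(m)
                drawn += 1
    specs = []
    for i, m in enumerate(sorted(masses)):
        rel = np.exp(rng.uniform(np.log(min_rel_abundance), 0.0))
        mu = float(np.clip(m / 900.0, 5.0, 60.0))
        specs.append(
            ProteoformSpec(
                id=f"pf{i:03d}",
                monoisotopic_mass=m,
                total_ion_budget=int(round(rel * max_budget)),
                charge_mu=mu,
                charge_sigma=max(1.5, 0.1 * mu),
                spatial_profile=gaussian_profile(
                    scans_per_line, rng.uniform(0.1, 0.9), rng.uniform(0.05, 0.2)
                ),
            )
        )
    return specs


@dataclass
class TwoClassRegions:
    """Simulated per-region proteoform counts for a two-class LFQ design."""

    counts: pd.DataFrame  # regions x proteoforms
    classes: np.ndarray  # per-region class label
    is_differential: np.ndarray  # per-proteoform truth flag
    true_log2fc: np.ndarray = field(default=None)  # signed effect per proteoform


def simulate_two_class_regions(
    n_proteoforms: int,
    n_regions_per_class: int | tuple[int, int],
    frac_differential: float,
    effect_log2fc: float,
    dispersion: float = 0.1,
    seed: int = 0,
    class_labels: tuple[str, str] = ("tumor", "stroma"),
    base_mean_log_mu: float = np.log(3.0),
    base_mean_log_sigma: float = 1.0,
) -> TwoClassRegions:
    """Simulate negative-binomial region counts with a differential subset.

    Exactly ``round(frac_differential * n_proteoforms)`` proteoforms differ
    between classes by ``effect_log2fc`` (random sign, split symmetrically in
    log space).  ``dispersion`` is the gamma-Poisson overdispersion; zero
    gives Poisson counts.
    """
    if not 0 <= frac_differential <= 1:
        raise InvalidInputError("frac_differential must be in [0, 1]")
    if dispersion < 0:
        raise InvalidInputError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    if isinstance(n_regions_per_class, int):
        n_a = n_b = n_regions_per_class
    else:
        n_a, n_b = n_regions_per_class

    base = rng.lognormal(base_mean_log_mu, base_mean_log_sigma, n_proteoforms)
    n_diff = int(round(frac_differential * n_proteoforms))
    diff_idx = rng.permutation(n_proteoforms)[:n_diff]
    is_diff = np.zeros(n_proteoforms, dtype=bool)
    is_diff[diff_idx] = True
    sign = np.zeros(n_proteoforms)
    sign[diff_idx] = rng.choice([-1.0, 1.0], n_diff)
    true_fc = sign * effect_log2fc

    mean_a = base * 2.0 ** (-true_fc / 2.0)
    mean_b = base * 2.0 ** (true_fc / 2.0)

    def draw(mu, n_regions):
        lam = np.broadcast_to(mu, (n_regions, n_proteoforms))
        if dispersion > 1e-12:
            lam = rng.gamma(1.0 / dispersion, dispersion * lam)
        return rng.poisson(lam)

    counts = np.vstack([draw(mean_a, n_a), draw(mean_b, n_b)])
    classes = np.array([class_labels[0]] * n_a + [class_labels[1]] * n_b)
    df = pd.DataFrame(
        counts,
        index=[f"region{i:03d}" for i in range(n_a + n_b)],
        columns=[f"pf{j:04d}" for j in range(n_proteoforms)],
    )
    return TwoClassRegions(counts=df, classes=classes, is_differential=is_diff, true_log2fc=true_fc)
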