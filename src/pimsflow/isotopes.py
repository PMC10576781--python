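"""Averagine isotope model.

Protein isotope envelopes are modeled with the averagine approximation: the
elemental composition of a protein of a given mass is taken to be a scaled
version of the average amino-acid residue, and the aggregated isotopologue
distribution follows from convolving the per-element isotope distributions.
Isotopologue centroids are placed on a uniform comb with
:data:`~pimsflow.constants.ISOTOPE_SPACING` Da spacing above the
monoisotopic mass, which is adequate at the 10 ppm tolerances used
downstream.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from pyteomics import mass as _pmass

from .constants import (
    AVERAGINE_MONOMER,
    AVERAGINE_MONOMER_MASS,
    ISOTOPE_SPACING,
)
from .errors import InvalidInputError

_H_MONO = _pmass.nist_mass["H"][1][0]

_TRIM = 1e-12


def _single_atom_distribution(element: str) -> np.ndarray:
    """Abundance vector of one atom indexed by neutron-number offset."""
    entries = {k: v for k, v in _pmass.nist_mass[element].items() if k != 0}
    numbers = sorted(k for k, (_, a) in entries.items() if a > 0)
    base = numbers[0]
    out = np.zeros(numbers[-1] - base + 1)
    for k in numbers:
        out[k - base] = entries[k][1]
    return out


def _trim(vec: np.ndarray) -> np.ndarray:
    keep = np.nonzero(vec > _TRIM * vec.max())[0]
    return vec[: keep[-1] + 1]


def _power_convolve(base: np.ndarray, n: int) -> np.ndarray:
    """Distribution of ``n`` i.i.d. atoms via binary-exponentiation convolution."""
    out = np.array([1.0])
    b = base.copy()
    while n:
        if n & 1:
            out = _trim(np.convolve(out, b))
        n >>= 1
        if n:
            b = _trim(np.convolve(b, b))
    return out


def averagine_composition(monoisotopic_mass: float) -> dict[str, int]:
    """Integer elemental composition of an averagine pseudo-protein.

    C, N, O and S counts are the scaled monomer counts rounded to integers;
    hydrogens are then adjusted so the monoisotopic mass of the composition
    matches the requested mass as closely as whole atoms allow.
    """
    if monoisotopic_mass <= 0:
        raise InvalidInputError("monoisotopic_mass must be positive")
    n_units = monoisotopic_mass / AVERAGINE_MONOMER_MASS
    comp = {
        el: int(round(AVERAGINE_MONOMER[el] * n_units))
        for el in ("C", "N", "O", "S")
    }
    mono_no_h = sum(_pmass.nist_mass[el][0][0] * n for el, n in comp.items())
    comp["H"] = max(0, int(round((monoisotopic_mass - mono_no_h) / _H_MONO)))
    return comp


@lru_cache(maxsize=512)
def _distribution_cached(key: float) -> np.ndarray:
    comp = averagine_composition(key)
    dist = np.array([1.0])
    for el, n in comp.items():
        if n > 0:
            dist = _trim(np.convolve(dist, _power_convolve(_single_atom_distribution(el), n)))
    return dist / dist.max()


def isotope_distribution(monoisotopic_mass: float) -> np.ndarray:
    """Relative isotopologue intensities (max = 1) indexed from the monoisotope.

    Compositions are cached on a 25 Da mass grid; the envelope shape varies
    negligibly over that scale.
    """
    if monoisotopic_mass <= 0:
        raise InvalidInputError("monoisotopic_mass must be positive")
    key = max(25.0, round(monoisotopic_mass / 25.0) * 25.0)
    return _distribution_cached(key)


def averagine_isotopes(
    monoisotopic_mass: float, n_isotopes: int
) -> list[tuple[float, float]]:
    """First ``n_isotopes`` isotopologues of an averagine protein.

    Returns ``(mass, relative_intensity)`` pairs with strictly increasing
    masses spaced by :data:`~pimsflow.constants.ISOTOPE_SPACING` and
    intensities normalized to a maximum of 1 over the returned entries.
    """
    if monoisotopic_mass <= 0:
        raise InvalidInputError("monoisotopic_mass must be positive")
    if not 1 <= n_isotopes <= 30:
        raise InvalidInputError("n_isotopes must be in [1, 30]")
    dist = isotope_distribution(monoisotopic_mass)
    intens = np.zeros(n_isotopes)
    k = min(n_isotopes, dist.size)
    intens[:k] = dist[:k]
    intens = intens / intens.max()
    return [
        (monoisotopic_mass + i * ISOTOPE_SPACING, float(intens[i]))
        for i in range(n_isotopes)
    ]


def most_abundant_offset(monoisotopic_mass: float) -> int:
    """Isotope index (0 = monoisotopic) of the most intense isotopologue."""
    return int(np.argmax(isotope_distribution(monoisotopic_mass)))


def mean_offset(monoisotopic_mass: float) -> float:
    """Intensity-weighted mean isotope index of the envelope."""
    dist = isotope_distribution(monoisotopic_mass)
    ks = np.arange(dist.size)
    return float((ks * dist).sum() / dist.sum())


def envelope_sigma(monoisotopic_mass: float) -> float:
    """Intensity-weighted standard deviation of the isotope index."""
    dist = isotope_distribution(monoisotopic_mass)
    ks = np.arange(dist.size)
    mu = (ks * dist).sum() / dist.sum()
    return float(np.sqrt(((ks - mu) ** 2 * dist).sum() / dist.sum()))


def envelope_support(monoisotopic_mass: float, frac: float = 0.005) -> tuple[int, int]:
    """Inclusive isotope-index range where intensity is >= ``frac`` of the max."""
    dist = isotope_distribution(monoisotopic_mass)
    idx = np.nonzero(dist >= frac * dist.max())[0]
    return int(idx[0]), int(idx[-1])


def n_major_isotopes(monoisotopic_mass: float) -> int:
    """Number of major isotopes carried per feature.

    Five below 10 kDa, scaling linearly to eleven at and above 40 kDa — small
    proteins concentrate their signal in a few isotopologues while large ones
    spread it over many.
    """
    frac = np.clip((monoisotopic_mass - 10_000.0) / 30_000.0, 0.0, 1.0)
    return int(round(5 + 6 * frac))


def major_isotope_indices(monoisotopic_mass: float, n_iso: int | None = None) -> np.ndarray:
    """Contiguous block of ``n_iso`` isotope indices maximizing summed intensity."""
    if n_iso is None:
        n_iso = n_major_isotopes(monoisotopic_mass)
    dist = isotope_distribution(monoisotopic_mass)
    if dist.size <= n_iso:
        return np.arange(n_iso)
    sums = np.convolve(dist, np.ones(n_iso), mode="valid")
    start = int(np.argmax(sums))
    return np.arange(start, start + n_iso)
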