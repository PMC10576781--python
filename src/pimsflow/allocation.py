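"""Spatial bin allocation: one fragmentation slot per target, near its maximum.

The fragmentation line is divided into equally sized bins and each target
must be fragmented in a bin where it is abundant.  Allocation proceeds in
rounds: every unassigned target claims its best remaining bin (highest
binned ion count; ties to the lower bin index); bins claimed by a single
target are granted immediately; contested bins go to the claimant with the
lowest total ion count over the whole line — the weakest target is the one
that can least afford a sub-optimal location — and losers return to the pool
to look for secondary bin options in the next round.  The process repeats
until every target holds a unique bin.

A multi-bin variant serves individual-ion MS² of large targets, which needs
far more scans: after the first pass, remaining bins are granted one per
target in ascending order of total abundance, up to two bins per target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigurationError, InvalidInputError, NonConvergenceError
from .geometry import ScanGeometry


@dataclass
class SpatialProfile:
    """Binned ion counts of one target along the fragmentation line."""

    feature_id: str
    counts_per_bin: np.ndarray
    bin_edges: np.ndarray
    mass: float = np.nan

    @property
    def total(self) -> int:
        return int(self.counts_per_bin.sum())


@dataclass
class BinAssignment:
    """Result of an allocation run."""

    mapping: dict[int, str]  # bin index -> feature id
    bin_edges: np.ndarray
    iterations: int
    mode: str  # "single-bin" | "multi-bin"
    unassigned_bins: set[int] = field(default_factory=set)

    def bins_for(self, feature_id: str) -> list[int]:
        return sorted(b for b, f in self.mapping.items() if f == feature_id)


def bin_profiles(
    ions: pd.DataFrame,
    assignments: pd.DataFrame,
    geometry: ScanGeometry,
    n_bins: int,
    feature_ids: list[str] | None = None,
    feature_masses: dict[str, float] | None = None,
) -> list[SpatialProfile]:
    """Low-resolution spatial profiles: per-target ion counts per bin.

    Scan indices map to along-track coordinates through the probe rate and
    acquisition rate; the line region [0, line_length) is divided into
    ``n_bins`` equal bins and each target's assigned-ion counts are summed
    within bins, conserving totals.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    merged = ions.merge(assignments, on="ion_id")
    merged = merged[merged["feature_id"].notna()]
    if feature_ids is None:
        feature_ids = sorted(merged["feature_id"].unique())
    edges = np.linspace(0.0, geometry.line_length, n_bins + 1)
    coord = geometry.scan_coordinate(merged["scan_index"].to_numpy())
    bin_idx = np.clip(
        (coord / geometry.line_length * n_bins).astype(int), 0, n_bins - 1
    )
    profiles = []
    for fid in feature_ids:
        sel = (merged["feature_id"] == fid).to_numpy()
        counts = np.bincount(bin_idx[sel], minlength=n_bins)
        profiles.append(
            SpatialProfile(
                feature_id=fid,
                counts_per_bin=counts,
                bin_edges=edges,
                mass=(feature_masses or {}).get(fid, np.nan),
            )
        )
    return profiles


def _contest_key(p: SpatialProfile, bin_index: int, metric: str):
    strength = p.total if metric == "total" else int(p.counts_per_bin[bin_index])
    mass = p.mass if np.isfinite(p.mass) else np.inf
    return (strength, mass, p.feature_id)


def allocate(
    profiles: list[SpatialProfile],
    max_iterations: int = 50,
    contest_metric: str = "total",
) -> BinAssignment:
    """Assign each target a unique bin by iterative claim-and-contest rounds.

    ``contest_metric`` selects how the winner of a contested bin is chosen:
    ``"total"`` (default) grants it to the claimant with the lowest total ion
    count over the line, ``"bin"`` to the claimant with the lowest count
    inside the contested bin.  All ties break deterministically (lower bin
    index for bins; lower mass, then feature id, for targets).
    """
    if contest_metric not in ("total", "bin"):
        raise InvalidInputError("contest_metric must be 'total' or 'bin'")
    if not profiles:
        return BinAssignment({}, np.array([0.0]), 0, "single-bin")
    n_bins = profiles[0].counts_per_bin.size
    if any(p.counts_per_bin.size != n_bins for p in profiles):
        raise InvalidInputError("profiles must share one binning")
    if n_bins < len(profiles):
        raise InfeasibleConfigurationError(
            f"{len(profiles)} targets cannot each get one of {n_bins} bins"
        )

    by_id = {p.feature_id: p for p in profiles}
    pool = [p.feature_id for p in profiles]
    mapping: dict[int, str] = {}
    iterations = 0
    while pool:
        if iterations >= max_iterations:
            partial = BinAssignment(
                mapping=mapping,
                bin_edges=profiles[0].bin_edges,
                iterations=iterations,
                mode="single-bin",
                unassigned_bins=set(range(n_bins)) - set(mapping),
            )
            raise NonConvergenceError(
                f"allocation did not converge in {max_iterations} iterations",
                partial=partial,
            )
        iterations += 1
        claims: dict[int, list[str]] = {}
        for fid in pool:
            counts = by_id[fid].counts_per_bin.astype(float).copy()
            counts[list(mapping)] = -np.inf
            best = int(np.argmax(counts))
            claims.setdefault(best, []).append(fid)
        for b in sorted(claims):
            contenders = claims[b]
            winner = min(
                contenders, key=lambda fid: _contest_key(by_id[fid], b, contest_metric)
            )
            mapping[b] = winner
        pool = [fid for fid in pool if fid not in mapping.values()]

    return BinAssignment(
        mapping=mapping,
        bin_edges=profiles[0].bin_edges,
        iterations=iterations,
        mode="single-bin",
        unassigned_bins=set(range(n_bins)) - set(mapping),
    )


def allocate_multibin(
    profiles: list[SpatialProfile],
    bin_size: float | None = None,
    max_bins_per_target: int = 2,
    prioritize_low_abundance: bool = True,
    max_iterations: int = 50,
    contest_metric: str = "total",
) -> BinAssignment:
    """Two-pass allocation granting up to two bins per target.

    The first pass is identical to :func:`allocate`.  The second pass walks
    the targets in ascending order of total abundance (descending when
    ``prioritize_low_abundance`` is False) and grants each one extra bin —
    its best-remaining bin — while unassigned bins last.  ``bin_size`` is
    validated against the profiles' bin edges when given (the line should be
    cut into 150–300 µm bins for this mode).
    """
    if profiles and bin_size is not None:
        width = float(np.diff(profiles[0].bin_edges).mean())
        if not np.isclose(width, bin_size, rtol=0.01):
            raise InvalidInputError(
                f"profiles are binned at {width:.1f} µm, expected {bin_size:.1f}"
            )
    first = allocate(profiles, max_iterations=max_iterations, contest_metric=contest_metric)
    mapping = dict(first.mapping)
    n_bins = profiles[0].counts_per_bin.size if profiles else 0
    by_id = {p.feature_id: p for p in profiles}

    def order_key(p: SpatialProfile):
        mass = p.mass if np.isfinite(p.mass) else np.inf
        return (p.total, mass, p.feature_id)

    ranked = sorted(profiles, key=order_key, reverse=not prioritize_low_abundance)
    extra_rounds = 0
    for p in ranked:
        if len(mapping) >= n_bins:
            break
        held = sum(1 for f in mapping.values() if f == p.feature_id)
        if held >= max_bins_per_target:
            continue
        counts = p.counts_per_bin.astype(float).copy()
        counts[list(mapping)] = -np.inf
        best = int(np.argmax(counts))
        mapping[best] = p.feature_id
        extra_rounds = 1
    return BinAssignment(
        mapping=mapping,
        bin_edges=first.bin_edges,
        iterations=first.iterations + extra_rounds,
        mode="multi-bin",
        unassigned_bins=set(range(n_bins)) - set(mapping),
    )


def n_bins_for_line(line_length: float, bin_size: float) -> int:
    """Number of equal bins of approximately ``bin_size`` µm covering the line."""
    if bin_size <= 0 or line_length <= 0:
        raise InvalidInputError("line_length and bin_size must be positive")
    return max(1, int(round(line_length / bin_size)))
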