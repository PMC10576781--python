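"""Precursor target selection by in-silico purification.

Every charge-assigned ion is attributed, where possible, to the picked
feature whose nearest isotope mass lies within an inclusion half-width of the
ion's neutral mass.  With those assignments the m/z spectrum of each target
can be reconstructed purified in silico, candidate isolation windows are
enumerated on an m/z grid, and each window is scored by the product of
target-ion abundance and window purity (the fraction of ions in the window
that belong to the intended target), with the co-isolating species recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .spectrum import ProteoformFeature

UNASSIGNED = None


def assign_ions(
    ions: pd.DataFrame,
    features: list[ProteoformFeature],
    inclusion_halfwidth: float = 2.0,
) -> pd.DataFrame:
    """Assign each ion to at most one feature by nearest isotope mass.

    An ion is assigned to the feature whose closest isotope mass is nearest
    to the ion's neutral mass and within ``±inclusion_halfwidth`` Da; exact
    distance ties go to the feature with the lower monoisotopic mass.  Ions
    without an assigned charge stay unassigned.  Returns a DataFrame with
    columns ``ion_id, feature_id`` (``feature_id`` is NA when unassigned).
    """
    if not features:
        raise InvalidInputError("features must be non-empty")
    if inclusion_halfwidth <= 0:
        raise InvalidInputError("inclusion_halfwidth must be positive")

    iso_mass = np.concatenate([f.isotope_masses for f in features])
    iso_fid = np.concatenate(
        [np.full(f.isotope_masses.size, i) for i, f in enumerate(features)]
    )
    feat_mass = np.array([f.monoisotopic_mass for f in features])
    order = np.argsort(iso_mass, kind="mergesort")
    iso_mass = iso_mass[order]
    iso_fid = iso_fid[order]

    mass = ions["neutral_mass"].to_numpy(dtype=float) if "neutral_mass" in ions else np.full(len(ions), np.nan)
    fid_out = np.full(len(ions), -1, dtype=int)
    ok = np.isfinite(mass)
    m = mass[ok]

    j = np.searchsorted(iso_mass, m)
    left = np.clip(j - 1, 0, iso_mass.size - 1)
    right = np.clip(j, 0, iso_mass.size - 1)
    d_left = np.abs(m - iso_mass[left])
    d_right = np.abs(m - iso_mass[right])
    best = np.where(d_right < d_left, right, left)
    d_best = np.minimum(d_left, d_right)

    chosen = np.where(d_best <= inclusion_halfwidth, iso_fid[best], -1)

    # Exact-distance ties (including duplicated isotope masses) need a scan
    # over every candidate at the minimal distance; rare, so done row-wise.
    ext_left = np.clip(left - 1, 0, iso_mass.size - 1)
    ext_right = np.clip(right + 1, 0, iso_mass.size - 1)
    tie = (
        (np.abs(d_left - d_right) < 1e-9)
        | (np.abs(np.abs(m - iso_mass[ext_left]) - d_best) < 1e-9)
        | (np.abs(np.abs(m - iso_mass[ext_right]) - d_best) < 1e-9)
    ) & (d_best <= inclusion_halfwidth)
    for idx in np.nonzero(tie)[0]:
        lo = np.searchsorted(iso_mass, m[idx] - d_best[idx] - 1e-9, side="left")
        hi = np.searchsorted(iso_mass, m[idx] + d_best[idx] + 1e-9, side="right")
        cands = np.unique(iso_fid[lo:hi])
        chosen[idx] = cands[np.argmin(feat_mass[cands])]

    fid_out[ok] = chosen
    feature_ids = np.array([f.feature_id for f in features] + [None], dtype=object)
    return pd.DataFrame(
        {"ion_id": ions["ion_id"].to_numpy(), "feature_id": feature_ids[fid_out]}
    )


def reconstruct_mz_profile(
    assignments: pd.DataFrame,
    ions: pd.DataFrame,
    feature_id: str,
    mz_bin: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned m/z histogram of one target's assigned ions.

    Returns ``(bin_edges, counts)`` with ``counts.sum()`` equal to the
    target's assigned-ion count.
    """
    if feature_id not in set(assignments["feature_id"].dropna()):
        raise KeyError(f"unknown feature_id: {feature_id}")
    merged = ions.merge(assignments, on="ion_id")
    mz = merged.loc[merged["feature_id"] == feature_id, "mz"].to_numpy()
    lo = np.floor(mz.min() / mz_bin) * mz_bin
    hi = np.ceil(mz.max() / mz_bin) * mz_bin + mz_bin
    edges = np.arange(lo, hi + mz_bin / 2, mz_bin)
    counts, _ = np.histogram(mz, bins=edges)
    return edges, counts


@dataclass
class IsolationWindow:
    """A scored candidate isolation window for one target."""

    target_feature_id: str
    center_mz: float
    width: float
    target_ion_count: int
    other_ion_count: int
    purity: float
    score: float
    coisolating: list[tuple[str, int]] = field(default_factory=list)


def score_windows(
    assignments: pd.DataFrame,
    ions: pd.DataFrame,
    feature_id: str,
    window_width: float = 4.0,
    center_grid_step: float | None = None,
    gamma: float = 1.0,
    top_k: int | None = 50,
) -> list[IsolationWindow]:
    """Rank candidate isolation windows for one target.

    Candidate centers are enumerated on a grid spanning the target's occupied
    m/z range; each half-open window ``[c - w/2, c + w/2)`` is scored as
    ``target_count * purity ** gamma`` and the list is returned sorted by
    score (ties: higher purity, then lower center).  Co-isolating features
    with at least one ion in the window are annotated, most abundant first;
    only the ``top_k`` best windows carry the annotation unless ``top_k`` is
    None, in which case every window does.
    """
    if window_width <= 0:
        raise InvalidInputError("window_width must be positive")
    step = window_width / 8.0 if center_grid_step is None else center_grid_step
    merged = ions[["ion_id", "mz"]].merge(assignments, on="ion_id")
    is_target = (merged["feature_id"] == feature_id).to_numpy()
    tgt_mz = np.sort(merged.loc[is_target, "mz"].to_numpy())
    if tgt_mz.size == 0:
        return []
    other = merged.loc[~is_target]
    other_mz = other["mz"].to_numpy()
    other_fid = other["feature_id"].to_numpy(dtype=object)
    oorder = np.argsort(other_mz, kind="mergesort")
    other_mz = other_mz[oorder]
    other_fid = other_fid[oorder]

    centers = np.arange(tgt_mz[0], tgt_mz[-1] + step / 2, step)
    half = window_width / 2.0
    t = np.searchsorted(tgt_mz, centers + half, side="left") - np.searchsorted(
        tgt_mz, centers - half, side="left"
    )
    o = np.searchsorted(other_mz, centers + half, side="left") - np.searchsorted(
        other_mz, centers - half, side="left"
    )
    total = t + o
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, t / np.maximum(total, 1), 0.0)
    score = t * purity**gamma

    order = np.lexsort((centers, -purity, -score))
    windows = []
    for rank, i in enumerate(order):
        annotate = top_k is None or rank < top_k
        cois: list[tuple[str, int]] = []
        if annotate and o[i] > 0:
            a = np.searchsorted(other_mz, centers[i] - half, side="left")
            b = np.searchsorted(other_mz, centers[i] + half, side="left")
            fids = other_fid[a:b]
            fids = fids[pd.notna(fids)]
            if fids.size:
                vals, cnts = np.unique(fids.astype(str), return_counts=True)
                corder = np.lexsort((vals, -cnts))
                cois = [(str(vals[k]), int(cnts[k])) for k in corder]
        windows.append(
            IsolationWindow(
                target_feature_id=feature_id,
                center_mz=float(centers[i]),
                width=window_width,
                target_ion_count=int(t[i]),
                other_ion_count=int(o[i]),
                purity=float(purity[i]),
                score=float(score[i]),
                coisolating=cois,
            )
        )
        if top_k is not None and rank + 1 >= top_k:
            break
    return windows


def select_targets(
    features: list[ProteoformFeature],
    assignments: pd.DataFrame,
    ions: pd.DataFrame,
    mass_range: tuple[float, float],
    rel_abundance_threshold: float = 0.01,
    window_width: float = 4.0,
    min_purity: float = 0.5,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """Pick the best isolation window per in-range, above-threshold feature.

    A feature is windowless (NA window columns) when its best window's purity
    falls below ``min_purity``.  Output rows are ordered by feature mass.
    """
    lo, hi = mass_range
    if not lo < hi:
        raise InvalidInputError("mass_range must satisfy lo < hi")
    rows = []
    for f in sorted(features, key=lambda f: f.monoisotopic_mass):
        if not (lo <= f.monoisotopic_mass <= hi):
            continue
        if f.relative_abundance < rel_abundance_threshold:
            continue
        wins = score_windows(
            assignments, ions, f.feature_id,
            window_width=window_width, gamma=gamma, top_k=1,
        )
        best = wins[0] if wins else None
        ok = best is not None and best.purity >= min_purity
        rows.append(
            {
                "feature_id": f.feature_id,
                "monoisotopic_mass": f.monoisotopic_mass,
                "ion_count": f.ion_count,
                "relative_abundance": f.relative_abundance,
                "center_mz": best.center_mz if ok else np.nan,
                "width": best.width if ok else np.nan,
                "purity": best.purity if ok else np.nan,
                "score": best.score if ok else np.nan,
                "coisolating": (
                    ";".join(f"{fid}:{n}" for fid, n in best.coisolating) if ok else ""
                ),
                "has_window": bool(ok),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "monoisotopic_mass", "ion_count", "relative_abundance",
            "center_mz", "width", "purity", "score", "coisolating", "has_window",
        ],
    )
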