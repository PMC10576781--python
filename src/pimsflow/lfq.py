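"""Region-of-interest label-free quantitation.

Adjacent MS scans (45–50 per region, ~80 µm of tissue) are binned into
sampled regions; per-region proteoform ion counts use only each feature's
major isotopes at ±10 ppm, which keeps interference from overlapping
proteoforms low.  Regions with fewer than 1000 total ions are discarded as
empty-probe artifacts.  Per proteoform, a two-sample T-test compares the two
tissue classes; proteoforms are ranked by -log10(p) descending and the
rank-dependent critical value

    c(i) = -log10(i * Q / m)

is applied as the classical Benjamini–Hochberg step-up rule: every rank up
to the largest rank whose -log10(p) exceeds its critical value is declared
significant.  ``m`` defaults to the number of tested proteoforms; fold
change is the mean stroma count over the mean tumor count.  PCA on
total-count-normalized regions provides an unsupervised check that the two
classes separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateVarianceError, InvalidInputError
from .geometry import ScanGeometry
from .spectrum import ProteoformFeature


@dataclass
class RegionProfile:
    """Per-region proteoform ion counts."""

    region_id: str
    class_label: str | None
    scan_range: tuple[int, int]  # (first, last) global scan indices, inclusive
    counts: pd.Series  # indexed by feature_id
    total_ions: int


def build_regions(
    ions: pd.DataFrame,
    features: list[ProteoformFeature],
    geometry: ScanGeometry,
    scans_per_region: int = 48,
    class_labels: list[str] | None = None,
    ppm_tol: float = 10.0,
) -> list[RegionProfile]:
    """Tile the scan stream into sampled regions and count feature ions.

    Scans are ordered globally (line by line); consecutive groups of
    ``scans_per_region`` scans form non-overlapping regions.  A region's
    feature counts include only ions within ±``ppm_tol`` of a feature's
    major isotope masses (nearest feature wins when windows overlap);
    ``total_ions`` counts every ion in the region.
    """
    if not 45 <= scans_per_region <= 50:
        raise InvalidInputError("scans_per_region must be within 45-50")
    gscan = (
        ions["line_index"].to_numpy() * geometry.scans_per_line
        + ions["scan_index"].to_numpy()
    )
    n_regions = (geometry.n_lines * geometry.scans_per_line) // scans_per_region
    region_of_ion = gscan // scans_per_region

    mass = ions["neutral_mass"].to_numpy(dtype=float) if "neutral_mass" in ions else np.full(len(ions), np.nan)
    iso_mass = np.concatenate([f.isotope_masses for f in features]) if features else np.array([])
    iso_feat = np.concatenate(
        [np.full(f.isotope_masses.size, i) for i, f in enumerate(features)]
    ) if features else np.array([], dtype=int)
    order = np.argsort(iso_mass, kind="mergesort")
    iso_mass, iso_feat = iso_mass[order], iso_feat[order]

    feat_of_ion = np.full(len(ions), -1, dtype=int)
    ok = np.isfinite(mass)
    if iso_mass.size and ok.any():
        m = mass[ok]
        j = np.searchsorted(iso_mass, m)
        left = np.clip(j - 1, 0, iso_mass.size - 1)
        right = np.clip(j, 0, iso_mass.size - 1)
        d_left = np.abs(m - iso_mass[left])
        d_right = np.abs(m - iso_mass[right])
        best = np.where(d_right < d_left, right, left)
        d_best = np.minimum(d_left, d_right)
        within = d_best <= ppm_tol * 1e-6 * iso_mass[best]
        feat_of_ion[ok] = np.where(within, iso_feat[best], -1)

    fids = [f.feature_id for f in features]
    regions = []
    for r in range(n_regions):
        in_region = region_of_ion == r
        matched = feat_of_ion[in_region]
        counts = np.bincount(matched[matched >= 0], minlength=len(features))
        regions.append(
            RegionProfile(
                region_id=f"region{r:03d}",
                class_label=class_labels[r] if class_labels is not None else None,
                scan_range=(r * scans_per_region, (r + 1) * scans_per_region - 1),
                counts=pd.Series(counts, index=fids),
                total_ions=int(in_region.sum()),
            )
        )
    return regions


def qc_filter(
    regions: list[RegionProfile], min_total_ions: int = 1000
) -> tuple[list[RegionProfile], list[RegionProfile]]:
    """Partition regions into (kept, discarded) by the total-ion floor.

    A region is kept iff ``total_ions >= min_total_ions`` (regions with
    fewer ions are treated as empty-probe dropouts).
    """
    kept = [r for r in regions if r.total_ions >= min_total_ions]
    discarded = [r for r in regions if r.total_ions < min_total_ions]
    return kept, discarded


def regions_to_counts(regions: list[RegionProfile]) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack region profiles into a regions x features count matrix."""
    df = pd.DataFrame(
        {r.region_id: r.counts for r in regions}
    ).T
    classes = np.array([r.class_label for r in regions])
    return df, classes


def bh_critical_value(rank: int, Q: float, m: int) -> float:
    """Rank-dependent significance threshold ``-log10(rank * Q / m)``."""
    if rank < 1 or m < 1 or not 0 < Q < 1:
        raise InvalidInputError("need rank >= 1, m >= 1 and Q in (0, 1)")
    return float(-np.log10(rank * Q / m))


def differential_test(
    counts: pd.DataFrame,
    classes,
    Q: float = 0.01,
    m_convention: str = "tests",
    test: str = "welch",
    numerator_class: str | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-proteoform two-class T-test with step-up FDR filtering.

    Returns one row per proteoform with the p-score, its rank by
    -log10(p) descending, the rank's critical value, the step-up
    significance flag, and ``log2_fc = log2(mean_numerator/mean_denominator)``
    (stroma over tumor by default; a configurable pseudocount replaces a
    zero class mean, flagged in ``fc_pseudocount``).  ``m_convention``
    chooses the denominator of the critical value: ``"tests"`` (number of
    proteoforms, the default that controls the FDR) or ``"regions"`` (number
    of sampled regions).
    """
    if not 0 < Q < 1:
        raise InvalidInputError("Q must be in (0, 1)")
    if test not in ("welch", "student"):
        raise InvalidInputError("test must be 'welch' or 'student'")
    classes = np.asarray(classes)
    labels = sorted(pd.unique(classes))
    if len(labels) != 2:
        raise InvalidInputError("exactly two classes required")
    if numerator_class is None:
        numerator_class = "stroma" if "stroma" in labels else labels[1]
    denominator_class = next(l for l in labels if l != numerator_class)
    a = counts.loc[classes == denominator_class].to_numpy(dtype=float)
    b = counts.loc[classes == numerator_class].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("need >= 2 regions per class")

    res = stats.ttest_ind(a, b, axis=0, equal_var=(test == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)

    n_tests = counts.shape[1]
    m = n_tests if m_convention == "tests" else len(classes)

    order = np.argsort(p, kind="mergesort")  # ascending p == descending -log10(p)
    rank = np.empty(n_tests, dtype=int)
    rank[order] = np.arange(1, n_tests + 1)
    crit = -np.log10(rank * Q / m)
    neg_log10_p = -np.log10(np.maximum(p, 1e-300))

    passing = neg_log10_p > crit
    significant = np.zeros(n_tests, dtype=bool)
    if passing.any():
        k = rank[passing].max()
        significant = rank <= k

    mean_den = a.mean(axis=0)
    mean_num = b.mean(axis=0)
    num = np.where(mean_num > 0, mean_num, pseudocount)
    den = np.where(mean_den > 0, mean_den, pseudocount)
    fc_pseudo = (mean_num <= 0) | (mean_den <= 0)
    log2_fc = np.log2(num / den)

    return pd.DataFrame(
        {
            "feature_id": counts.columns,
            "p_score": p,
            "neg_log10_p": neg_log10_p,
            "rank_i": rank,
            "bh_critical": crit,
            "significant": significant,
            "log2_fc": log2_fc,
            f"mean_{denominator_class}": mean_den,
            f"mean_{numerator_class}": mean_num,
            "fc_pseudocount": fc_pseudo,
            "degenerate": degenerate,
        }
    ).set_index("feature_id")


def differential_list(
    results: pd.DataFrame, log2fc_cut: float = 0.5
) -> pd.DataFrame:
    """Significant proteoforms with ``|log2_fc|`` strictly above the cut."""
    sel = results[results["significant"] & (results["log2_fc"].abs() > log2fc_cut)]
    return sel.reindex(sel["log2_fc"].abs().sort_values(ascending=False).index)


def pca_scores(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """First-two-component PCA scores of total-count-normalized regions.

    Each region's counts are divided by its total ion count, the matrix is
    mean-centered, and the scores on the first two principal components are
    returned with their explained-variance fractions.
    """
    if len(counts) < 3:
        raise InvalidInputError("need >= 3 regions for PCA")
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise InvalidInputError("every region needs a positive total count")
    x = x / totals
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise DegenerateVarianceError("count matrix has no variance across regions")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_
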