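"""Precursor assignment, m/z reconstruction and isolation-window scoring."""

import numpy as np
import pandas as pd
import pytest

import pimsflow as pf
from pimsflow.constants import ISOTOPE_SPACING, M_PROTON
from pimsflow.spectrum import ProteoformFeature, assign_charge
from pimsflow.targets import (
    IsolationWindow,
    assign_ions,
    reconstruct_mz_profile,
    score_windows,
    select_targets,
)


def _feature(fid, mono, n_iso=5):
    ks = np.arange(n_iso)
    return ProteoformFeature(
        feature_id=fid,
        monoisotopic_mass=mono,
        isotope_masses=mono + ks * ISOTOPE_SPACING,
        isotope_indices=ks,
        ion_count=0,
        member_ion_ids=np.array([], dtype=object),
        relative_abundance=1.0,
    )


def _ions_at_masses(masses, z=10):
    masses = np.asarray(masses, dtype=float)
    df = pd.DataFrame(
        {
            "ion_id": [f"i{k}" for k in range(masses.size)],
            "mz": (masses + z * M_PROTON) / z,
            "stori_slope": float(z),
            "scan_index": 0,
            "line_index": 0,
        }
    )
    return assign_charge(df, 1.0, slope_uncertainty_cv=0.0)


def test_exact_isotope_hit_and_out_of_range_miss():
    feats = [_feature("a", 9000.0)]
    ions = _ions_at_masses([9000.0 + 2 * ISOTOPE_SPACING, 9100.0])
    out = assign_ions(ions, feats, inclusion_halfwidth=2.0)
    assert out["feature_id"].tolist() == ["a", None]


def test_distance_tie_goes_to_lower_mass_feature():
    feats = [_feature("low", 9000.0), _feature("high", 9010.0)]
    midpoint = (feats[0].isotope_masses[-1] + feats[1].isotope_masses[0]) / 2
    ions = _ions_at_masses([midpoint])
    out = assign_ions(ions, feats, inclusion_halfwidth=5.0)
    assert out["feature_id"].iloc[0] == "low"


def test_assignment_partitions_and_is_monotone_in_halfwidth(mixture_run):
    specs, ds, res = mixture_run
    ions = res.ions
    counts = []
    for hw in (0.5, 1.0, 2.0, 4.0):
        out = assign_ions(ions, res.features, inclusion_halfwidth=hw)
        assert len(out) == len(ions)  # partition: every ion appears once
        counts.append(out["feature_id"].notna().sum())
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_assignment_accuracy_against_truth(mixture_run):
    specs, ds, res = mixture_run
    out = assign_ions(res.ions, res.features, inclusion_halfwidth=2.0)
    merged = out.merge(ds.truth, on="ion_id")
    feat_of_spec = {
        s.id: min(
            res.features,
            key=lambda f: abs(f.monoisotopic_mass - s.monoisotopic_mass),
        ).feature_id
        for s in specs
    }
    pro = merged[(merged["source_id"] != "noise") & merged["feature_id"].notna()]
    correct = pro.apply(
        lambda r: feat_of_spec[r["source_id"]] == r["feature_id"], axis=1
    )
    assert correct.mean() >= 0.99


def test_mz_reconstruction_shows_charge_states_and_conserves(mixture_run):
    _, _, res = mixture_run
    assignments = assign_ions(res.ions, res.features, 2.0)
    fid = res.features[0].feature_id
    edges, counts = reconstruct_mz_profile(assignments, res.ions, fid, mz_bin=2.0)
    n_assigned = (assignments["feature_id"] == fid).sum()
    assert counts.sum() == n_assigned
    # distinct charge-state clusters: count occupied, isolated bin groups
    occupied = counts > 0
    clusters = np.sum(np.diff(np.r_[0, occupied.astype(int)]) == 1)
    assert clusters >= 3
    with pytest.raises(KeyError):
        reconstruct_mz_profile(assignments, res.ions, "missing", 2.0)


def test_partition_conservation_over_all_features(mixture_run):
    _, _, res = mixture_run
    assignments = assign_ions(res.ions, res.features, 2.0)
    total = 0
    for f in res.features:
        total += (assignments["feature_id"] == f.feature_id).sum()
    total += assignments["feature_id"].isna().sum()
    assert total == len(res.ions)


def test_purity_definition():
    feats = [_feature("a", 9000.0), _feature("b", 9030.0)]
    masses = [9000.0] * 8 + [9030.0] * 2
    ions = _ions_at_masses(masses, z=1)
    assignments = assign_ions(ions, feats, 2.0)
    wins = score_windows(assignments, ions, "a", window_width=100.0, top_k=None)
    top = wins[0]
    assert top.target_ion_count == 8
    assert top.other_ion_count == 2
    assert top.purity == pytest.approx(0.8)
    pure = score_windows(assignments, ions, "a", window_width=4.0, top_k=None)[0]
    assert pure.purity == 1.0
    assert pure.coisolating == []


def brute_force_best(assignments, ions, fid, width, step, gamma=1.0):
    merged = ions[["ion_id", "mz"]].merge(assignments, on="ion_id")
    tgt = np.sort(merged.loc[merged["feature_id"] == fid, "mz"].to_numpy())
    other = np.sort(merged.loc[merged["feature_id"] != fid, "mz"].to_numpy())
    best = None
    for c in np.arange(tgt.min(), tgt.max() + step / 2, step):
        t = int(((tgt >= c - width / 2) & (tgt < c + width / 2)).sum())
        o = int(((other >= c - width / 2) & (other < c + width / 2)).sum())
        purity = t / (t + o) if t + o else 0.0
        key = (t * purity**gamma, purity, -c)
        if best is None or key > best[0]:
            best = (key, c, t, o)
    return best


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_top_window_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    feats = [_feature("a", 9000.0), _feature("b", 9800.0)]
    masses = np.concatenate(
        [
            9000.0 + rng.integers(0, 5, 200) * ISOTOPE_SPACING,
            9800.0 + rng.integers(0, 5, 150) * ISOTOPE_SPACING,
        ]
    )
    z = rng.choice([8, 9, 10, 11], masses.size)
    df = pd.DataFrame(
        {
            "ion_id": [f"i{k}" for k in range(masses.size)],
            "mz": (masses + z * M_PROTON) / z,
            "stori_slope": z.astype(float),
            "scan_index": 0,
            "line_index": 0,
        }
    )
    df["charge"] = pd.array(z, dtype="Int64")
    df["neutral_mass"] = masses
    assignments = assign_ions(df, feats, 2.0)
    width = 4.0
    wins = score_windows(assignments, df, "a", window_width=width, top_k=None)
    key, c, t, o = brute_force_best(assignments, df, "a", width, width / 8.0)
    assert wins[0].score == pytest.approx(key[0])
    assert wins[0].target_ion_count == t
    assert wins[0].other_ion_count == o
    assert wins[0].center_mz == pytest.approx(c)


def test_select_targets_threshold_and_min_purity(mixture_run):
    _, _, res = mixture_run
    assignments = assign_ions(res.ions, res.features, 2.0)
    lo = min(f.monoisotopic_mass for f in res.features) - 1
    hi = max(f.monoisotopic_mass for f in res.features) + 1

    none = select_targets(res.features, assignments, res.ions, (lo, hi),
                          rel_abundance_threshold=1.01)
    assert len(none) == 0

    table = select_targets(res.features, assignments, res.ions, (lo, hi),
                           rel_abundance_threshold=0.0, min_purity=0.0)
    assert len(table) == len(res.features)
    assert table["has_window"].all()
    assert table["monoisotopic_mass"].is_monotonic_increasing

    strict = select_targets(res.features, assignments, res.ions, (lo, hi),
                            rel_abundance_threshold=0.0, min_purity=1.01)
    assert not strict["has_window"].any()
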