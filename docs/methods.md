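# Methods

This note documents the models behind `pimsflow`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the procedure was genuinely open.

## Neutral mass and the isotope model

Every m/z ↔ mass conversion uses `M = (m/z)·z − z·M_proton` with
`M_proton = 1.007276466 Da`.  Protein isotope envelopes are modeled with the
averagine approximation: the elemental composition of a protein of mass *M*
is the average residue C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ (111.1254 Da)
scaled to *M*, with C/N/O/S counts rounded and hydrogens adjusted to match
the mass.  The aggregated isotopologue distribution is the convolution of
per-element isotope distributions (abundances from the pyteomics NIST
table), computed by binary-exponentiation convolution and cached on a 25 Da
mass grid.  Isotopologue centroids sit on a uniform comb spaced
1.00235 Da above the monoisotopic mass — a standard approximation that is
exact to well under 10 ppm over the 1–70 kDa range handled here.

The number of *major isotopes* carried per feature grows from 5 at ≤10 kDa
linearly to 11 at ≥40 kDa, and the carried block is the contiguous window
of that length with the greatest summed theoretical intensity.

## Charge assignment by bootstrap voting

An ion's charge readout (STORI slope) is proportional to *z* through the
instrument calibration slope.  Each ion's slope is resampled `n_votes`
(default 25) times at its estimated relative uncertainty
(`slope_uncertainty_cv`, default 0.005); each resample votes for
`max(1, round(slope/calib_slope))` and the charge is accepted only when the
modal vote share reaches `vote_agreement` (default 0.8).  Ions whose slope
sits ambiguously between two integer multiples abstain rather than guess;
with the resampling scale matched to the true slope uncertainty, the
acceptance region shrinks as *z* grows, which is what keeps the accuracy of
*accepted* charges high even where single-shot rounding would be unreliable
(at relative slope error σ the single-shot error probability is
`2Φ(−1/(2zσ))`, already ~2% at z = 10, σ = 0.02).  The defaults were fixed
from that Gaussian calculation, not fitted.

## Mass spectrum and feature picking

The mass-domain spectrum is a Gaussian KDE over the neutral masses of
charge-accepted ions, each ion contributing unit area, evaluated on a
uniform grid.  Bandwidth `auto` is `max(0.2 Da, 5 ppm × median mass)` — it
resolves the 1.00235 Da comb below roughly 30 kDa and merges it smoothly
above; the grid step is bandwidth/4.  `density.sum()·step` equals the
number of contributing ions exactly (the kernel is normalized discretely).

Peak picking is iterative masked argmax: take the global maximum, record a
feature, zero the density over the feature's region, repeat until the
remaining maximum falls below a user threshold times the *first* maximum.
The masked region is the modeled averagine envelope around the apex
(isotopologues down to 0.5% of the envelope maximum) padded by
`mask_halfwidth` (2.5 Da below 30 kDa, else 0.75× the envelope FWHM).
Masking the full envelope, not just ±2.5 Da, is essential whenever the
bandwidth resolves isotopes: otherwise the ±3, ±4 Da isotopologue peaks of
an already-picked proteoform — often 40% of its apex — would be re-picked
as spurious features.

Reported feature masses are **monoisotopic** (recorded in output metadata;
whether instrument software reports monoisotopic or most-abundant
centroids varies, so the convention is explicit).  The apex of a picked
peak is some isotopologue centroid; its isotope index is chosen so the
resulting monoisotopic mass agrees with the envelope's ion-mass centroid
minus the averagine mean offset, then the mass is refined as the mean of
`member mass − k·1.00235` over the member ions (ions within ±10 ppm of any
major isotope mass).  The integer-index step is the accuracy bottleneck: its
error probability is roughly `2Φ(−√N/(2σ_env))` for *N* member ions and an
envelope of σ_env isotopes, so features above ~30 kDa need a few hundred
ions for a reliable monoisotopic assignment — the familiar ±1 Da ambiguity
of intact-mass work.  Each feature carries a THRASH-style confirmation
score: the cosine between its per-isotope member-ion counts and the
theoretical averagine intensities.

## Target selection

Ions are attributed to the feature whose nearest major-isotope mass lies
within ±`inclusion_halfwidth` (default 2.0 Da; ties to the lower-mass
feature).  For each target, candidate isolation windows (default width
4 Th) are enumerated on a grid (step = width/8) over the target's occupied
m/z range and scored `target_count × purity^γ` with γ = 1 by default —
the simplest monotone combiner of the two stated criteria (abundance and
purity); both are config-exposed.  Ties break toward higher purity, then
lower center m/z.  Co-isolating features with ≥1 ion inside a window are
annotated most-abundant-first.  The grid search is global over m/z rather
than per charge state, which is a superset of any per-charge-state search.

## Spatial bin allocation

Scan *k* sits at `k · probe_rate / acquisition_rate` µm.  The line is cut
into equal bins (one per target by default; 150–300 µm bins — default
200 µm — in multi-bin mode) and each target's assigned ions are summed per
bin.  Allocation proceeds in claim-and-contest rounds: every unassigned
target claims its highest-count remaining bin; uniquely claimed bins are
granted; a contested bin goes to the claimant with the lowest **total**
ion count over the line (the weakest target can least afford a sub-optimal
slot; an in-bin-count variant is available via `contest_metric="bin"`
since the original wording is ambiguous), and losers re-enter the pool to
look for secondary options.  All ties are deterministic: equal counts →
lower bin index; equal totals → lower target mass, then feature id.  Each
round assigns at least one target, so iterations ≤ #targets; on
tissue-like profiles (Gaussian bumps 5–20% of the line wide with
Poisson-counted bins) 100 targets on 100 bins converge in ≤9 rounds.
Multi-bin mode runs the same first pass, then grants one extra bin each —
best remaining bin — in ascending order of total abundance, up to two bins
per target, which protects scan-hungry large, low-abundance proteoforms.

## Method export

Assigned bins become chronological events via `time = position /
probe_rate`.  Targets below 17 kDa are fragmented in ensemble mode
(normalized collision energy default 35), heavier targets in individual-ion
mode (default 10 eV) — the mass threshold and energies are configurable.
The CSV schema (`start_time_min, end_time_min, center_mz, isolation_width,
ce, mode, target_id`; RFC 4180; 2-decimal minutes, 4-decimal m/z) is a
documented neutral stand-in for a vendor targeted-MS²/DIA import; the
~20 µm lateral offset between survey and MS² lines is physical positioning
metadata, not computed here.

## Region label-free quantitation

Consecutive groups of 45–50 scans (default 48) form sampled regions;
per-region proteoform counts use only ions within ±10 ppm of the major
isotope masses (nearest feature wins), which keeps interference from
overlapping envelopes low.  Regions under 1000 total ions are discarded as
empty-probe artifacts (kept iff total ≥ threshold).  Per proteoform a
two-sample t-test compares the classes — Welch by default (robust to
unequal variance), Student optional.  Proteoforms are ranked by −log10(p)
descending and the critical value `−log10(i·Q/m)` is applied as the
classical step-up rule: every rank up to the largest passing rank is
significant.  `m` defaults to the number of tested proteoforms — the choice
under which the procedure actually controls the FDR — with an
`m_convention="regions"` override.  Fold change is
`mean_stroma / mean_tumor`; a zero class mean is replaced by a pseudocount
(default 0.5) and flagged.  Zero-variance proteoforms get p = 1 and a
degenerate flag.  PCA operates on total-count-normalized, mean-centered
region vectors; the first two scores and explained-variance fractions are
returned, and a constant matrix raises a degenerate-variance error.

## Imaging

A proteoform image accumulates ions within ±10 ppm of the major isotope
masses into pixels of `pixel_along` µm (default 20, matching the probe's
effective along-track resolution) by one strip step across (80 µm imaging /
100 µm LFQ geometries both supported via configuration).  Counts are raw —
no smoothing or interpolation — so images remain auditable;
99th-percentile hot-spot clipping is available but off.  Overlays are
channelwise max-normalized with no cross-channel mixing.

## Intact-mass-tag search

Each database protein yields 11 candidates: unmodified, four single
modifications (initiator-Met loss −131.040485, water loss −18.010565,
acetylation +42.010565, phosphorylation +79.966331 Da) and their six
unordered pairs.  Masses are monoisotopic throughout, consistent with the
survey convention; the Met-loss delta is offered even without sequence
knowledge since the search operates on a mass database.  Matching uses a
sorted-mass index, returns every candidate within the ppm tolerance
(default ±1.5 ppm) ordered by |error|, and is exactly equivalent to a
linear scan.  Optional recalibration fits `ppm(m) = a + b·m` by least
squares to anchor proteoforms of known mass and reports anchor residuals so
nonlinear drift shows up rather than being absorbed.

## Synthetic data: what it emulates, what it does not

The generator emulates denaturing-electrospray single-ion line scans: per
scan, each proteoform contributes Poisson ion counts proportional to its
spatial profile; charges are rounded Gaussians (envelope means near
mass/900, as for denatured proteins); isotopologues are sampled from the
averagine envelope with ions placed exactly on the comb; slopes are
`calib·z·(1 + N(0, cv))` with cv default 0.005 (consistent with the
near-unit charge accuracy real individual-ion processing attains up to
z ≈ 60); background ions are uniform in m/z and scan index with uniform
slopes.  The default survey roster holds 113 proteoforms, ~78% between 4
and 17 kDa and the rest up to 50 kDa, with log-uniform ion budgets spanning
1.5–100% of the most abundant feature and ≥0.4% relative mass separation.
Two-class region counts are gamma-Poisson (negative binomial, dispersion
default 0.1) with a chosen fraction of proteoforms shifted by a fixed log2
effect of random sign, split symmetrically between classes.

Not emulated: time-domain transients and image-charge physics, ion decay,
detector artifacts, chimeric/harmonic assignments, m/z measurement error
(ion masses are exact given the true charge), correlated background, and
spatial carryover between regions.  Passing tests therefore demonstrate
that the algorithms recover what the model plants — charge, masses,
locations, differential abundance — not that the instrument model itself is
complete; in particular real data would add per-ion mass jitter that the
monoisotopic refinement averages over, and background statistics the
uniform model only approximates.

## Problem sizes used in the checks

The shipped checks run at desk scale chosen to finish in minutes on one
core: the survey-recovery check uses the full 113-feature roster
(~180 000 ions, one 2000-scan line); charge-recovery uses six envelopes
(18 000 ions) at 2% slope noise; the FDR/recall/PCA checks use 1000
proteoforms × 472 regions with 20 replicate seeds; allocation convergence
uses 50 instances of 100 targets × 100 bins; oracle-equivalence checks use
≤500-ion window instances and a ~10⁴-candidate mass index.

## Known limitations

- Monoisotopic assignment above ~30 kDa needs a few hundred ions per
  feature; sparser features may sit ±1 isotope off (reported mass still
  within ~30–70 ppm).
- Features closer than the masked envelope width merge into one.
- Allocation optimizes each target's bin greedily per round; it does not
  search for a globally optimal assignment (and the original procedure does
  not either).
- LFQ supports exactly two classes; no batch correction or normalization
  beyond total ion count.
- The method table is a neutral schema; emitting vendor method files and
  controlling instruments are out of scope, as are MS² fragment searches
  and identification FDR.
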