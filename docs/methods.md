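# Methods

This note documents the models, numerical conventions and design
choices behind trflpkit, and what its synthetic-data tests do and do
not demonstrate about real data.

## Fingerprint model

A T-RFLP profile is a list of (fragment size, peak area) pairs from a
capillary run of a fluorescently end-labeled, restriction-digested 16S
amplicon pool. Each ribotype ideally contributes one terminal fragment
whose called size identifies it; areas are proportional to template
abundance only loosely (PCR and loading are non-quantitative), so all
downstream statistics use within-profile *relative* fluorescence or
presence/absence.

### Duplicate consensus

Each sample is run twice. Peaks whose sizes agree within
`duplicate_tol` (default 0.5 bp) are treated as the same fragment and
merged by averaging size and area; peaks seen in only one run are
treated as run artifacts and dropped. Matching is greedy on the
smallest size difference, each peak used at most once, with ties on
distance resolved toward the smaller fragment. Greedy
nearest-pair was chosen because it is deterministic, symmetric in the
two runs, idempotent on identical runs, and needs no tuning; an
optimal-assignment matcher would differ only in contrived tie cases.

### Gating and background threshold

Fragments are kept when strictly inside (80, 600) bp — the reliably
size-called range of the instrument/standard combination — and when
their area strictly exceeds `pct`% of the profile's total
fluorescence. The threshold is computed once from the input profile's
total, not iterated after removal. The literal strict inequalities are
deliberate and tested.

`pct` defaults to 1.2 but can be selected by the variable percentage
threshold procedure: because loaded DNA amounts vary, raw
detected-peak counts rise with total fluorescence; the procedure scans
a grid (default 0.1–5.0% in 0.1 steps) and returns the smallest value
at which the one-sided Pearson test (α = 0.05) no longer finds a
positive count/total correlation across profiles, falling back to the
correlation-minimizing value if none qualifies. At least 3 profiles
are required for the correlation to be defined.

### Binning and the best frame

Sizes are called with sub-bp imprecision, so profiles are aligned on
1 bp bins over `round(WS/Sh) = 10` candidate frames offset by
multiples of Sh = 0.1 bp. Bins are left-closed half-open intervals
(an arbitrary but fixed and tested convention); within a sample, peaks
in one bin are summed; values are relative fluorescence (area divided
by the sample's post-filter total); a bin's label is the
fluorescence-weighted mean peak size, reported to 0.1 bp.

A frame whose first bin edge lies above a peak drops that peak, so
frames are scored by total retained relative fluorescence and the
maximum wins. That score alone is degenerate in the common case where
no frame drops anything (all scores equal); ties are therefore broken
by *fewest bins* — the frame that splits the fewest TRF size clusters
across bin edges — and finally by smallest offset. Without the
bin-count tie-break the selector can return a frame whose edges sit on
the TRF size clusters, scattering one fragment into two columns and
destroying presence/absence structure; with it, the selected frame
keeps each planted TRF in a single bin in the synthetic benchmarks.

## Ordination and group statistics

Presence/absence rows are compared by the Dice dissimilarity
1 − 2a/(2a+b+c); a pair of all-absent rows is defined as distance 0
(identical in presence space) and such samples are worth flagging
upstream. The embedding is classical metric scaling (principal
coordinates): eigendecomposition of the double-centered squared
distance matrix, top-2 axes, with each axis's sign canonicalized so
the first nonzero loading is positive; the reported fit is the share
of positive eigenvalue mass captured. Classical scaling was preferred
over nonmetric stress minimization because it is deterministic,
closed-form and directly testable against planted geometry; Dice
matrices are generally non-Euclidean, so negative eigenvalues are
simply excluded from the fit denominator.

Clusters come from seeded k-means (best of 50 initializations by
within-cluster sum of squares, labels ordered by center
x-coordinate); k is a user parameter, default 2, reflecting the
baseline-versus-shifted contrast the pipeline is built to expose, not
an automatic model selection. Per-cluster confidence ellipses use the
sample mean and covariance scaled by the χ²₂ quantile at the 50% and
95% levels; collinear clusters yield a degenerate (zero-minor-axis)
ellipse and are flagged. Group richness contrasts (TRF count per
sample) report mean ± sd (n−1) with a two-sided Welch t-test, chosen
as the conservative default when no test is otherwise specified; a
permutation test on the mean difference is provided as a
distribution-free alternative.

## Clone-library statistics

Sequences are trimmed to 750 bp from the 5′ end of the 63F forward
primer (default `CAGGCCTAACACATGCAAGTC`, user-overridable), located by
exact match and otherwise by the best sliding window with ≤ 2
mismatches; unlocatable primers exclude the sequence (reported, not
fatal) and short remainders are kept but flagged.

Pairwise identity uses global alignment (+1 match, −1 mismatch, −2 gap
open, −1 gap extend) with the identity denominator restricted to
columns between the first and last position where both sequences have
a residue — terminal overhangs of partial-length clones are not
penalized. Dereplication at 97% identity is greedy single-pass in
input order (join the first group whose *seed* matches, else found a
new group), mirroring classical dereplication tools; because group
counts can shift by 1–2 under variant clustering rules, an all-pairs
complete-linkage mode is provided and both counts are reported by the
acceptance script.

Chao1 uses Ŝ = S_obs + F₁²/(2F₂) when doubletons exist and the
bias-form S_obs + F₁(F₁−1)/2 otherwise, with the log-normal 95% CI on
the unseen richness T = Ŝ − S_obs (K = exp(1.96√ln(1+var/T²)),
bounds S_obs + T/K and S_obs + T·K, collapsing to S_obs when F₁ = 0).
Shannon–Weaver uses natural logarithms, which is what reproduces
literature magnitudes for libraries of a few dozen ribotypes.

## In-silico digestion

Only the forward (labeled) strand matters: the predicted TRF of a
clone is (first recognition-site start − 1) + cut offset in 1-based
coordinates — CfoI (GCG^C) has offset 3, MspI (C^CGG) offset 1.
Site matching is IUPAC-aware with one asymmetry: an N in the
*sequence* never satisfies a concrete recognition code, since an
ambiguous base cannot be trusted to be cut. Detectability uses the
same strict (80, 600) window as the fingerprint gate. Matching
predictions to observed bins allows ±3 bp by default because
electrophoretic mobility shifts called sizes from true fragment
lengths by a few bp; the signed offset is reported per match for drift
diagnosis, and a prediction equidistant between two bins is assigned
to the smaller center and flagged.

## Synthetic surveys

The generator emulates the statistical structure the pipeline assumes,
at desk scale. Defaults define the study conditions: 3 sites × 8
seasons × 3 colonies (72 samples), two enzymes, a dominant ribotype at
expected share 0.7 with 6 rare associates, one shift season in which a
different ribotype takes over and the baseline dominant vanishes,
size-call jitter sd 0.15 bp (below the 0.5 bp duplicate tolerance but
wide enough to exercise the 0.1 bp frame grid), log-normal total
fluorescence (sd 0.5 on the log scale around 50,000 units), Poisson(2)
background peaks per sample with fractional areas uniform in
0.2–1.0% (below the background threshold in expectation, so
thresholding rather than gating removes them), and an absolute
instrument detection floor of 300 fluorescence units. The detection
floor is what creates the count-versus-loading dependence that the
variable percentage threshold exists to remove; with it, the selected
percentage lands around 0.5–1.5% across seeds. Clone libraries are
multinomial over regime abundances with per-clone substitution rate
set to half the configured within-ribotype divergence (default 1%), so
*pairwise* divergence among clones of one ribotype is sub-percent.
Rare taxa are split between regimes with a 10% cross-share so
off-regime associates appear sporadically near the threshold, as
infrequently detected taxa do in real profiles.

Reference sequences (700–1500 bp window, default draw 700–1100) are
i.i.d. random DNA with restriction sites planted so each taxon's first
CfoI/MspI cut yields its declared TRF (accidental earlier sites are
mutated away and the construction is verified against the digestion
model); an optional extra taxon carries its first CfoI site at 636 bp,
past the detection gate, to exercise the undetectable-prediction path.
Everything is bit-reproducible from the scenario seed.

What the generator does *not* emulate: realistic 16S base composition
and phylogenetic covariance (between-taxon identity is far below any
real pair of bacteria), PCR amplification bias, chimeras, pseudo-TRFs,
multi-operon heterogeneity beyond i.i.d. substitutions, or systematic
electrophoretic mobility drift between true and called sizes (true
TRFs are integers; called sizes jitter around them). Passing the
synthetic benchmarks therefore shows the *procedures* are implemented
correctly and are robust at the stated noise levels; it does not
certify recovery rates on real electropherograms, where drift and
peak-calling artifacts add error modes the generator omits.

## Problem sizes and tolerances

The benchmark suite uses: 200 random instances (≤6 samples × ≤8
peaks) for frame-selection against exhaustive enumeration; 1,000
random run pairs for the duplicate-consensus properties; 100 seeded
replicates of the default 72-sample survey for shift recovery (mean
Rand index ≥ 0.95 against true shift membership, one enzyme); 10⁵
points for 95%-ellipse coverage within ±0.01; 100 seeded libraries of
24 clones on 700–760 bp references for exact ribotype-count recovery,
with greedy/complete-linkage agreement checked on 18-clone instances;
and 500 random 1 kb sequences × 12 enzymes for digestion against a
substring-scan oracle. Numerical comparisons use float tolerances of
1e-9 for row sums, 1e-8 for Procrustes-aligned MDS recovery, and
printed precision elsewhere.
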