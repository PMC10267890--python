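# Methods

This note documents the models, parameter choices, and numerical policies
behind `migscreen`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Mass arithmetic (chemcore)

Atomic and isotope masses are embedded as a static CODATA/IUPAC table so no
result depends on an external resource. Charged-species masses include the
electron: an adduct is (name, polarity, multimer n, mass delta δ, charge z)
with m/z = (n·M + δ)/|z|, and δ carries the ∓m_e correction (e.g. the
sodium adduct adds 22.989218 Da, not the neutral atom's 22.989769). The
registry ships the 15 ESI forms relevant to packaging-migrant screening:
eight positive ([M+H]+, [M+NH4]+, [M+Na]+, [M+K]+ and their 2M dimers), six
negative ([M-H]-, formate [M+FA-H]-, acetate [M+Hac-H]- and their 2M
dimers), plus the in-source water loss [M+H-H2O]+, which real QTOF data of
fatty-acid esters regularly shows. Only |z| = 1 is supported: multiply
charged species are essentially absent in this compound domain.

Isotope patterns are computed by per-element convolution (binary
exponentiation of the single-atom distribution), aggregating probability on
a 1 mDa grid and pruning below 1e-4 of the base peak — both chosen to match
QTOF resolving behavior; neither is critical, and both are arguments.

Formula enumeration from an accurate mass searches heavy elements
depth-first (hydrogen closed-form last) inside per-element ceilings implied
by the target mass. Candidates must have ring-plus-double-bond equivalents
(RDBE, computed as 1 + Σ nᵢ(vᵢ−2)/2 with standard valences) that are
non-negative integers ≤ 40 and H/C ≤ 4. These are the common plausibility
heuristics for small organics; all are configurable. With the full
C,H,O,N,P,S,F,Cl element set the search is exhaustive and fast below ~600
Da; for heavier targets the element set should be restricted (the test
suite does this above 400 Da), since the candidate space grows
combinatorially.

## Library compilation (speclib)

MSP dialects are absorbed by one case-insensitive key-synonym table
(PRECURSORMZ / PrecursorMZ / "PRECURSOR M/Z", RT / RETENTIONTIME, CAS#, …);
unknown keys are preserved verbatim so no metadata is lost on round trip.
Harmonization normalizes adduct labels to registry names, re-serializes
formulas to Hill order, rescales intensities to base peak 100, and *flags*
rather than rejects problems (precursor/formula disagreement > 0.01 Da,
product ions above the precursor, unknown adducts) — curation decisions
stay with the user. Deduplication keys on (InChIKey — first block when only
that is available — adduct label, collision-energy string) and keeps the
record from the highest-priority source, then the richest peak list; the
merge is therefore stable under permutation of input libraries. Collision
energies compare as exact strings; numeric binning would be a guess about
vendor conventions. All tie-breaks in the package resolve to lower m/z,
then lexicographic name, so golden files are deterministic.

Transition export takes the `top_n = 5` most intense product ions per
compound (all of them when fewer exist), normalized so the strongest is
100.

## Feature cleaning (features)

The cleaning cascade uses the standard screening thresholds as defaults:
minimum peak height 3000 counts, sample-max/blank-max > 5, blank/QC ≤ 0.5,
QC RSD ≤ 30%. The blank/QC ratio uses *means* of the role groups (maxima are
selectable by the caller by pre-aggregating); RSD uses the sample standard
deviation (ddof = 1). A blank of all zeros is replaced by a 1-count floor so
the presence ratio stays defined — any visible signal then passes. Each
filter is a pure row predicate, hence idempotent and order-independent;
the property suite checks both.

Clustering connects co-eluting features (|ΔRT| ≤ 0.025 min) whose
cross-sample intensity profiles (untransformed, as aligned exports provide
them) correlate with Pearson r ≥ 0.8 at p ≤ 0.05, the p-value from the
two-sided t transform with n−2 degrees of freedom — the standard Pearson
test, which requires ≥ 3 sample columns. Constant vectors have undefined
correlation and contribute no edges. Edges are annotated by mass
difference: registered adduct-pair deltas (e.g. 21.9819 for Na-vs-H) and
monomer→dimer relations at 0.005 Da; a pair is an in-source fragment link
when the lighter feature's m/z appears in the heavier one's MS2 spectrum.
Isotopologue links (Δm ≈ 1.00335·k) are implemented but off by default,
since upstream alignment software usually collapses isotopologues already.
Each connected component keeps two representatives — highest sample
intensity and highest degree — because the most intense member carries the
best MS2 while the most connected is the most probable neutral-form anchor.

Positive/negative merging infers each feature's neutral mass from its
assigned adduct (falling back to [M+H]+ / [M-H]-) and merges features whose
neutral masses agree within 0.005 Da at |ΔRT| ≤ 0.025 min; many-to-many
conflicts resolve to the closest mass pairing and the rest pass through.

## Identification (identify)

The spectral identification score is
100·(0.5·cosine + 0.25·reverse-cosine + 0.25·matched-reference-fraction)
with greedy nearest-m/z peak pairing at 0.025 Da (deterministic: candidate
pairs taken by ascending m/z gap, each peak used once). The component
weights are this package's policy — alignment-software scores differ in
detail — and are arguments; self-match is always 100 and the default
acceptance cutoff is 80. The plain-cosine component is cross-checked in the
tests against an independent implementation (matchms `CosineGreedy`).

Database search evaluates, per adduct hypothesis, every entry whose
theoretical adduct m/z falls within 0.005 Da, with three sub-scores in
[0, 1]: mass error (1 − |Δm|/tol), isotope agreement (1 − mean |ΔA+1, ΔA+2|
relative abundance difference), and fragment explanation — the fraction of
MS2 intensity carried by peaks whose mass minus the charge carrier matches a
sub-formula of the candidate (RDBE ≥ −0.5) within 0.025 Da. Sub-formula
explanation is a deliberate formula-level stand-in for structure-based
bond-disconnection fragmenters: it needs no structure files, is exactly
invariant to intensity rescaling, and suffices for formula-level decisions;
SMILES are retained in the data model for a future structural fragmenter.
Missing evidence (no isotope pattern, no MS2) is excluded from the mean
rather than zeroed, so sparse features are not penalized into oblivion. The
base score is scaled to 10 and multiplied by the database weight
(defaults 2 / 1.5 / 1 for sample-specific, packaging-specific, generic);
a multiplicative combination keeps ranks monotone in the weight, which the
tests assert. A library match at or above the cutoff always outranks a
database annotation; every feature ends as exactly one of library_match /
db_annotated / unknown.

## Pseudo-MRM (pseudomrm)

DIA (all-ion fragmentation) runs are modeled as product-ion chromatograms
inside precursor isolation windows — by default one wide window, the MS^E
case. Peak detection applies a moving average of window 2·level+1 (level 1
by default), takes local maxima that top the half-height run they sit in
(this rejects shoulders and noise bumps riding a larger peak), and requires
≥ 5 contiguous points above half height and apex ≥ 100 counts. `min_width`
counts data points, not seconds. Areas are trapezoid integrals over bounds
that extend while intensity descends and stays above 1% of the apex; on a
noiseless Gaussian the area is within 2% of h·σ·√(2π), which the tests
verify.

The presence score is a transparent composite standing in for trained
posterior models of targeted-metabolomics software: four components in
[0, 1] — RT agreement 1 − min(|Δrt|/0.1 min, 1); ion-ratio fidelity
1 − min(meanᵢ(|obsᵢ−refᵢ|/refᵢ)/0.15, 1), i.e. the 15% amplitude tolerance
applies to relative ion-ratio deviation (apex-height deviation is the
documented alternative reading; the ratio reading matches how transition
libraries are used); shape, the mean pairwise correlation of transition
traces over the union peak span; and coelution, the fraction of library
transitions whose apex is within the RT tolerance of the group median. The
posterior is 100 × the mean of available components, threshold 60. A
compound is present in a sample iff the score passes *and* its summed
transition area is ≥ 3× the largest blank-run area (1-count floor for clean
blanks), which makes presence monotone in both directions (asserted as a
property).

## Synthetic data (synthdata)

The generators are pure functions of (parameters, seed) and emulate the
statistics the pipeline's filters assume. Compounds get random CHNO(S,Cl)
formulas with integer RDBE in [1, 12]; their product ions are true
sub-formula masses plus the charge carrier, so fragment-explanation scores
are 1 by construction. Feature tables draw a latent per-sample abundance
per compound (log-normal, σ = 0.8 across samples) shared by all of its
adduct features, each multiplied by log-normal noise of CV 10% by default
(5% where a test exercises the r ≥ 0.8 clustering bound); blanks sit at 5%
of the nominal abundance, QCs are the sample mean with 2% noise — the
dispersion regime in which the 0.5 / 30% / 5× thresholds are meaningful.
DIA batches place Gaussian peaks (σ = 0.03 min on a 0.005 min grid, so the
half-height width is ~14 points) at the reference RT jittered by ≤ 0.02 min,
with a per-compound response factor (log-normal, σ = 0.3) shared between
sample and blank runs — a compound's response is a property of the
compound — and a small per-run factor (σ = 0.05). Blank contamination
defaults to 10% of the nominal height (20% in the stress test); baseline
noise is folded white noise sized so the *weakest* transition of each
chromatogram has the requested S/N (default 20, 10 in the stress test).

What passing these tests shows: the arithmetic, thresholds, clustering and
decision logic behave exactly as specified under the stated statistical
model. What they do not show: robustness to chromatographic tailing,
retention drift between simulants (a documented hazard for RT-based
identification), mass-calibration drift, detector saturation, or chimeric
MS2 spectra — none of which the generators simulate. Headline counts from a
real campaign (how many compounds a material contains) are properties of
the sample, not of the software, and are deliberately not test targets.

## Problem sizes

The default test suite runs desk-scale problems: libraries of 5–20
compounds, feature tables of ≤ 80 features, DIA batches of 12 runs × ≤ 100
chromatograms of 2 601 points, and full-element formula enumeration below
400 Da. These sizes exercise every code path; the algorithms are linear to
mildly polynomial in their inputs and have been run on larger synthetic
batches without issue.
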