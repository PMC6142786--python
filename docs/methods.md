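# Methods

This note documents the models, estimators and design choices behind
`sleepforest`, in the order the pipeline runs them, together with the
defaults and their rationale, what the synthetic-data generator does and
does not emulate, and known limitations.

## Data model

The unit of analysis is the 30-s epoch: a (2 × 3000) microvolt array —
channels Fpz-Cz and Pz-Oz at 100 Hz — carrying one six-state R&K label
(WA, NREM1–4, REM), a subject reference and an epoch id.  Six-state
labels are encoded internally as integers 0–5 in that order; merged
schemes (five: NREM3+NREM4 → SWS; four: NREM1+NREM2 → light sleep;
three: all NREM → NREM; two: all non-WA → sleep) use 0..k−1 in scheme
order.  Epoch boundaries are half-open sample ranges [kN, (k+1)N); a
trailing partial window is discarded.  Hypnogram entries outside the
six-state vocabulary (MOVEMENT, "?") are flagged and excluded from all
downstream computation.  The canonical interchange format is a CSV
feature table (60 feature columns plus `stage`, `subject_id`, `gender`,
`epoch_id`); EDF reading is optional and goes through `mne`.

## Preprocessing

*Filter.* 4th-order Butterworth high-pass at 0.5 Hz cascaded with a
4th-order low-pass at 30 Hz, applied forward–backward (zero phase).
Only the cutoffs are externally prescribed; the realization is ours.
A consequence worth knowing: content lying exactly at a cutoff is
attenuated ~3 dB per pass, so band-edge features (beta absolute power
especially) shift by several percent with every additional filter
application.  The stability test therefore checks *near*-idempotence
(second pass within 12% per feature, median change < 2%) rather than a
tighter bound.

*ICA.* FastICA with symmetric orthogonalization, tanh contrast,
eigendecomposition whitening, tolerance 1e-4, max 200 iterations, fixed
seed.  A component is flagged ocular when > 60% of its power lies below
4 Hz **and** its kurtosis exceeds 5; with only two channels at most the
single highest-kurtosis qualifying component is zeroed before
back-projection, so a recording is never annihilated.  With two
channels the "artifact" component inevitably retains some brain signal,
so the flag fires reliably only for large events (roughly ≥ 10 standard
deviations); the thresholds are configurable.

## Features (60 per epoch)

Per channel: 5 bands × {absolute power, relative power, center
frequency, max power} + Activity, Mobility, Complexity, Skewness,
Kurtosis (25 linear) and Shannon entropy, spectral entropy, Kolmogorov
entropy, largest Lyapunov exponent, C0-complexity (5 nonlinear).
Feature names are `<channel>.<feature>[.<band>]`, listed in
`feature_manifest.json`.

*Moments.* Activity is the sample variance (1/(n−1)); the first- and
second-difference variances use 1/(n−2) and 1/(n−3); Mobility =
sqrt(var(Δx)/var(x)); Complexity = Mobility(Δx)/Mobility(x).  Skewness
and kurtosis use population (1/n) moments in the Fisher–Pearson,
non-excess convention (m₃/m₂^{3/2}, m₄/m₂²; Gaussian → 3).  The
"variance cubed / squared" shorthand sometimes seen for these statistics
is read as σ³ and σ⁴ — anything else is dimensionally inconsistent.

*Spectra.* Welch periodogram, 2-s Hamming windows, 50% overlap
(Δf = 0.5 Hz at 100 Hz).  The five bands tile 0.5–30 Hz and share
endpoints, so a PSD bin sitting exactly on an interior band edge is
split half-and-half between its two bands (outer 0.5/30 Hz bins count
fully); summed band powers then equal the total exactly.  Relative
power is normalized by total 0.5–30 Hz power; center frequency is the
power-weighted centroid within the band (not the argmax — "max power"
already captures the peak).  Note that Hamming leakage spreads a pure
tone over ~3–4 bins, so the spectral-entropy floor is ~1 bit, not 0.

*Shannon entropy.* Base-2 entropy of a 16-bin amplitude histogram over
[min, max]; bin count and base configurable; constant input → 0.

*Kolmogorov entropy.* The defining triple limit is not computable from
a finite record; the implemented statistic is the Grassberger–Procaccia
K2 (correlation) entropy: delay-embed at dimensions m and m+1, form
correlation sums C_m(ε) over Theiler-separated pairs (Chebyshev norm),
and report the geometric mean over ε ∈ {0.5, 0.7, 1.0}·std of
(1/τ_s)·ln(C_m/C_{m+1}), clamped at 0.  Defaults m = 3, τ = 5 samples,
Theiler 50.  Pairwise sums are computed on an evenly strided subsample
of at most 400 embedded vectors — correlation-sum estimates stabilize
well below that, and it keeps one epoch ~5 ms.

*Largest Lyapunov exponent.* Wolf-style divergence tracking: embed
(m = 5, τ = 5, Theiler 50), follow the nearest admissible neighbor of
the current trajectory point for 5 samples, accumulate ln(d₁/d₀),
replace the neighbor with a fresh nearest neighbor, repeat (≤ 150
steps); the exponent is the accumulated log growth per second.
Separations below 1e-8 of the embedded scale are treated as coincident
periodic-orbit points contributing zero divergence — without this
floor, exactly periodic signals return spuriously large exponents
because the minimum-selection bias on d₀ at machine epsilon never
averages out.  On the r = 4 logistic map (m = 2, τ = 1) the tracker
recovers ln 2 within a few percent; a Rosenstein-flavored check appears
in the tests.

*C0-complexity.* Mean-removed FFT; coefficients whose squared magnitude
exceeds r × the mean squared magnitude (r = 5 by default) form the
"regular" part y; the statistic is Σ(x−y)²/Σx² ∈ [0, ~1].  A pure tone
scores ~0, white noise close to 1.  The construction of y is our
choice; r is configurable.

*Normalization.* Min–max to [0, 1], fitted on training data only and
applied to unseen data with clipping (leakage guard).  A constant
column maps to 0 with a warning.

## Ontology store

An in-memory four-layer hierarchy (domain → category → class →
instance) with object-property triples and typed data properties
(Integer/Float/String/Boolean), conjunctive queries in insertion order,
and JSON serialization.  The bootstrap schema creates the EEG and Sleep
categories, the participants/electrodes/features/sleep staging/staging
rules classes, the two electrodes and the five scheme names.  Ingesting
a feature table creates one instance per epoch with 60 Float properties
plus `hasSleepStages`/`hasGender`, linked to feature instances via
`hasEEGfeature` and to its participant via `belongsTo`; export inverts
this exactly.  SPARQL/OWL tooling is deliberately out of scope — the
store's role is structured storage and lookup, which this API covers
with referential integrity enforced on every mutation.

## Feature selection

Pearson r between each normalized feature and the ordinal stage code,
computed per gender; two-sided p from the t distribution with n−2
degrees of freedom.  The stage enters as an ordinal (0–4, five-state by
default): the merged schemes are ordered from wake to deep sleep with
REM last, and the monotone trends of delta/alpha power along that
ordering are exactly what the correlation is meant to pick up.  The
subset is all features with p below the threshold, ordered by |r|.
The default threshold is 0.005; self-adaptive mode evaluates candidates
{0.05, 0.01, 0.005, 0.001} by 5-fold cross-validated accuracy of a
10-tree forest on the induced subset and keeps the best, ties to the
stricter cutoff.  No multiple-testing correction is applied; the strict
threshold plays that role, and selection runs on a data half that the
classifier never sees.  Correlation is affine-invariant, so running it
before or after min–max normalization is equivalent; it is run after,
on the stored (ontology) representation.

## Weighted forest

Feature weights are computed on the normalized training matrix with the
population (1/n) standard deviation and normalized to sum to 1.  The
split criterion multiplies the standard information gain (parent
entropy minus size-weighted child entropies, base 2) by the weight of
the candidate feature; with equal weights this is a constant scaling,
and the trees produced are identical to plain information-gain trees —
the unweighted mode is implemented as exactly that uniform-weight path,
so the equivalence is structural, not approximate.  A printed variant
of the gain formula that omits the parent-entropy term is treated as
shorthand: the parent term is constant per node but required for
cross-feature comparability once weights differ.

Trees: midpoint thresholds between consecutive distinct sorted values,
vectorized gain scan via cumulative class counts, mtry = ⌈√d⌉ features
per node (per-node subsampling, the standard Breiman scheme), grown to
purity (no depth cap, min 1 sample per leaf).  Zero-gain splits are
allowed on impure nodes so interaction patterns (XOR-like) are still
separable deeper down.  Ties break toward the lower feature index and
lower threshold.  Forests: 30 trees by default, bootstrap samples of
size n with replacement, all randomness derived from one seed, JSON
serialization byte-stable.  Prediction is majority vote with ties to
the lowest class index; vote fractions serve as ROC scores.

The classical majority-vote bound for k independent trees of equal
error p — Σ_{j>k/2} C(k,j) p^j (1−p)^{k−j} — is exposed as
`ensemble_error` (odd k only; 3 trees at p = 0.4 → 0.352).

## Evaluation

Confusion matrices with rows = expert, columns = classifier.  Binary
definitions (TPR, TNR, precision, F) aggregate one-vs-rest with macro
averaging; F is defined 0 when precision + recall = 0.  Kappa comes in
two forms: multiclass Cohen (marginal-product chance agreement) and the
per-class binary formula 2(TN·TP − FP·FN)/((TN+FN)(FN+TP)+(FP+TP)(TN+FP)).
ROC area is the Mann–Whitney rank statistic with midranks, macro
one-vs-rest, classes absent from the truth excluded with a warning.
Printed percentages round half-up to 2 decimals.  Specificity is
reported in the standard orientation (higher = better).

## Synthetic EEG

Each stage is a sum of band-limited Gaussian noise components (spectral
shaping: random Fourier coefficients outside the band zeroed — noise,
not tones, so entropy and complexity estimators stay non-degenerate)
plus a 1/f background confined to 0.5–30 Hz.  Band variances are
compensated for the background's own band shares so the *composite*
relative band powers land on the profile's `band_weights` (verified to
±0.05 over 100 epochs per stage).  Default profiles: alpha-dominant WA
(0.45 alpha), theta-prominent NREM1 (0.40 theta), NREM2 with 2
spindles (0.8-s Hann-windowed 13 Hz bursts) and 1 K-complex
(Gaussian-windowed ~1-s biphasic pulse) per epoch on average,
delta-dominant NREM3/NREM4 (0.55/0.65 delta), beta-rich REM (0.40
beta).  Amplitude scales grow from 30 µV (WA, REM) to 85 µV (NREM4),
mirroring the increase of EEG amplitude with sleep depth.  Channel 2
shares 70% of its variance with channel 1.  Stage prevalences default
to overnight proportions (NREM2 ≈ 46%, WA ≈ 8%).  The gender effect
multiplies female delta weights by 1.15 (renormalized) — large enough
for correlation-based selection to find, small enough not to dominate.
Ocular artifacts are optional ~1-s Gaussian-windowed deflections, a
frontal-dominant gain pattern, energy well below 16 Hz.

What the generator does *not* emulate: stage transitions and temporal
continuity (epochs are i.i.d. given the stage), arousals, real spindle
density/topography statistics, inter-subject spectral variability
beyond the gender tweak, EMG/ECG contamination, electrode artifacts.
Passing tests therefore demonstrate that the pipeline recovers the
spectral structure it is built to exploit, not that it reaches any
particular accuracy on clinical recordings.

## Experiment protocol

`run_experiment`: stratified (stage × gender) split into a correlation
half and a classification half; normalization fitted per use (on the
correlation half for selection, on the training 2/3 of the
classification half for the forest); ontology ingest of the correlation
half and export back (the stored representation is the one correlated);
per-gender selection; per-gender standard-deviation weights and a
30-tree forest on the selected features; pooled test confusion matrix.
The correlation analysis always runs against the five-state codes —
the subset is computed once, and only the classification stage varies
across merge schemes, mirroring the case design (case 1: five-state
unweighted; case 2: five-state weighted; cases 3–5: four/three/two-state
weighted).  Every run records its seeds, splits, thresholds, subsets and
weights in a manifest; re-running a manifest reproduces every output.

Merging labels can only make a *fixed* set of predictions more often
correct, so scoring a five-state run under the two-state scheme never
lowers accuracy; a *retrained* binary forest is not covered by that
argument and can lose an occasional borderline WA epoch to the 92:8
class imbalance even when the five-state run is perfect.

Problem sizes in the shipped tests: end-to-end runs use 2,000 epochs
(5 subjects per gender × 200 epochs) over 5 seeds, smaller suites use
hundreds; with ~26 ms per-epoch feature extraction the full test run
completes in a few minutes on one CPU.

## Known limitations

- Two-channel ICA can only ever split the recording into two sources;
  ocular cleanup is coarse and conservative by design.
- K2 and Lyapunov estimates at these defaults are rank features, not
  precision measurements; their absolute values depend on the embedding
  and radii (documented above, configurable).
- The class-prior imbalance (NREM2 dominance) is left as-is to match
  the protocol; no rebalancing is applied by default.
- EDF writing exists only at fixture quality (1-s records, integer
  microvolts, physical = digital range).
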