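# Methods

This note records the models, conventions and defaults behind
`broileracc`, the choices made where the design was genuinely open, and
what the synthetic data can and cannot establish.

## Signal decomposition

Each axis is filtered twice: a 1.78 Hz low-pass isolates the static
(gravitational) component and a 1.75–22.05 Hz band-pass the dynamic
(movement) component.  The filter family and order are a package choice:
4th-order Butterworth, applied forward and backward (`sosfiltfilt`) so
the output has zero phase lag and windows stay aligned with behaviour
annotations.  The band edges overlap slightly (1.75 vs 1.78 Hz), so
static + dynamic only approximately reconstructs the raw signal; no
reconstruction identity is asserted anywhere.  When the sampling rate
cannot support the 22.05 Hz upper edge (fs ≤ 44.1 Hz) the edge is
clipped to 0.99 × Nyquist with a logged warning rather than failing.
The first and last ⌈fs⌉ samples are flagged as edge-affected;
`extract_features(..., drop_edge_windows=True)` discards windows that
touch them (retained by default).

VeDBA is the per-sample Euclidean norm of the three dynamic components —
the definition universal in the accelerometry literature.  Tilt angles
are computed from the **static** components.  Roll and yaw follow the
printed operational forms (`atan(Y/√(X²+Z²))`, `atan(Z/√(Y²+X²))`);
these measure rotation of the gravity vector toward the y- and z-axes
and are not the aeronautical Euler angles.  No pitch formula is printed
in the source toolchain, so pitch is taken as the axis-symmetric
completion `atan(X/√(Y²+Z²))` — an assumption, stated here.  Degenerate
denominators resolve via `atan2`: ±π/2 by the numerator's sign, 0 when
the numerator is 0 too.

## Windows, purity and the 99 attributes

Windows are 3 s with 50 % overlap: `round(3·fs)` samples every
`round(1.5·fs)`, trailing partial windows discarded.  A window's purity
is the fraction of its duration occupied by its most-represented
behaviour among sit/stand/walk; `other` and unannotated time count
against purity.  Ties break deterministically in the order
sit < stand < walk (a tie can only be returned at thresholds ≤ 0.5;
training uses 1.0 and testing 0.6, where ties are discarded).

Skewness and kurtosis use the (N−1)-denominator moment form with the
sample standard deviation, `Σ(k−k̄)³/(N−1)/sd³` and `Σ(k−k̄)⁴/(N−1)/sd⁴`,
with skew = kurt = 0 for constant windows.  Two quantities needed
concrete conventions:

* **Entropy** — Shannon entropy in nats of the window's values
  histogrammed into 10 equal-width bins over the window's own range
  (scale-free; constant windows give 0).  Bin count is configurable.
* **Peaks/troughs** — strict local extrema, with plateaus collapsed to a
  single extremum; implemented on forward-filled difference signs and
  cross-checked in tests against `scipy.signal.find_peaks`.
* **Spectral peaks** — local maxima of the magnitude spectrum of the
  mean-removed window, kept when at least 5 % of the spectrum maximum
  (configurable floor; suppresses numerical-noise peaks).  The spectral
  input is the **dynamic** component per axis; the static component is
  near-DC and spectrally uninformative.  With no qualifying peak all
  eight outputs are 0.
* **IQR** — linear-interpolation quantiles (NumPy default), stated so
  other implementations can match it.

## Datasets

The split is at the bird level within strain — the guard against
pseudo-replication, where windows of one animal fall on both sides of
the split and inflate test accuracy.  Per strain the test count is
`max(1, round((1−ratio)·n))`, giving 2/2/3 test birds for strains of
8/10/15 at the default 0.8.  Which birds land where is random with a
fixed seed (the original assignment rule is unknown).

Training keeps only 100 %-pure windows and is balanced by sampling each
(strain × behaviour) cell with replacement up to the globally largest
cell; original rows are always retained and no new feature values can
appear.  Test sets keep windows at ≥ 60 % purity and are never
resampled.  Balancing precedes cross-validation, mirroring the original
workflow; this lets duplicates of one window cross folds, which is
optimistic for CV accuracy — the held-out-bird and unseen-strain
evaluations are unaffected, and `build_datasets(..., balance=False)`
plus per-fold balancing is available when leakage-free CV matters.
Windows labelled `other` are dropped from both sides.

## Attribute ranking and the forest

Information gain is `H(labels) − H(labels | bin(attribute))` in bits,
with the attribute discretised by Fayyad–Irani entropy-minimising
binary splitting under the MDL stopping criterion (the default of the
WEKA-style toolchain this mirrors; equal-frequency binning is the
configurable alternative).  An attribute the criterion cannot usefully
split contributes 0.  Because cuts depend only on the value ordering,
gains are invariant under strictly monotone transforms.  Ranking tasks:
A = sit/stand/walk, B = {sit,stand}→static vs walk, C = sit vs stand
(walk rows dropped).  Bands follow the quartile rule — low ≤ LQ,
high ≥ UQ, medium between — computed over the 99 gains; when LQ = UQ
both boundary clauses apply and `high` wins (documented tie rule).

The forest is scikit-learn's `RandomForestClassifier` configured to the
classic defaults of that toolchain: bootstrap samples of size n,
unpruned trees, `⌊log₂M⌋+1` candidate attributes per split (7 for
M = 99), default 100 trees.  Tree count can be tuned by stratified
10-fold CV over {100, 300, 500}; ties select the smallest forest.  All
training is deterministic given the seed.

"Overall" metrics micro-aggregate: the one-vs-rest TP/TN/FP/FN are
summed across the three classes before the four formulas apply.  This
convention was selected by brute force — among macro averaging,
support-weighted averaging and micro-aggregation it is the only one
reproducing all eight published overall values from the two published
confusion matrices — and has two exact identities, asserted on random
matrices in the tests: overall sensitivity = overall precision =
trace/n, and overall accuracy = mean per-class accuracy.  Display
rounding is half-up to integer percent (matching every published cell);
full precision stays on the objects.  Zero denominators set an
`undefined` flag rather than raising.

## The synthetic flock

The generator reproduces the statistical structure the classifier
exploits, not broiler biomechanics:

* **Bout durations** are log-normal, moment-matched per strain and
  behaviour to the bundled population statistics (e.g. fast-growing CNV
  sit bouts 42.45 ± 42.97 s; slower-growing SGH walk bouts
  4.29 ± 2.33 s), truncated below at 0.5 s by rejection.  Log-normal is
  the standard right-skewed choice when sd ≈ mean.  Transitions are
  restricted to sit↔stand and stand↔walk — a bird stands up before
  walking.  Bout *frequency* and total duration are emergent, not
  targeted.
* **Posture**: gravity pitched by −0.35 rad when sitting vs 0 when
  standing (arbitrary but fixed; what matters, and is tested, is that
  the postures differ in static orientation), interpolated over 0.3 s at
  transitions.
* **Gait**: walking adds a stride sinusoid at 1 Hz (≈ one stride per
  second) plus a half-amplitude second harmonic on heave and surge, with
  a per-bout log-normal vigour multiplier (σ = 0.3).
* **Idle motion**: sitting and standing add band-limited 2.5–8 Hz noise
  on all axes (base amplitudes 0.03 g and 0.05 g), each bout scaled by a
  log-normal vigour multiplier (σ = 0.35).  The band sits above the
  static low-pass cut-off so gravity recovery stays clean, and the
  vigour variation makes the two stationary postures overlap
  dynamically — so the sit/stand distinction genuinely rests on the
  posture (static/tilt) features, as it does in real birds.  White
  sensor noise (sd 0.01 g) covers everything.
* Defaults mirror the study conditions: strains CNV/SGH/SGN with 8/10/15
  birds, 5-min sessions, 50 Hz sampling (the recording rate is not
  documented; 50 Hz clears the 22.05 Hz band edge with margin).  An FGC
  profile (alias CFG) supports unseen-strain evaluation; the end-to-end
  checks use 8 unseen-strain test birds, enough for stable window-level
  metrics at these session lengths.

What passing tests on this data do show: the pipeline's plumbing is
correct, the features carry the intended signal, posture features are
necessary and sufficient for sit/stand, and the forest generalises
across birds and to an unseen strain *of this generative family*.  What
they cannot show: performance on real broilers — real postural
transitions, surface effects, device slippage, behaviour mixtures and
inter-individual variation are all richer than this model.  The
published real-data numbers (e.g. training CV accuracy) are therefore
not targets for the synthetic pipeline; the package instead reproduces
the published evaluation arithmetic exactly and demonstrates
learnability synthetically (ten-seed medians ≥ 85 % overall accuracy).

## Numerical and degenerate-input conventions

Half-open `[start, end)` intervals everywhere; times are seconds from
recording start.  Sampling rate is inferred from the median time step
and must agree with any override within 1 %.  Readers raise typed errors
(`EmptyInput`, `NonMonotonicTime`, `OverlappingIntervals`, …) rather
than returning invalid objects; unknown behaviours map to `other` unless
strict mode is on.  Feature tables round-trip CSV with ≤ 1e-12 relative
float error.  Traces shorter than the zero-phase filter's padding raise
`TraceTooShort`; series shorter than a statistic's minimum raise
`SeriesTooShort`.

## Known limitations

* The pitch tilt formula is an assumption (see above).
* The MDL discretiser is single-attribute; interactions are invisible to
  the ranking (as with any filter method).
* Balancing before CV is kept for fidelity to the original workflow
  despite its optimism; use the provided switch for unbiased CV.
* The simulator's gait is a two-harmonic sinusoid; spectral features
  richer than peak frequency/amplitude would not be validated by it.
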