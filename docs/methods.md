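# Methods

## Scope and data model

bloodspec implements a complete FT-NIR adulteration-screening workflow for
blood-gel foods: simulate (or load) absorbance spectra, pretreat, partition,
select informative wavenumbers, and fit identification and quantification
models. The in-memory currency is the `SpectraSet`: an n × 1,557 absorbance
matrix on the ascending 4,000–10,000 cm⁻¹ grid, with sample ids, one of six
class labels, and (f_DBT, f_CBG, f_PBG) mass fractions on the unit simplex.
Class labels are a deterministic function of the fractions, so labels and
compositions can never disagree.

## The simulator

Each species (duck blood tofu, cow blood gel, pig blood gel) is modeled as a
flat baseline plus twelve Gaussian absorption bands at the key wavenumbers
where blood species differ chemically (4,108 … 9,997 cm⁻¹; C–H
combination/overtone bands, C=O and RCO₂H second overtones, S–H/C–H first
overtones, aromatic C–H, O–H/amide, N–H second overtones). Band widths are
40–120 cm⁻¹ sigma — NIR overtone bands are broad — and amplitudes
(0.10–0.80 AU over a 0.25–0.30 AU baseline) are hand-set constants chosen so
the species contrasts qualitatively track measured composition differences:
the fat-rich cow gel is strongest at the C–H bands, the protein- and
sugar-rich pig gel at the C=O and N–H bands, duck blood tofu at the
O–H/amide band. These amplitudes are stated constants, not calibrated to any
measured absorbance scale.

Mixtures are convex Beer–Lambert combinations of the endmembers by mass
fraction. A zero-artifact design is therefore exactly rank-3, and
regressing any clean spectrum on the three endmember spectra returns the
generating fractions to machine precision — the simulator's built-in
linearity oracle, asserted in the tests.

The measurement model per replicate scan is
`b·s(ν) + a + t·(ν − ν̄) + ε(ν)` with `b = exp(N(0, σ_slope))`,
`a ~ N(0, σ_offset)`, `t ~ N(0, σ_tilt)` and white noise ε; the reported
spectrum is the mean of `n_replicates` scans. The slope+offset pair is
exactly the artifact MSC models, the tilt is a mild baseline drift, and the
white noise represents detector noise after the instrument's internal
32-scan averaging. Defaults: σ_slope = 0.05 (≈5% multiplicative scatter),
σ_offset = 0.02 AU, σ_tilt = 2·10⁻⁶ AU/cm⁻¹ (≈±6 mAU across the range),
σ_noise = 0.002 AU, 3 replicates. These describe a well-maintained FT-NIR
instrument measuring homogenized gels in a standard cup.

Seeding: one master seed; each sample's generator is spawned from
`SeedSequence(seed, spawn_key=(sample_index,))`, so subsetting or reordering
the design never shifts any other sample's spectrum, and the full design is
bit-reproducible.

What the simulator does *not* emulate: instrument line shape, water/
temperature band shifts, nonlinear detector response, scattering that varies
across the wavenumber axis, and batch effects. Passing tests therefore show
that the chemometric machinery behaves correctly on data satisfying its own
assumptions (linear mixing, MSC-form scatter); they do not certify the
published real-sample accuracies, which depend on spectra that were never
deposited.

## Pretreatments

- **Centralization**: column mean-centering with training means.
- **SNV**: per row, subtract the row mean and divide by the row sample
  (n−1) standard deviation. A zero-variance row raises a degenerate-spectrum
  error.
- **MSC**: per row, OLS of the row on the training-mean reference spectrum
  (row ≈ a + b·ref), returning (row − a)/b; |b| < 10⁻¹² raises. The
  reference always comes from the training split only.
- **Derivatives**: Savitzky–Golay, default window 15 points and polynomial
  order 2, scaled by the grid spacing so the output is per cm⁻¹; edges are
  mirror-padded. SG is the NIR standard because plain finite differences
  amplify noise; window and order are configurable.

All pretreatments preserve the row count, and the fitted ones refuse to run
before fitting.

## Partitioning

The Kennard–Stone algorithm selects, within each group, the samples at
maximum pairwise distance first and then repeatedly the point farthest (in
minimum-distance terms) from the already-selected set; ties break to the
lowest index, duplicates are allowed. The *selected* third forms the
prediction set — an unusual orientation (KS normally picks calibration
samples) retained deliberately, because the workflow being reproduced holds
out the KS-selected samples. KS runs on the raw absorbance over all 1,557
variables, so the partition is identical across every pretreatment and
variable subset: all model comparisons share one split. For the
quantification tasks the same machinery stratifies by adulteration level
(five groups of 30) rather than by the six classes.

## Variable selection

**SWDA.** Forward selection with backward removal on Wilks'
Λ = det(W)/det(T). Partial F statistics use the classical thresholds
F-to-enter = 3.84 and F-to-remove = 2.71 (χ²₁ at ~5%), configurable.
Λ updates use the Schur-complement identity
Λ_{S∪v} = Λ_S · (w_v|S / t_v|S), so only scatter *rows* of selected
variables are ever materialized (the full 1,557² matrices never are).
Constant variables and variables collinear with the selected set (relative
conditional variance below 10⁻¹⁰) are skipped; requiring
f_enter > f_remove prevents entry/removal cycling. An empty selection is an
error, not a silent fallback.

**CARS.** 50 Monte-Carlo runs, 80% row sampling, PLS1 coefficients as
variable weights. The enforced retention ratio follows r_i = a·e^(−k·i)
with a, k fixed so r₁ keeps all p variables and r₅₀ keeps 2; after the
top-|coefficient| cut, adaptive reweighted sampling (a weighted draw with
replacement) fixes the retained set, with a degenerate draw (< 2 distinct
variables) falling back to the enforced set so the audit trace always has
one entry per run. Each run's subset is scored by 5-fold cross-validated
RMSE with the PLS component count chosen by that same CV (capped at 10);
the CV is computed from one maximum-rank PLS fit per fold, truncating the
rotation/loading expansion to get every smaller component count for free.
The subset with minimal RMSECV wins. With a fixed generator the whole
procedure is bit-reproducible. The PLS primitive itself is scikit-learn's
NIPALS `PLSRegression` (uncentered-scale mode), wrapped to return an
explicit coefficient/intercept pair.

Selected-variable *counts* are data-dependent and are reported, never
asserted: on synthetic data CARS tends to keep larger subsets (hundreds of
collinear spectral variables carry nearly equal information) than the few
dozen variables typical of real-sample studies.

## Identification

Per pretreatment: SWDA on the training split → PCA to 3 components (a
warning, not an error, if they explain < 99% of variance) → Fisher LDA. The
discriminant functions are the leading eigenvectors of the generalized
problem S_b v = λ S_w v (at most min(C−1, dims) = 3 of them for six classes
in 3 PCs), unit-normalized; prediction assigns the nearest class centroid
in DF space (Euclidean; Mahalanobis was considered and rejected as the
default for symmetry with the centroid plots practitioners expect). A
singular S_w falls back to a 10⁻⁸ diagonal ridge, logged.

The ELM then runs on the best pretreatment's PC scores, sweeping hidden
neurons 1–50 × {sigmoid, sine, hardlim}, one fresh uniform [−1, 1] weight
draw per grid cell spawned from the master seed. The sweep's default winner
is the best *test-set* accuracy — matching the original model-selection
protocol — which leaks the held-out set into model choice; treat the
reported test accuracy as optimistic, and use the full sweep curve when an
honest estimate is needed. The empirical neuron-range rule
N_h = N_s/(α(N_i+N_0)) is provided as a helper and gives [9, 45] for this
design (360 training samples, 3 PCs, 1 output); the sweep deliberately
covers the wider [1, 50].

**Class coding.** The default ELM target coding is one-hot with argmax
decoding. A single-numeric-code mode (codes 1..6, nearest-code decoding,
one output neuron) is provided, but it is not the default because
least-squares regression onto an arbitrary code ordering penalizes
confusions by code *distance*: classes that are spectral neighbors but code
non-neighbors (the binary series flank the ternary wedge, raw DBT sits at
the 10%-level apex) drag the fit toward adjacent-code errors, and on this
design the mode empirically plateaus near 85% test accuracy while one-hot
reaches ~96–100%. The neuron-range rule is still evaluated with one output
neuron, as its originating usage does.

## Quantification

Four single-output sine-activation ELMR tasks: CBG% in the binary DBT+CBG
series, PBG% in the binary DBT+PBG series, and CBG%/PBG% separately in the
ternary series (responses {10…50}% and {5…25}% respectively). Inputs are
the CARS-selected pretreated variables directly (no PCA), column-
standardized with training statistics and additionally scaled by
1/√(n_selected) so the random-projection arguments stay O(1) whatever the
subset size — without this the sine activation aliases once CARS keeps
hundreds of variables and the network output decorrelates from the
response. The ternary tasks can also inherit the corresponding binary
task's selection, keeping whichever scores better. Metrics are computed
exactly in the verbatim forms listed in the README, including two
conventions kept deliberately: `r` is the 1 − SSE/SST form (not Pearson's
r, despite the name used in the field's shorthand), and RER divides by the
*training* RMSE.

## Numerical and testing notes

- Tie-breaks are everywhere "lowest index wins"; all stochastic stages are
  driven by explicit `numpy` generators or spawned `SeedSequence`s, with
  per-stage seeds derived by stable hashing of stage names (kept < 2³¹).
- CSV round-trips are exact: writes use shortest-repr floats and reads use
  pandas' round-trip parser.
- Degenerate inputs raise typed exceptions (`InvalidCompositionError`,
  `DegenerateSpectrumError`, `EmptySelectionError`, `NotFittedError`,
  `SpectraIOError`) rather than propagating NaNs.
- The test suite runs the full 540 × 1,557 design (a fraction of a second
  to simulate) and the complete identification and per-task quantification
  pipelines at their default sizes; the CARS recovery property uses 20
  repeats of a 60 × 50 planted-signal problem. Dual-route checks pin the
  authored primitives to independent oracles: ELM output weights vs a
  direct SVD least-squares solve, Kennard–Stone vs an explicit brute-force
  search, PLS vs OLS in the full-rank limit, metric identities on random
  data.

## Known limitations

- Synthetic spectra are far better behaved than real gel measurements;
  absolute accuracies obtained here should not be read as expected field
  performance.
- The test-set-driven sweep criterion is optimistically biased by design
  (see above); a cross-validated criterion would be the defensible
  alternative for deployment.
- SWDA on heavily collinear spectra is sensitive to its collinearity
  tolerance; very different but equally valid subsets can result from small
  perturbations. The Wilks-Λ trace is recorded for audit.
- The `r` metric can be negative (it is not a correlation); quality bands
  quoted for RPD/RER assume the conventional usage and are reported as
  flags, not enforced.
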