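# Methods

## The analysis model

The pipeline treats each subject-run as a multivariate time series
`X ∈ R^{V×N}` of N node (ICA-component) time courses sampled every TR
seconds. Dynamic functional connectivity is estimated on temporally
overlapping windows and summarized as visits to a small set of
recurring whole-brain connectivity patterns.

**Preparation.** The first `n_discard` volumes (default 4) are dropped
(scanner signal stabilization), each node's least-squares linear trend
is removed, and the series is low-pass filtered below `cutoff_hz`
(default 0.15 Hz). The filter is a 5th-order Butterworth applied
forward and backward (`filtfilt`), i.e. zero-phase, so filtering cannot
shift state boundaries in time; the effective attenuation is that of a
10th-order filter. The stage order (discard → detrend → filter) is
enforced through provenance flags on the time-series container, and the
windowing stage refuses unprepared input. Component QC summarizes each
node's Welch spectrum (segments of 64 volumes, 50 % overlap) by the
dynamic range of the power spectral density and the ratio of integrated
power below vs. above a split frequency (default 0.10 Hz); both
thresholds are configuration, not constants, since inclusion criteria
are study-specific judgments.

**Windowed connectivity.** Windows are half-open index intervals of
`window_length` volumes (default 15 = 30 s at TR 2 s) advanced by
`step` (default 1), giving `⌊(V − L)/s⌋ + 1` windows. The default
window length follows the task-dynamics literature in which ~30 s
windows expose the most network flexibility; both parameters are
configurable. Per window the estimator is either the (optionally
Gaussian-tapered) Pearson correlation of the windowed rows, or a
sparse precision matrix — the graphical-lasso solution of
`min_P −log det P + tr(S P) + λ‖P_offdiag‖₁` — reported as partial
correlations `−P_ij/√(P_ii P_jj)`. At λ = 0 the program's solution is
the plain inverse of a positive-definite input and is computed as such.
Because a 15-volume window yields a rank-deficient sample correlation
for N > 15, the input to the lasso is ridge-shrunk minimally to
positive definiteness. Windows containing a constant node have the
affected edges zeroed and flagged rather than aborting the run.
Clustering features are the vectorized upper triangles — of the
partial-correlation matrices when the sparse estimator is selected,
else of the correlation matrices. The correlation estimator is the
default: the two estimators order window similarities almost
identically on block-structured states, correlation needs no penalty
choice (which the dFC literature leaves unsettled), and it is ~100×
cheaper over the ~18 000 windows of a full cohort.

**States.** Windows from all subjects, groups and runs are pooled and
clustered jointly (states are assumed shared across groups and runs;
labels are split back per run afterwards) with squared-Euclidean
k-means in two phases: (1) k-means (best of `n_replicates` restarts by
inertia) on *exemplar* windows — per run, the windows at local maxima
of the across-edge variance profile, a boundary window counting as a
maximum when it exceeds its single neighbor — then (2) a single
k-means pass over every window initialized at the phase-1 centroids.
Lloyd iterations are delegated to scikit-learn's KMeans; empty clusters
are re-seeded at the points farthest from their centers (the library's
relocation rule, which is the farthest-point rule). A flat variance
profile falls back to uniform subsampling with a warning. Note that on
this generator exemplar windows are not concentrated near state
switches — windows straddling a switch average two patterns and have
*lower* across-edge variance — so exemplar initialization should be
read as a seeding heuristic, not a change-point detector. Per run the
label sequence yields: frequency (fraction of windows per state), mean
dwell time (mean maximal constant-label run length, in windows and in
seconds via `step × TR`), and the transition count (adjacent unequal
labels). The identity `Σ_s visits_s = transitions + 1` holds by
construction. The occupancy scan clusters at each k in a range
(default 2..8), averages per-run frequencies, flags k when more than
half its states fall below the low-occupancy band (default upper edge
4 %), and recommends the largest unflagged k — an explicit rule
standing in for a judgment usually made by eye.

**Graph metrics.** The static adjacency for a run is the full-run
correlation matrix thresholded by edgewise significance: two-sided
p-values from `t = r√((n−2)/(1−r²))` with n−2 df, Benjamini–Hochberg
across the `N(N−1)/2` unique edges at α (default 0.05); survivors keep
their signed weight. State-level graphs are cluster centroids
unvectorized and thresholded by a configured rule (absolute cutoff or
top-percentile). On the binary mask: clustering coefficient
`C_i = 2 T_i/(k_i(k_i−1))` (0 when degree < 2, where the formula is
undefined), average shortest path length as the mean BFS hop count over
*reachable* ordered pairs with the reachability fraction reported
alongside (the definition's "fully connected ⇒ PL = 1" remark only
covers connected graphs), and global efficiency `1/PL`. On the
retained weights: network strength `Σ|w|` over unique edges, node
strength over incident edges, and cost — per edge the Euclidean
distance between node centroids (mm) times `|w|`; node costs sum
incident edge costs, so `Σ_i node_cost_i = 2 × network_cost`. Negative
correlations participate through their absolute weight, and as edges
when significant. Hubs are nodes whose metric exceeds the sample mean
by more than `sd_multiplier` (default 1.5) sample SDs (ddof 1); the
metric fed in (degree, strength, or cost) is recorded, since "most
connected" is ambiguous across sections of typical reports.

**Group statistics.** Test-retest reliability is the Pearson r between
run-1 and run-2 values of each metric, per group and pooled, with
pairwise deletion and n reported. Group contrasts use Welch's unequal-
variance t-test (the robust default when no test is named). The
dominant-state analysis assigns each subject the state with maximal
mean frequency (ties to the lowest id, logged) and applies the Pearson
chi-square to the group × state table, warning when any expected count
is below 5. Correlation tables report raw r/p/n for every pair with an
*optional* BH column — adjustment is never silent.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, emulating the
two-group, two-run design of a patient/control dFC study.

**States.** K correlation matrices over N nodes with block structure:
nodes are partitioned into subnetwork blocks; state s couples the
blocks of its (distinct, smallest-first) block subset at
`coupling_strength` (default 0.8) against a zero background, unit
diagonal. Positive definiteness is verified (ridge-repaired if
marginal, hard failure otherwise); `coupling = 0` is rejected because
states would coincide.

**Dynamics.** A first-order Markov chain over states per volume
(state changes at volume boundaries — the simplest model consistent
with window-level analysis granularity). Group transition matrices are
uniform-off-diagonal sticky chains: control self-transition 0.94,
"TBI-like" 0.97. At TR 2 s these give mean dwells of ~33 s and ~67 s —
set at/above the 30 s analysis window because a sliding-window method
cannot, in principle, resolve states briefer than its window, and
empirical dFC studies report dwells in the tens of seconds.
Group-exclusive rare states are modeled by zeroing their columns in the
other group's matrix. Each subject draws private transition rows from
a Dirichlet centered on the group rows (concentration 7, structural
zeros preserved), making occupancy a subject-stable trait; the
concentration was chosen from a generator-only pilot grid as the value
maximizing the ratio of between-subject occupancy spread to within-run
sampling noise — the regime the test-retest analyses require. Runs
start from the subject's stationary distribution (a resting scan
samples ongoing dynamics at equilibrium; a non-equilibrium start was
found to inject run-level occupancy noise unrelated to the subject
trait). Sequence sampling uses one inverse-CDF draw per volume.

**Emissions.** Given labels, volumes are independent draws
`x_t ~ N(0, Σ_{s_t} + noise_sd² I)` (default noise_sd 0.5). Signals
are zero-mean with unit-variance structure because the downstream
analysis is correlation-based — means and scales are nuisance. The
generator does **not** model hemodynamic convolution, temporal
autocorrelation, motion or physiological artifacts, scanner drift
beyond what detrending removes, or spatial (voxel-level) structure.
Consequently, passing recovery tests show the *inference chain* is
correct under the stated model; they do not certify performance on
real fMRI, where autocorrelation shrinks the effective sample per
window and artifacts can masquerade as states.

**Determinism.** A cohort is a pure function of its spec (including
the seed): seeds are expanded via `SeedSequence` spawning per subject
and run, and regenerated cohorts are byte-identical on disk.

## Validation experiments and problem sizes

The test-bench experiments (in `tests/test_acceptance.py`) use, as the
package's standard validation sizes: a default cohort of 2 groups ×
20 subjects × 2 runs × 240 post-discard volumes × 20 nodes with 4
states for recovery (window-label adjusted Rand index, per-run
frequency and transition-count recovery after Hungarian alignment of
cluster ids) and across-run reliability; 20 seed replicates of a
sticky (0.95) vs mobile (0.85) one-run design for the transitions-
vs-k sweep; 200-replicate null simulations for Welch/Pearson p-value
calibration (KS against uniform) and 100 replicates of 240 × 20 null
data for FDR control of edge selection. Graph metrics are checked
against brute-force triangle enumeration and BFS oracles on every
non-isomorphic graph with ≤ 6 nodes and on random 20-node graphs; the
graphical lasso against a generic Nelder–Mead solve of the same convex
objective on 3-node chain models; k-means inertia against exhaustive
partition enumeration on ≤ 12 windows.

## Numerical choices and edge cases

- Correlations are clipped to [−1, 1] and symmetrized after weighted
  computation; `|r| = 1` maps to p = 0 in edgewise inference.
- Zero-variance inputs: QC ratio and Pearson r are reported missing
  with a warning; hub detection returns an empty set.
- Detrend is idempotent; double low-pass filtering is refused via the
  provenance flag rather than silently compounding attenuation.
- Dominant-state ties break to the lowest state id, deterministically.
- k exceeding the number of distinct windows is an error; too few
  distinct exemplars widen the phase-1 set to all windows.
- All tables are written with a provenance header (config hash, seed)
  and a sha256 manifest; reruns with identical config and seed are
  table-identical.

## Known limitations

- The i.i.d.-within-state Gaussian emission is a modeling choice; real
  component time courses are autocorrelated and the within-state noise
  spectrum is not characterized by typical study reports.
- The occupancy-scan recommendation rule (largest unflagged k) is an
  explicit heuristic; it can recommend k above the generating number
  of states when splitting populated states still leaves occupancy
  above the low band.
- Sparse-precision windowing is ~100× slower than correlation and is
  intended for targeted analyses, not the default cohort sweep.
- Reliability of *transition counts* is intrinsically lower than of
  frequencies (counts are small integers with high sampling variance),
  mirroring what such studies report.
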