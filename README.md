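# dfcstates

Dynamic functional-connectivity (dFC) state analysis for node
time-course data, with a ground-truth cohort simulator for validating
every stage of the chain.

Resting-state fMRI connectivity is not static: over a scan, whole-brain
coupling reorganizes among a small number of recurring patterns
("states"). This package implements the standard sliding-window /
k-means pipeline used to characterize those dynamics — e.g. to ask
whether a clinical group (such as traumatic brain injury patients)
shows *diminished* network dynamics: fewer transitions between states,
longer dwell times, and occupancy of states that controls never enter.
Because real studies rarely deposit their data, the package ships a
first-class synthetic-cohort generator (a hidden Markov
switching-covariance model) so that every inference — state recovery,
occupancy, transition counts, test-retest reliability, group contrasts
— can be checked against known ground truth.

## What it computes

Given per-subject, per-run node time courses (volumes × nodes, TR in
seconds, each node annotated with a subnetwork label and a 3-D centroid
in mm):

1. **Preparation** — discard initial volumes (default 4), remove linear
   trends, zero-phase low-pass below 0.15 Hz; spectral QC per node
   (dynamic range, low/high-frequency power ratio).
2. **Windowed connectivity** — sliding windows (default 15 volumes =
   30 s, step 1), per-window Pearson correlation or L1-regularized
   sparse precision (graphical lasso) reported as partial correlations.
3. **States** — pooled windows clustered by two-phase squared-Euclidean
   k-means: first on high-variability *exemplar* windows (best of
   n replicates), then one pass over all windows initialized at those
   centroids. Per run: state frequency, mean dwell time (windows and
   seconds), transition count. An occupancy scan over k = 2..8 flags
   settings where most states are nearly empty.
4. **Graph metrics** — on the FDR-thresholded (Benjamini–Hochberg,
   α = 0.05) correlation adjacency and on per-state centroid graphs:
   local clustering coefficient `C_i = 2 T_i / (k_i (k_i − 1))`,
   average shortest path length `PL = mean hop distance over reachable
   ordered pairs` (complete graph ⇒ PL = 1), global efficiency `1/PL`,
   total connections, network/node strength `Σ|w|`, distance-weighted
   network cost `Σ ‖x_i − x_j‖·|w_ij|`, and hubs (metric > mean +
   1.5 SD).
5. **Group statistics** — run 1 vs run 2 Pearson test-retest
   reliability per metric, Welch group comparison of transition counts,
   chi-square on the group × dominant-state table, and predictor ×
   outcome correlation tables with optional BH adjustment.

The API is scikit-learn-shaped: `TimeCoursePreprocessor` and
`SlidingWindowConnectivity` are transformers, `ConnectivityStateKMeans`
is a clusterer with `fit`/`predict`/`get_params`, and module-level
functions wrap them for pipeline use.

## Worked example

Run the default synthetic study (2 groups × 20 subjects × 2 runs ×
244 volumes × 20 nodes; a control-like "HC" group and a sticky
"TBI-like" group) end to end:

```python
from dfcstates import run_pipeline

res = run_pipeline({"states": {"k": 4}}, seed=1, out_dir="example_run")
print(res["transitions_compare"])
```

This writes TSV tables (QC report, state metrics, static and
state-level graph metrics, reliability, group stats — each with a
provenance header) and prints, for seed 1:

```
transitions: HC 3.08 (sd 3.11) vs TBI 0.88 (sd 1.13); Welch t = 2.97, p = 0.0066

pooled test-retest reliability:
group        metric     r   p  n
  all   freq_state1 0.805 0.0 40
  all   freq_state2 0.851 0.0 40
  all   freq_state3 0.784 0.0 40
  all   freq_state4 0.673 0.0 40
  all n_transitions 0.550 0.0 40

static graphs: mean PL 1.611, mean CC 0.251, mean connections 16
```

Reading: the sticky group switches states far less often than controls
(0.88 vs 3.08 transitions per run, Welch p ≈ 0.007 — the "diminished
dynamics" signature); state occupancy is a subject-stable trait
(frequency reliability r ≈ 0.67–0.85 across runs); and the
FDR-thresholded static graphs sit in the small-world-ish regime
(PL ≈ 1.6 on 20 nodes).

The same analysis is available from the shell:

```bash
dfcstates run --config my_config.yaml --seed 1 --out example_run
dfcstates simulate --seed 1 --out cohort_only   # generator alone
dfcstates validate --config my_config.yaml
```

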