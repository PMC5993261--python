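"""Recurring connectivity states via exemplar-initialized k-means.

Windowed connectivity from all subject-runs is pooled in edge space and
clustered with squared-Euclidean k-means in two phases: (1) k-means
(best of ``n_replicates`` by inertia) on high-variability "exemplar"
windows — local maxima over window index of the across-edge variance —
then (2) a single k-means pass over every window initialized at the
phase-1 centroids. Per subject-run, the resulting window labels yield
the state summary statistics: occupancy frequency, mean dwell time, and
the number of state transitions. An occupancy scan over a range of k
flags settings where most states are nearly empty and recommends the
largest unflagged k.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "StatePartition", "StateMetrics", "select_exemplars",
    "ConnectivityStateKMeans", "cluster_states", "state_metrics",
    "occupancy_scan", "transitions_vs_k", "split_labels",
]


@dataclass
class StatePartition:
    """k centroids in edge space plus per-run 1-based window labels."""
    k: int
    centroids: np.ndarray              # (k, n_edges)
    labels: dict                       # run key -> 1-based label array
    inertia: float
    seed: int | None = None
    n_replicates: int = 5

    def all_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[key] for key in self.labels])


@dataclass
class StateMetrics:
    """Per subject-run state summary.

    ``frequency[s]`` is the fraction of windows labeled ``s`` (1-based);
    ``mean_dwell[s]`` the mean maximal run length in windows (NaN when
    state never visited); ``n_transitions`` the count of adjacent label
    changes.
    """
    k: int
    frequency: np.ndarray
    mean_dwell: np.ndarray
    n_transitions: int
    n_windows: int
    mean_dwell_seconds: np.ndarray | None = None


def _variance_profile(features: np.ndarray) -> np.ndarray:
    """Across-edge variance of each window's connectivity vector."""
    return features.var(axis=1)


def select_exemplars(features: np.ndarray, run_lengths=None) -> np.ndarray:
    """Indices of exemplar windows (pooled indexing).

    Within each run, exemplars are the windows at local maxima of the
    across-edge variance profile; a boundary window counts as a local
    maximum when it exceeds its single neighbor. Flat (all-constant)
    profiles fall back to uniform subsampling with a warning.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if run_lengths is None:
        run_lengths = [n]
    if sum(run_lengths) != n:
        raise ValueError("run_lengths must sum to the number of windows")
    out, offset = [], 0
    for L in run_lengths:
        prof = _variance_profile(features[offset:offset + L])
        idx = _local_maxima(prof)
        if idx.size == 0:
            warnings.warn("flat variance profile; falling back to uniform "
                          "exemplar subsampling", RuntimeWarning,
                          stacklevel=2)
            idx = np.arange(0, L, max(1, L // 8))
        out.append(idx + offset)
        offset += L
    return np.concatenate(out)


def _local_maxima(prof: np.ndarray) -> np.ndarray:
    n = prof.size
    if n == 1:
        return np.array([0])
    if np.ptp(prof) == 0:
        return np.array([], dtype=int)
    keep = []
    for i in range(n):
        left = prof[i - 1] if i > 0 else -np.inf
        right = prof[i + 1] if i < n - 1 else -np.inf
        if i == 0:
            if prof[0] > prof[1]:
                keep.append(i)
        elif i == n - 1:
            if prof[-1] > prof[-2]:
                keep.append(i)
        elif prof[i] >= left and prof[i] >= right and (prof[i] > left or
                                                       prof[i] > right):
            keep.append(i)
    return np.array(keep, dtype=int)


class ConnectivityStateKMeans(BaseEstimator, ClusterMixin):
    """Two-phase exemplar-initialized k-means over windowed connectivity.

    Parameters
    ----------
    n_states : int, default 6
        Number of connectivity states (k).
    n_replicates : int, default 5
        Phase-1 restarts on the exemplar windows; the best replicate by
        inertia seeds the single phase-2 pass over all windows.
    random_state : int or None
        Seeds both phases; fixed seed gives a deterministic partition.

    Attributes
    ----------
    cluster_centers_ : (n_states, n_edges) final centroids.
    labels_ : 0-based window labels (sklearn convention; the pipeline's
        state ids are ``labels_ + 1``).
    inertia_ : within-cluster sum of squared Euclidean distances.
    exemplar_indices_ : pooled indices of the phase-1 exemplar windows.
    """

    def __init__(self, n_states: int = 6, n_replicates: int = 5,
                 random_state=None):
        self.n_states = n_states
        self.n_replicates = n_replicates
        self.random_state = random_state

    def fit(self, X, y=None, run_lengths=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (windows x edges)")
        k = self.n_states
        if k < 2:
            raise ValueError("n_states must be >= 2")
        n_distinct = np.unique(X, axis=0).shape[0]
        if k > n_distinct:
            raise ValueError(
                f"k={k} exceeds the {n_distinct} distinct windows")
        ex = select_exemplars(X, run_lengths=run_lengths)
        if np.unique(X[ex], axis=0).shape[0] < k:
            # too few distinct exemplars to seed k clusters: widen to all
            ex = np.arange(X.shape[0])
        phase1 = KMeans(n_clusters=k, n_init=self.n_replicates,
                        init="k-means++", random_state=self.random_state)
        phase1.fit(X[ex])
        phase2 = KMeans(n_clusters=k, n_init=1,
                        init=phase1.cluster_centers_,
                        random_state=self.random_state)
        phase2.fit(X)
        self.exemplar_indices_ = ex
        self.cluster_centers_ = phase2.cluster_centers_
        self.labels_ = phase2.labels_
        self.inertia_ = float(phase2.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(-1)
        return d.argmin(axis=1)


def split_labels(labels: np.ndarray, run_keys, run_lengths) -> dict:
    """Split pooled labels back into per-run arrays."""
    out, offset = {}, 0
    for key, L in zip(run_keys, run_lengths):
        out[key] = labels[offset:offset + L]
        offset += L
    return out


def cluster_states(window_features: np.ndarray, k: int, seed=None,
                   n_replicates: int = 5, run_keys=None,
                   run_lengths=None) -> StatePartition:
    """Pooled two-phase k-means; returns a 1-based :class:`StatePartition`."""
    est = ConnectivityStateKMeans(n_states=k, n_replicates=n_replicates,
                                  random_state=seed)
    est.fit(window_features, run_lengths=run_lengths)
    labels1 = est.labels_ + 1
    if run_keys is None:
        n = window_features.shape[0]
        run_keys, run_lengths = ["all"], [n]
    labels = split_labels(labels1, run_keys, run_lengths)
    return StatePartition(k=k, centroids=est.cluster_centers_, labels=labels,
                          inertia=est.inertia_, seed=seed,
                          n_replicates=n_replicates)


def state_metrics(labels, k: int | None = None,
                  window_step_seconds: float | None = None) -> StateMetrics:
    """Frequency, mean dwell time and transition count of a label run.

    ``labels`` are 1-based state ids in temporal window order. The
    identity ``sum_s visits_s = n_transitions + 1`` holds by
    construction.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if k is None:
        k = int(labels.max())
    n = labels.size
    freq = np.array([(labels == s).mean() for s in range(1, k + 1)])
    # maximal constant runs
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    dwell = np.full(k, np.nan)
    for s in range(1, k + 1):
        runs = ends[labels[starts] == s] - starts[labels[starts] == s]
        if runs.size:
            dwell[s - 1] = runs.mean()
    nt = int(change.size)
    dwell_sec = dwell * window_step_seconds if window_step_seconds else None
    return StateMetrics(k=k, frequency=freq, mean_dwell=dwell,
                        n_transitions=nt, n_windows=n,
                        mean_dwell_seconds=dwell_sec)


def occupancy_scan(window_features: np.ndarray, k_range=range(2, 9),
                   low_band=(0.02, 0.04), seed=None, n_replicates: int = 5,
                   run_keys=None, run_lengths=None) -> pd.DataFrame:
    """Cluster at each k and flag settings dominated by near-empty states.

    For each k the per-run state frequencies are averaged across runs; a
    k is flagged when more than half of its states have mean frequency
    below the upper edge of ``low_band`` (the "very low occupancy" band,
    default 2-4%). The recommended k is the largest unflagged k — or the
    smallest k overall if every setting is flagged.

    Returns a DataFrame with one row per k, mean frequencies as a list
    column, ``n_low_states``, ``flagged``, and ``recommended``.
    """
    rows = []
    for k in k_range:
        part = cluster_states(window_features, k, seed=seed,
                              n_replicates=n_replicates, run_keys=run_keys,
                              run_lengths=run_lengths)
        freqs = np.array([state_metrics(lab, k=k).frequency
                          for lab in part.labels.values()])
        mean_freq = freqs.mean(axis=0)
        n_low = int((mean_freq < low_band[1]).sum())
        rows.append({"k": k, "mean_frequencies": mean_freq.tolist(),
                     "n_low_states": n_low, "flagged": n_low > k / 2})
    df = pd.DataFrame(rows)
    unflagged = df.loc[~df["flagged"], "k"]
    rec = int(unflagged.max()) if len(unflagged) else int(df["k"].min())
    df["recommended"] = df["k"] == rec
    return df


def transitions_vs_k(window_features: np.ndarray, run_keys, run_lengths,
                     subject_of_run: dict, group_of_subject: dict,
                     k_range=range(2, 9), seed=None,
                     n_replicates: int = 5) -> pd.DataFrame:
    """Group-mean transition counts as a function of k, with a Welch test.

    For each k, windows are clustered jointly, transition counts are
    computed per run and averaged within subject, and the two groups are
    compared with Welch's t-test. Returns one row per k with per-group
    means, SEs and the p-value.
    """
    groups = sorted(set(group_of_subject.values()))
    if len(groups) != 2:
        raise ValueError("transitions_vs_k expects exactly 2 groups")
    rows = []
    for k in k_range:
        part = cluster_states(window_features, k, seed=seed,
                              n_replicates=n_replicates, run_keys=run_keys,
                              run_lengths=run_lengths)
        per_subject = {}
        for key, lab in part.labels.items():
            subj = subject_of_run[key]
            per_subject.setdefault(subj, []).append(
                state_metrics(lab, k=k).n_transitions)
        vals = {g: [] for g in groups}
        for subj, counts in per_subject.items():
            vals[group_of_subject[subj]].append(float(np.mean(counts)))
        a, b = (np.asarray(vals[g]) for g in groups)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "k": k,
            f"mean_{groups[0]}": a.mean(), f"mean_{groups[1]}": b.mean(),
            f"se_{groups[0]}": a.std(ddof=1) / np.sqrt(a.size),
            f"se_{groups[1]}": b.std(ddof=1) / np.sqrt(b.size),
            "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows)
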