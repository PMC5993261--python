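"""Synthetic cohorts of piecewise-stationary multivariate time series.

The generator emulates the data a dynamic functional-connectivity study
works from: per-subject, per-run node time courses whose covariance
switches among K latent connectivity "states" under a hidden Markov
chain. Each state is a correlation matrix with block structure over
subnetworks (strongly coupled blocks on a weak background), transition
dynamics are group-specific (e.g. a "sticky" injured-like group with
higher self-transition probability and optional group-exclusive rare
states), and subjects within a group get their own transition matrix by
Dirichlet perturbation of the group rows so that state occupancy is a
stable, subject-level trait — the property test-retest reliability
analyses rely on.

Emissions are i.i.d. Gaussian within a state: at volume t with active
state s, x_t ~ N(0, Sigma_s + noise_sd^2 I). State changes occur at
volume boundaries. No hemodynamics, autocorrelation or motion artifacts
are modeled.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ComponentTimeSeries, make_node_meta

__all__ = [
    "StateLibrary", "TransitionModel", "CohortSpec", "SubjectRecord",
    "build_state_library", "sample_state_sequence", "generate_subject_run",
    "generate_cohort", "make_group_transition_model", "default_cohort_spec",
    "count_transitions",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class StateLibrary:
    """K symmetric positive-definite correlation matrices (the latent states).

    ``block_design[s]`` records which subnetwork blocks are strongly
    coupled in state ``s`` (a tuple of block labels).
    """
    covariances: list
    state_ids: list
    block_design: list

    def __post_init__(self):
        if len(self.covariances) < 2:
            raise ValueError("a state library needs K >= 2 states")
        n = self.covariances[0].shape[0]
        for s, cov in zip(self.state_ids, self.covariances):
            if cov.shape != (n, n):
                raise ValueError("all state covariances must share a dimension")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {s} covariance is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
                raise ValueError(f"state {s} is not on correlation scale")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"state {s} covariance is not positive definite")

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_nodes(self) -> int:
        return self.covariances[0].shape[0]

    def covariance_of(self, state_id) -> np.ndarray:
        return self.covariances[self.state_ids.index(state_id)]


@dataclass
class TransitionModel:
    """Row-stochastic K x K transition matrix plus initial distribution."""
    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.matrix.shape[0]
        if self.matrix.shape != (K, K):
            raise ValueError("transition matrix must be square")
        if self.initial.shape != (K,):
            raise ValueError("initial distribution length must match K")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector, normalized)."""
        w, v = np.linalg.eig(self.matrix.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class CohortSpec:
    """Full description of a synthetic two-(or more-)group cohort."""
    library: StateLibrary
    groups: dict                     # name -> TransitionModel
    n_subjects_per_group: int = 20
    n_runs: int = 2
    n_volumes: int = 240
    tr_seconds: float = 2.0
    noise_sd: float = 0.5
    subject_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.subject_concentration <= 0:
            raise ValueError("subject_concentration must be positive")
        names = list(self.groups)
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for name, tm in self.groups.items():
            if tm.n_states != self.library.n_states:
                raise ValueError(
                    f"group '{name}' transition model has {tm.n_states} states "
                    f"but the library has {self.library.n_states}")


@dataclass
class SubjectRecord:
    """One simulated subject: per-run time series plus ground-truth labels."""
    subject_id: str
    group: str
    runs: list = field(default_factory=list)          # ComponentTimeSeries
    state_sequences: list = field(default_factory=list)  # ndarray per run
    transition_model: TransitionModel | None = None


# ---------------------------------------------------------------------------
# construction

def _block_subsets(n_blocks: int):
    """Nonempty block subsets ordered by size then lexicographically."""
    for size in range(1, n_blocks + 1):
        yield from itertools.combinations(range(n_blocks), size)


def build_state_library(n_states: int, n_nodes: int, network_labels,
                        coupling_strength: float = 0.8,
                        background: float = 0.0,
                        seed: int | None = None) -> StateLibrary:
    """Construct K distinct SPD correlation matrices with block structure.

    Nodes are partitioned into subnetwork blocks by ``network_labels``;
    state ``s`` couples the nodes inside each block of its subset at
    correlation ``coupling_strength`` (blocks outside the subset stay at
    the ``background`` level). Subsets are assigned smallest-first, so
    with K <= number of blocks each state activates one subnetwork.

    Raises if the requested K exceeds the number of distinct block
    patterns, if ``coupling_strength`` is 0 (all states would coincide),
    or if a matrix cannot be repaired to positive definiteness.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    labels = list(network_labels)
    if len(labels) != n_nodes:
        raise ValueError("network_labels must have one entry per node")
    blocks = sorted(set(labels), key=lambda b: labels.index(b))
    if len(blocks) < 2:
        raise ValueError("network_labels must define at least 2 blocks")
    if not -1.0 < coupling_strength < 1.0:
        raise ValueError("coupling_strength must lie in (-1, 1)")
    if coupling_strength == 0:
        raise ValueError(
            "coupling_strength 0 makes every state the identity matrix; "
            "states must be distinct")
    n_patterns = 2 ** len(blocks) - 1
    if n_states > n_patterns:
        raise ValueError(
            f"{n_states} states requested but only {n_patterns} distinct "
            f"block patterns exist for {len(blocks)} blocks")

    member = {b: np.array([l == b for l in labels]) for b in blocks}
    covariances, design = [], []
    for subset in itertools.islice(_block_subsets(len(blocks)), n_states):
        C = np.full((n_nodes, n_nodes), float(background))
        for bi in subset:
            m = member[blocks[bi]]
            C[np.ix_(m, m)] = coupling_strength
        np.fill_diagonal(C, 1.0)
        C = _repair_spd(C, tuple(blocks[bi] for bi in subset))
        covariances.append(C)
        design.append(tuple(blocks[bi] for bi in subset))

    lib = StateLibrary(covariances=covariances,
                       state_ids=list(range(1, n_states + 1)),
                       block_design=design)
    # distinctness: strictly positive pairwise Frobenius separation
    for a, b in itertools.combinations(range(n_states), 2):
        if np.linalg.norm(covariances[a] - covariances[b]) <= 0:
            raise ValueError(f"states {a + 1} and {b + 1} are not distinct")
    return lib


def _repair_spd(C: np.ndarray, label) -> np.ndarray:
    """Ridge-repair a near-PD correlation matrix; hard-fail if impossible."""
    lo = np.linalg.eigvalsh(C).min()
    if lo > 1e-8:
        return C
    ridge = 1e-6 - lo
    C = (C + ridge * np.eye(C.shape[0])) / (1.0 + ridge)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError(
            f"state with coupled blocks {label} is not positive definite "
            f"even after ridge repair (min eigenvalue {lo:.3e})")
    return C


# ---------------------------------------------------------------------------
# sampling

def sample_state_sequence(model: TransitionModel, n_volumes: int,
                          seed=None) -> np.ndarray:
    """Sample a length-``n_volumes`` state-id sequence (ids 1..K).

    The chain starts from ``model.initial``. Empirical transition
    frequencies converge to ``model.matrix`` as the sequence grows.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.n_states
    # inverse-CDF sampling with one uniform per volume
    u = rng.random(n_volumes)
    cdf_rows = np.cumsum(model.matrix, axis=1)
    seq = np.empty(n_volumes, dtype=int)
    seq[0] = np.searchsorted(np.cumsum(model.initial), u[0], side="right")
    for t in range(1, n_volumes):
        seq[t] = np.searchsorted(cdf_rows[seq[t - 1]], u[t], side="right")
    return np.minimum(seq, K - 1) + 1  # guard fp round-up; 1-based ids


def count_transitions(labels) -> int:
    """Number of adjacent unequal label pairs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0
    return int(np.sum(labels[1:] != labels[:-1]))


def generate_subject_run(library: StateLibrary, label_sequence,
                         noise_sd: float = 0.5, seed=None,
                         tr_seconds: float = 2.0,
                         node_meta: pd.DataFrame | None = None,
                         subject_id: str = "", run_id: str = ""
                         ) -> ComponentTimeSeries:
    """Emit Gaussian observations for a given ground-truth label sequence.

    At each volume the observation is drawn from N(0, Sigma_state +
    noise_sd^2 I); volumes are independent given the labels.
    """
    labels = np.asarray(label_sequence)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    unknown = set(labels.tolist()) - set(library.state_ids)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in the state library")
    rng = np.random.default_rng(seed)
    n, p = labels.size, library.n_nodes
    z = rng.standard_normal((n, p))
    X = np.empty((n, p))
    eye = noise_sd ** 2 * np.eye(p)
    for sid in library.state_ids:
        mask = labels == sid
        if not mask.any():
            continue
        L = np.linalg.cholesky(library.covariance_of(sid) + eye)
        X[mask] = z[mask] @ L.T
    return ComponentTimeSeries(data=X, tr_seconds=tr_seconds,
                               subject_id=subject_id, run_id=run_id,
                               node_meta=node_meta)


def _perturb_transition_model(group_model: TransitionModel,
                              concentration: float,
                              rng: np.random.Generator) -> TransitionModel:
    """Subject-level transition matrix: Dirichlet around each group row.

    Structural zeros (e.g. columns of group-exclusive states zeroed for
    the other group) are preserved exactly.
    """
    gm = group_model.matrix
    out = np.zeros_like(gm)
    for i in range(gm.shape[0]):
        pos = gm[i] > 0
        out[i, pos] = rng.dirichlet(concentration * gm[i, pos])
    # runs sample the subject's ongoing dynamics: start at equilibrium
    tm = TransitionModel(matrix=out, initial=group_model.initial.copy())
    pi = tm.stationary()
    reachable = group_model.initial > 0
    pi = np.where(reachable, pi, 0.0)
    tm.initial = pi / pi.sum()
    return tm


def generate_cohort(spec: CohortSpec) -> list:
    """Generate the full cohort; a pure function of the spec (incl. seed).

    Each subject gets a private transition matrix drawn around its group
    model (Dirichlet, ``spec.subject_concentration``), then ``n_runs``
    independent label sequences and emissions from that same matrix, so
    state occupancy is a subject-stable trait across runs.
    """
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    networks = _default_networks(spec.library)
    node_meta = make_node_meta(spec.library.n_nodes, networks=networks,
                               rng=meta_rng)
    cohort = []
    idx = 0
    for gname in spec.groups:
        gmodel = spec.groups[gname]
        for s in range(spec.n_subjects_per_group):
            idx += 1
            sid = f"{gname}-{s + 1:03d}"
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            tm = _perturb_transition_model(gmodel, spec.subject_concentration,
                                           rng)
            rec = SubjectRecord(subject_id=sid, group=gname,
                                transition_model=tm)
            for r in range(spec.n_runs):
                run_ss, emit_ss = ss.spawn(2)
                seq = sample_state_sequence(tm, spec.n_volumes, seed=run_ss)
                ts = generate_subject_run(
                    spec.library, seq, noise_sd=spec.noise_sd, seed=emit_ss,
                    tr_seconds=spec.tr_seconds, node_meta=node_meta,
                    subject_id=sid, run_id=f"run{r + 1}")
                rec.runs.append(ts)
                rec.state_sequences.append(seq)
            cohort.append(rec)
    return cohort


def _default_networks(library: StateLibrary):
    """Per-node subnetwork labels consistent with the library's blocks."""
    n = library.n_nodes
    all_blocks = sorted({b for design in library.block_design for b in design})
    if not all_blocks:
        return None
    per = int(np.ceil(n / len(all_blocks)))
    return [all_blocks[min(i // per, len(all_blocks) - 1)] for i in range(n)]


# ---------------------------------------------------------------------------
# ready-made study designs

def make_group_transition_model(n_states: int, self_prob: float,
                                excluded_states=()) -> TransitionModel:
    """Uniform-off-diagonal sticky chain; optionally bar some states.

    ``excluded_states`` (1-based ids) get zero columns — the group never
    enters them — mirroring designs where rare states are exclusive to
    one group.
    """
    if not 0.0 <= self_prob <= 1.0:
        raise ValueError("self_prob must lie in [0, 1]")
    K = n_states
    excluded = {s - 1 for s in excluded_states}
    allowed = [j for j in range(K) if j not in excluded]
    if len(allowed) < 2:
        raise ValueError("need at least two reachable states")
    M = np.zeros((K, K))
    for i in range(K):
        targets = [j for j in allowed if j != i]
        if i in excluded or not targets:
            # unreachable row: park uniformly on allowed states
            M[i, allowed] = 1.0 / len(allowed)
            continue
        M[i, i] = self_prob
        M[i, targets] = (1.0 - self_prob) / len(targets)
    init = np.zeros(K)
    init[allowed] = 1.0 / len(allowed)
    return TransitionModel(matrix=M, initial=init)


def default_cohort_spec(seed: int = 0, n_states: int = 4, n_nodes: int = 20,
                        n_subjects_per_group: int = 20, n_runs: int = 2,
                        n_volumes: int = 240, coupling_strength: float = 0.8,
                        noise_sd: float = 0.5,
                        control_self_prob: float = 0.94,
                        sticky_self_prob: float = 0.97,
                        subject_concentration: float = 7.0) -> CohortSpec:
    """The default two-group study design used throughout the test-bench.

    A control-like group with moderate state persistence (mean dwell
    ~17 volumes = 33 s at TR 2 s, at or above the 15-volume analysis
    window so states are resolvable by a windowed method) and a
    "TBI-like" group with stickier self-transitions (~67 s dwell);
    4 well-separated block states over 20 nodes, 2 runs of 240 volumes
    at TR = 2 s. Subject heterogeneity (Dirichlet concentration 7)
    makes state occupancy a subject-stable trait whose between-subject
    spread dominates within-run sampling noise.
    """
    n_blocks = max(2, min(n_states, 8))
    per = int(np.ceil(n_nodes / n_blocks))
    from .containers import SUBNETWORKS
    labels = [SUBNETWORKS[min(i // per, n_blocks - 1)] for i in range(n_nodes)]
    library = build_state_library(n_states, n_nodes, labels,
                                  coupling_strength=coupling_strength)
    groups = {
        "HC": make_group_transition_model(n_states, control_self_prob),
        "TBI": make_group_transition_model(n_states, sticky_self_prob),
    }
    return CohortSpec(library=library, groups=groups,
                      n_subjects_per_group=n_subjects_per_group,
                      n_runs=n_runs, n_volumes=n_volumes,
                      noise_sd=noise_sd,
                      subject_concentration=subject_concentration, seed=seed)
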