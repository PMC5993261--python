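import numpy as np
import pytest

from dfcstates import (ComponentTimeSeries, build_state_library,
                       default_cohort_spec, generate_cohort, make_node_meta)


@pytest.fixture(scope="session")
def small_library():
    """2 states over 4 nodes, two blocks of two, coupling 0.8."""
    return build_state_library(2, 4, ["A", "A", "B", "B"],
                               coupling_strength=0.8)


@pytest.fixture(scope="session")
def four_state_library():
    """4 block states over 20 nodes (the default study design geometry)."""
    labels = [chr(65 + i // 5) for i in range(20)]
    return build_state_library(4, 20, labels, coupling_strength=0.8)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 groups x 3 subjects x 2 runs x 100 volumes x 12 nodes, 3 states."""
    spec = default_cohort_spec(seed=42, n_states=3, n_nodes=12,
                               n_subjects_per_group=3, n_runs=2,
                               n_volumes=100)
    return spec, generate_cohort(spec)


@pytest.fixture
def sine_ts():
    """240-volume, 3-node series at TR 2 s with known spectral content."""
    t = np.arange(240) * 2.0
    rng = np.random.default_rng(0)
    data = np.column_stack([
        np.sin(2 * np.pi * 0.05 * t),
        np.sin(2 * np.pi * 0.24 * t),
        rng.standard_normal(240),
    ])
    return ComponentTimeSeries(data=data, tr_seconds=2.0,
                               node_meta=make_node_meta(3))
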