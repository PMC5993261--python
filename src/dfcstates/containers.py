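"""Core in-memory containers shared across the pipeline.

The central object is :class:`ComponentTimeSeries`: one subject-run's
node (ICA-component) time courses as a volumes x nodes matrix, together
with the sampling interval (TR) and per-node metadata (subnetwork label
and 3-D centroid in mm). Downstream stages attach provenance flags so
that, e.g., windowed connectivity refuses to run on unprepared data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical subnetwork labels used for node metadata.
SUBNETWORKS = ("Aud", "ECN", "DMN", "SM", "SN", "Visual", "Cerebellar", "Other")

NODE_META_COLUMNS = ("node_id", "network", "x", "y", "z")


def make_node_meta(n_nodes: int,
                   networks=None,
                   coords: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Build a node-metadata table (id, subnetwork label, centroid in mm).

    If ``coords`` is omitted, centroids are drawn uniformly inside a
    brain-sized bounding box (+-70, +-90, +-60 mm) using ``rng``.
    """
    if networks is None:
        networks = [SUBNETWORKS[i % len(SUBNETWORKS)] for i in range(n_nodes)]
    if len(networks) != n_nodes:
        raise ValueError(f"networks has length {len(networks)}, expected {n_nodes}")
    if coords is None:
        if rng is None:
            rng = np.random.default_rng(0)
        coords = rng.uniform([-70.0, -90.0, -60.0], [70.0, 90.0, 60.0],
                             size=(n_nodes, 3))
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n_nodes, 3):
        raise ValueError(f"coords has shape {coords.shape}, expected ({n_nodes}, 3)")
    return pd.DataFrame({
        "node_id": [f"IC{i + 1:02d}" for i in range(n_nodes)],
        "network": list(networks),
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    })


@dataclass
class ComponentTimeSeries:
    """Volumes x nodes signal matrix for one subject-run.

    Attributes
    ----------
    data : ndarray, shape (n_volumes, n_nodes)
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    node_meta : DataFrame with columns node_id, network, x, y, z.
    prep_flags : set of str
        Provenance of preprocessing steps already applied
        ("discarded", "detrended", "filtered").
    """
    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    run_id: str = ""
    node_meta: pd.DataFrame | None = None
    prep_flags: set = field(default_factory=set)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D volumes x nodes matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_meta is None:
            self.node_meta = make_node_meta(self.data.shape[1])
        if len(self.node_meta) != self.data.shape[1]:
            raise ValueError(
                f"node_meta has {len(self.node_meta)} rows for "
                f"{self.data.shape[1]} data columns")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    def with_data(self, data: np.ndarray, extra_flag: str | None = None
                  ) -> "ComponentTimeSeries":
        """Copy of self with new data and (optionally) one more prep flag."""
        flags = set(self.prep_flags)
        if extra_flag:
            flags.add(extra_flag)
        return replace(self, data=np.asarray(data, dtype=float),
                       prep_flags=flags)

    def coords(self) -> np.ndarray:
        return self.node_meta[["x", "y", "z"]].to_numpy(dtype=float)
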