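"""Cluster formation from raw pixel hits.

A cluster is a group of fired pixels produced by one ionizing particle:
charge diffusion and electrostatic repulsion spread the collected charge
over several neighboring pixels.  Two hits belong to the same cluster iff
they are connected by a chain of 8-adjacent hits (diagonals included; two
hits on the *same* pixel also count as neighbors) whose pairwise arrival
time differences do not exceed the coincidence window (default 850 ns).
The time criterion is applied pairwise along the chain, not to the global
cluster span.

Noise rejection: clusters below a low-energy cutoff on the volume
(default 30 keV) and single-pixel clusters are removed.

An optional second merge pass repairs clusters cropped by erroneous
timestamp assignments: spatially abutting clusters whose reference times
differ by less than a repair window are rejoined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import Cluster, cluster_table, validate_hits
from .errors import ConfigurationError

DEFAULT_DT_MAX_NS = 850.0
DEFAULT_CUTOFF_KEV = 30.0


class _DisjointSet:
    """Union-find with path compression (internal)."""

    def __init__(self, n):
        self.parent = np.arange(n)

    def find(self, i):
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:  # path compression
            p[i], i = root, p[i]
        return root

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_clusters(hits: pd.DataFrame, dt_max_ns: float = DEFAULT_DT_MAX_NS,
                   repair_window_ns: float | None = None) -> list[Cluster]:
    """Partition pixel hits into clusters by 8-adjacency and time coincidence.

    Parameters
    ----------
    hits : DataFrame with columns x, y, toa_ns, energy_keV
    dt_max_ns : maximum allowed time difference between neighboring pixels
    repair_window_ns : if set, spatially abutting clusters whose reference
        times differ by less than this window are merged in a second pass
        (cropped-cluster repair)

    Returns
    -------
    list of Cluster, deterministically ordered by (t_ref_ns, x, y of the
    earliest hit).  An empty input yields an empty list.
    """
    if not dt_max_ns > 0:
        raise ConfigurationError("dt_max_ns must be positive")
    validate_hits(hits)
    n = len(hits)
    if n == 0:
        return []

    x = hits["x"].to_numpy(dtype=np.int64)
    y = hits["y"].to_numpy(dtype=np.int64)
    toa = hits["toa_ns"].to_numpy(dtype=np.float64)
    energy = hits["energy_keV"].to_numpy(dtype=np.float64)

    # Index hits by pixel so neighbor lookup is O(1) per (pixel, offset).
    by_pixel: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        by_pixel.setdefault((int(x[i]), int(y[i])), []).append(i)

    ds = _DisjointSet(n)
    offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    for i in range(n):
        xi, yi, ti = int(x[i]), int(y[i]), toa[i]
        for dx, dy in offsets:
            for j in by_pixel.get((xi + dx, yi + dy), ()):
                if j > i and abs(toa[j] - ti) <= dt_max_ns:
                    ds.union(i, j)

    roots = np.fromiter((ds.find(i) for i in range(n)), dtype=np.int64, count=n)

    if repair_window_ns is not None:
        roots = _repair_cropped(roots, x, y, toa, ds, repair_window_ns)

    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(int(r), []).append(i)

    clusters = []
    for idx in groups.values():
        idx = np.asarray(idx)
        order = np.lexsort((y[idx], x[idx], toa[idx]))
        idx = idx[order]
        clusters.append(Cluster(x[idx], y[idx], toa[idx], energy[idx]))
    clusters.sort(key=lambda c: (c.t_ref_ns, int(c.x[0]), int(c.y[0])))
    return clusters


def _repair_cropped(roots, x, y, toa, ds, repair_window_ns):
    """Second pass: merge spatially abutting clusters with close reference times.

    Erroneous timestamps can split one physical cluster in two; the repaired
    partition joins fragments whose pixel footprints touch (chebyshev
    distance <= 1) and whose earliest times differ by < repair_window_ns.
    """
    if not repair_window_ns > 0:
        raise ConfigurationError("repair_window_ns must be positive")
    # Reference time per current cluster root.
    t_ref: dict[int, float] = {}
    for i, r in enumerate(roots):
        r = int(r)
        t_ref[r] = min(t_ref.get(r, np.inf), toa[i])
    by_pixel: dict[tuple[int, int], list[int]] = {}
    n = len(roots)
    for i in range(n):
        by_pixel.setdefault((int(x[i]), int(y[i])), []).append(i)
    offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    for i in range(n):
        ri = ds.find(i)
        for dx, dy in offsets:
            for j in by_pixel.get((int(x[i]) + dx, int(y[i]) + dy), ()):
                rj = ds.find(j)
                if ri != rj and abs(t_ref[int(roots[i])] - t_ref[int(roots[j])]) < repair_window_ns:
                    ds.union(i, j)
                    ri = ds.find(i)
    return np.fromiter((ds.find(i) for i in range(n)), dtype=np.int64, count=n)


def apply_low_energy_cutoff(clusters, cutoff_keV: float = DEFAULT_CUTOFF_KEV) -> list[Cluster]:
    """Drop low-volume clusters and single-pixel (noise) clusters.

    A cluster survives iff ``volume_keV >= cutoff_keV`` and ``size >= 2``;
    single-pixel signals are rejected as noise regardless of the cutoff.
    """
    if cutoff_keV < 0:
        raise ConfigurationError("cutoff_keV must be >= 0")
    return [c for c in clusters if c.size >= 2 and c.volume_keV >= cutoff_keV]


class ClusterBuilder(BaseEstimator, TransformerMixin):
    """Estimator facade over cluster formation plus noise rejection.

    ``transform`` consumes a hit table (columns x, y, toa_ns, energy_keV)
    and returns the cluster summary table (size, volume_keV, t_ref_ns,
    cx, cy) after the low-energy cutoff.  Use :meth:`build` for the full
    Cluster objects, and ``apply_cutoff=False`` to keep the raw partition.

    Attributes
    ----------
    n_hits_in_ : number of input hits seen by the last transform
    n_clusters_raw_ : clusters before the cutoff
    n_clusters_ : clusters after the cutoff
    n_dropped_ : clusters removed by the cutoff / single-pixel rejection
    """

    def __init__(self, dt_max_ns: float = DEFAULT_DT_MAX_NS,
                 cutoff_keV: float = DEFAULT_CUTOFF_KEV,
                 repair_window_ns: float | None = None,
                 apply_cutoff: bool = True):
        self.dt_max_ns = dt_max_ns
        self.cutoff_keV = cutoff_keV
        self.repair_window_ns = repair_window_ns
        self.apply_cutoff = apply_cutoff

    def fit(self, X, y=None):
        if not self.dt_max_ns > 0:
            raise ConfigurationError("dt_max_ns must be positive")
        return self

    def build(self, hits: pd.DataFrame) -> list[Cluster]:
        raw = build_clusters(hits, self.dt_max_ns, self.repair_window_ns)
        self.n_hits_in_ = len(hits)
        self.n_clusters_raw_ = len(raw)
        out = apply_low_energy_cutoff(raw, self.cutoff_keV) if self.apply_cutoff else raw
        self.n_clusters_ = len(out)
        self.n_dropped_ = self.n_clusters_raw_ - self.n_clusters_
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return cluster_table(self.build(X))
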