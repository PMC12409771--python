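"""Cluster formation: adjacency, time coincidence, cutoff, conservation."""

import numpy as np
import pandas as pd
import pytest

from pixelet import (ClusterBuilder, apply_low_energy_cutoff, build_clusters,
                     hits_to_frame)
from pixelet.datatypes import Cluster
from pixelet.errors import ConfigurationError, GeometryError


def make_hits(rows):
    return pd.DataFrame(rows, columns=["x", "y", "toa_ns", "energy_keV"])


def oracle_partition(hits, dt_max_ns):
    """Independent oracle: BFS over the full pairwise neighbor graph."""
    n = len(hits)
    x = hits["x"].to_numpy()
    y = hits["y"].to_numpy()
    t = hits["toa_ns"].to_numpy()
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if max(abs(x[i] - x[j]), abs(y[i] - y[j])) <= 1 and abs(t[i] - t[j]) <= dt_max_ns:
                adj[i].append(j)
                adj[j].append(i)
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    return comp


def partition_as_sets(clusters):
    return {frozenset(zip(c.x, c.y, c.toa_ns)) for c in clusters}


class TestBuildClusters:
    def test_adjacent_coincident_hits_form_one_cluster(self):
        hits = make_hits([(10, 10, 0.0, 50.0), (10, 11, 0.0, 60.0), (11, 10, 0.0, 70.0)])
        clusters = build_clusters(hits)
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert clusters[0].volume_keV == pytest.approx(180.0)

    def test_coincidence_window_splits_late_neighbor(self):
        hits = make_hits([(10, 10, 0.0, 50.0), (10, 11, 900.0, 60.0)])
        clusters = build_clusters(hits, dt_max_ns=850.0)
        assert [c.size for c in clusters] == [1, 1]
        # inside the window the same pair merges
        hits2 = make_hits([(10, 10, 0.0, 50.0), (10, 11, 800.0, 60.0)])
        assert len(build_clusters(hits2, dt_max_ns=850.0)) == 1

    def test_diagonal_adjacency_included(self):
        hits = make_hits([(10, 10, 0.0, 50.0), (11, 11, 0.0, 60.0)])
        assert len(build_clusters(hits)) == 1

    def test_time_chains_transitively(self):
        # 0 -- 600 -- 1200: pairwise neighbor gaps 600 <= 850 chain all three,
        # although the global span (1200) exceeds the window.
        hits = make_hits([(10, 10, 0.0, 50.0), (10, 11, 600.0, 60.0),
                          (10, 12, 1200.0, 70.0)])
        clusters = build_clusters(hits, dt_max_ns=850.0)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_empty_input(self):
        assert build_clusters(hits_to_frame([])) == []

    def test_matches_bruteforce_oracle_on_random_field(self, rng):
        n = 200
        hits = make_hits([
            (int(rng.integers(0, 40)), int(rng.integers(0, 40)),
             float(rng.uniform(0, 5000)), float(rng.uniform(3, 100)))
            for _ in range(n)
        ])
        clusters = build_clusters(hits, dt_max_ns=850.0)
        comp = oracle_partition(hits, 850.0)
        oracle = {}
        for i, c in enumerate(comp):
            oracle.setdefault(c, set()).add(
                (hits["x"][i], hits["y"][i], hits["toa_ns"][i]))
        assert partition_as_sets(clusters) == {frozenset(s) for s in oracle.values()}

    def test_hit_and_energy_conservation(self, rng):
        hits = make_hits([
            (int(rng.integers(0, 30)), int(rng.integers(0, 30)),
             float(rng.uniform(0, 3000)), float(rng.uniform(3, 100)))
            for _ in range(150)
        ])
        clusters = build_clusters(hits)
        assert sum(c.size for c in clusters) == len(hits)
        assert sum(c.volume_keV for c in clusters) == pytest.approx(
            hits["energy_keV"].sum(), rel=1e-12)

    def test_partition_invariant_under_shuffle(self, rng):
        hits = make_hits([
            (int(rng.integers(0, 20)), int(rng.integers(0, 20)),
             float(rng.uniform(0, 2000)), float(rng.uniform(3, 100)))
            for _ in range(100)
        ])
        a = build_clusters(hits)
        shuffled = hits.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = build_clusters(shuffled)
        assert partition_as_sets(a) == partition_as_sets(b)
        # deterministic output ordering as well
        assert [(c.t_ref_ns, c.x[0], c.y[0]) for c in a] == \
            [(c.t_ref_ns, c.x[0], c.y[0]) for c in b]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            build_clusters(make_hits([(1, 1, 0.0, 10.0)]), dt_max_ns=0.0)
        with pytest.raises(GeometryError):
            build_clusters(make_hits([(300, 1, 0.0, 10.0)]))

    def test_cropped_cluster_repair_merges_abutting_fragments(self):
        # A timestamp error split one footprint: the two halves abut spatially
        # but differ by 2 us, beyond the coincidence window.
        hits = make_hits([(10, 10, 0.0, 40.0), (10, 11, 0.0, 40.0),
                          (10, 12, 2000.0, 40.0), (10, 13, 2000.0, 40.0)])
        assert len(build_clusters(hits, dt_max_ns=850.0)) == 2
        repaired = build_clusters(hits, dt_max_ns=850.0, repair_window_ns=5000.0)
        assert len(repaired) == 1 and repaired[0].size == 4


class TestLowEnergyCutoff:
    def test_cutoff_30_kev_on_volume(self):
        def cl(v):
            return Cluster([0, 1], [0, 0], [0.0, 0.0], [v / 2, v / 2])
        clusters = [cl(10.0), cl(29.9), cl(30.0), cl(500.0)]
        kept = apply_low_energy_cutoff(clusters, 30.0)
        assert sorted(c.volume_keV for c in kept) == [30.0, 500.0]

    def test_zero_cutoff_still_drops_single_pixel_noise(self):
        clusters = [Cluster([0], [0], [0.0], [100.0]),
                    Cluster([0, 1], [0, 0], [0.0, 0.0], [5.0, 5.0])]
        kept = apply_low_energy_cutoff(clusters, 0.0)
        assert len(kept) == 1 and kept[0].size == 2

    def test_matches_bruteforce_recount(self, rng):
        clusters = []
        for _ in range(10_000):
            size = int(rng.integers(1, 6))
            e = rng.uniform(2, 20, size=size)
            clusters.append(Cluster(np.arange(size), np.zeros(size, dtype=int),
                                    np.zeros(size), e))
        kept = apply_low_energy_cutoff(clusters, 30.0)
        expected = sum(1 for c in clusters if c.size >= 2 and c.volume_keV >= 30.0)
        assert len(kept) == expected


class TestClusterBuilder:
    def test_transform_emits_summary_table_and_counters(self, helium_dataset):
        _, hits, truth = helium_dataset
        builder = ClusterBuilder()
        table = builder.transform(hits)
        assert set(table.columns) == {"size", "volume_keV", "t_ref_ns", "cx", "cy"}
        assert builder.n_hits_in_ == len(hits)
        assert builder.n_clusters_ == len(table)
        assert builder.n_clusters_raw_ - builder.n_dropped_ == builder.n_clusters_
        # noise and sub-cutoff events are dropped, primaries survive
        assert len(table) <= builder.n_clusters_raw_
        assert (table["volume_keV"] >= 30.0).all()

    def test_one_cluster_per_event_on_clean_data(self, proton_dataset):
        scenario, hits, truth = proton_dataset
        builder = ClusterBuilder()
        clusters = builder.build(hits)
        # every surviving cluster comes from one generated event
        assert abs(len(clusters) - len(truth)) <= 0.02 * len(truth)
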