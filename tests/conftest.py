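"""Shared fixtures: a small seeded synthetic survey and an additive-matrix
generator used as the neighbor-joining oracle."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from pgpt_profiler.synthetic import (
    SimulationConfig,
    generate_reference_db,
    simulate_hit_tables,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(reads_per_sample=2000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(refdb, reads, truth, hit_tables) for a 3 x 2000-read survey."""
    refdb = generate_reference_db(small_cfg)
    reads, truth = simulate_reads(refdb, small_cfg)
    hits = simulate_hit_tables(reads, truth, refdb, small_cfg)
    return refdb, reads, truth, hits


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf distance matrix of a random unrooted binary tree with
    positive branch lengths — additive by construction, so neighbor joining
    must recover its path lengths exactly."""
    center = "c0"
    adj: dict[object, dict[object, float]] = {center: {}, 0: {}, 1: {}, 2: {}}
    for leaf in range(3):
        w = rng.uniform(0.1, 1.0)
        adj[center][leaf] = w
        adj[leaf][center] = w
    next_internal = 1
    edges = [(center, 0), (center, 1), (center, 2)]
    for leaf in range(3, n):
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        new = f"c{next_internal}"
        next_internal += 1
        split = rng.uniform(0.2, 0.8)
        del adj[u][v]
        del adj[v][u]
        adj[new] = {}
        adj[u][new] = w * split
        adj[new][u] = w * split
        adj[v][new] = w * (1 - split)
        adj[new][v] = w * (1 - split)
        pendant = rng.uniform(0.1, 1.0)
        adj[leaf] = {new: pendant}
        adj[new][leaf] = pendant
        edges.remove((u, v))
        edges += [(u, new), (v, new), (new, leaf)]
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        queue = collections.deque([i])
        while queue:
            x = queue.popleft()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    queue.append(y)
        for j in range(n):
            D[i, j] = dist[j]
    labels = [f"L{i:02d}" for i in range(n)]
    return labels, D
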