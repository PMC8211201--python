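"""Shared fixtures: tiny hand-built datasets and random-data helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from netsubsample import GeneratorConfig, RoostingData, generate_population


def random_roosting(rng: np.random.Generator, n_ind=6, n_days=10, n_roosts=3, p_detect=0.7):
    """Unstructured random detections — the brute-force oracle's playground."""
    records = []
    for i in range(n_ind):
        for d in range(n_days):
            if rng.random() < p_detect:
                records.append((f"I{i:02d}", d, f"R{rng.integers(n_roosts):02d}"))
    return RoostingData.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_data():
    """5-day toy stream: A,B together d0,d1; apart d2; A-only d3; B-only d4."""
    return RoostingData.from_records(
        [
            ("A", 0, "r1"), ("B", 0, "r1"),
            ("A", 1, "r2"), ("B", 1, "r2"),
            ("A", 2, "r1"), ("B", 2, "r2"),
            ("A", 3, "r1"),
            ("B", 4, "r2"),
        ]
    )


@pytest.fixture
def two_cliques_data():
    """Two permanently disjoint roosting groups observed over 12 days."""
    records = []
    for d in range(12):
        for i in ("A", "B", "C"):
            records.append((i, d, "r1"))
        for i in ("D", "E", "F"):
            records.append((i, d, "r2"))
    return RoostingData.from_records(records)


@pytest.fixture
def structured_small():
    """Generator output with clear 3-community structure at modest size."""
    cfg = GeneratorConfig(
        n_individuals=30, n_communities=3, n_days=60, n_roosts=6,
        p_detect=0.8, p_fission=0.3, p_drift=0.05, p_home_switch=0.2,
        drift_concentration=None, seed=42,
    )
    data, planted = generate_population(cfg)
    return data, planted, cfg


# ---------------------------------------------------------------------------
# Brute-force oracles, kept deliberately independent of the package internals
# ---------------------------------------------------------------------------


def brute_dyad_counts(data: RoostingData, a: str, b: str) -> tuple[int, int, int, int]:
    """Day-by-day enumeration of (x, y_ab, y_a, y_b) for one dyad."""
    where: dict[int, dict[str, str]] = {}
    for ind, day, roost in data.records:
        if ind in (a, b):
            where.setdefault(day, {})[ind] = roost
    x = y_ab = y_a = y_b = 0
    for day, seen in where.items():
        if a in seen and b in seen:
            if seen[a] == seen[b]:
                x += 1
            else:
                y_ab += 1
        elif a in seen:
            y_a += 1
        elif b in seen:
            y_b += 1
    return x, y_ab, y_a, y_b


def brute_hwi(data: RoostingData, a: str, b: str) -> float:
    x, y_ab, y_a, y_b = brute_dyad_counts(data, a, b)
    denom = x + y_ab + 0.5 * (y_a + y_b)
    return x / denom if denom > 0 else 0.0


def brute_sri(data: RoostingData, a: str, b: str) -> float:
    x, y_ab, y_a, y_b = brute_dyad_counts(data, a, b)
    denom = x + y_ab + y_a + y_b
    return x / denom if denom > 0 else 0.0


def brute_modularity(w: np.ndarray, labels: np.ndarray) -> float:
    """Direct double sum over all ordered node pairs."""
    total = w.sum()  # 2W
    if total == 0:
        return 0.0
    s = w.sum(axis=1)
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] / total - s[i] * s[j] / total**2
    return q


def brute_density(w: np.ndarray) -> float:
    n = w.shape[0]
    edges = sum(1 for i, j in itertools.combinations(range(n), 2) if w[i, j] > 0)
    return edges / (n * (n - 1) / 2)


def brute_clustering(w: np.ndarray) -> float:
    """Triple/triangle enumeration on the binarized graph."""
    n = w.shape[0]
    adj = w > 0
    triangles = triples = 0
    for i, j, k in itertools.combinations(range(n), 3):
        e = int(adj[i, j]) + int(adj[j, k]) + int(adj[i, k])
        if e == 3:
            triangles += 1
            triples += 3  # a triangle contains three connected triples
        elif e == 2:
            triples += 1
    return 3 * triangles / triples if triples else 0.0


def brute_rand_similarity(labels_a: dict, labels_b: dict, ids) -> float:
    agree = tot = 0
    for a, b in itertools.combinations(sorted(ids), 2):
        same_a = labels_a[a] == labels_a[b]
        same_b = labels_b[a] == labels_b[b]
        agree += same_a == same_b
        tot += 1
    return agree / tot
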