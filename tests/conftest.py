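"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from petnet import UptakeMatrix, threshold_network


# ---------------------------------------------------------------- oracles


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Direct two-pass Pearson product-moment correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def degree_brute_force(n_nodes: int, edges: list[tuple[int, int, float]], mode: str = "weighted") -> np.ndarray:
    """Sum |r| (or count) over the edge list, node by node."""
    deg = np.zeros(n_nodes)
    for i, j, r in edges:
        w = abs(r) if mode == "weighted" else 1.0
        deg[i] += w
        deg[j] += w
    return deg


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook recursion."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_uptake():
    """4 subjects x 3 VOIs, strictly positive, unnormalized."""
    values = np.array(
        [
            [2.0, 4.0, 6.0],
            [1.5, 3.1, 2.4],
            [2.2, 5.0, 4.8],
            [1.9, 2.5, 3.3],
        ]
    )
    return UptakeMatrix(("S1", "S2", "S3", "S4"), ("VOI-a", "VOI-b", "VOI-c"), values)


def random_network(rng, n_nodes=12, edge_prob=0.3, group="g", tau=0.7):
    """Random simple graph with signed weights of magnitude in [tau, 1)."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(iu.size) < edge_prob
    mag = tau + (1 - tau) * rng.random(iu.size) * 0.99
    sign = rng.choice([-1.0, 1.0], size=iu.size)
    corr = np.eye(n_nodes)
    corr[iu[keep], ju[keep]] = (sign * mag)[keep]
    corr[ju[keep], iu[keep]] = (sign * mag)[keep]
    labels = [f"n{i}" for i in range(n_nodes)]
    return threshold_network(corr, labels, tau=tau, group=group)


@pytest.fixture
def fixture_network(rng):
    return random_network(rng, n_nodes=12, edge_prob=0.35)
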