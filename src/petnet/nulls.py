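"""Configuration-model null ensembles by degree-preserving rewiring.

The significance of group differences in degree centrality is calibrated
against configuration models: random networks in which every node keeps its
original (binary) degree while the wiring is randomized.  Rewiring is done by
repeated double-edge swaps — pick two edges (u, v) and (x, y), replace them
with (u, x) and (v, y) (or (u, y) and (v, x)) — rejecting any swap that would
create a self-loop or a parallel edge.  Each swap leaves all four endpoint
degrees unchanged, so the degree sequence is preserved exactly, not just in
distribution.

Correlation weights are not rewired with their edges: after rewiring, the
observed multiset of edge weights is randomly permuted over the new edge set,
so null networks have the same weight distribution and the same total
connectivity mass as the source network.

Reproducibility: an ensemble is addressed by a root seed; replicate ``b`` uses
a child seed spawned deterministically from ``(seed, b)`` (numpy
``SeedSequence`` spawning), so ensembles are bit-identical across machines and
independent of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import CorrelationNetwork

logger = logging.getLogger("petnet")

SWAP_FACTOR = 10  # default swap attempts per edge
_ATTEMPT_BATCH = 4  # oversampling factor for pre-drawn randomness


@dataclass(frozen=True)
class NullEnsemble:
    """B degree-preserving rewirings of one group network.

    ``replicates[b]`` is an ``(edge_i, edge_j, edge_r)`` triple of parallel
    arrays; every replicate has the source network's edge count, binary degree
    sequence, and edge-weight multiset.
    """

    source_group: str
    B: int
    seed: int
    n_nodes: int
    replicates: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]

    def __post_init__(self) -> None:
        if self.B != len(self.replicates):
            raise ValueError("B must equal the number of replicates")


def _swap_edges(
    edges: list[tuple[int, int]],
    rng: np.random.Generator,
    n_swaps: int,
) -> tuple[list[tuple[int, int]], int]:
    """Attempt ``n_swaps`` double-edge swaps; return (edges, successful swaps)."""
    m = len(edges)
    edge_set = set(edges)
    done = 0
    attempts = 0
    # Randomness is pre-drawn in blocks: one (edge, edge, orientation) triple
    # per attempt, which keeps the rejection loop cheap and deterministic.
    while attempts < n_swaps:
        block = min(n_swaps - attempts, _ATTEMPT_BATCH * m + 64)
        pick = rng.integers(0, m, size=(block, 2))
        flip = rng.integers(0, 2, size=block)
        for (a, b), f in zip(pick, flip):
            attempts += 1
            if a == b:
                continue
            u, v = edges[a]
            x, y = edges[b]
            if f:
                x, y = y, x
            # proposed new edges: (u, x) and (v, y)
            if u == x or v == y:
                continue  # self-loop
            e1 = (u, x) if u < x else (x, u)
            e2 = (v, y) if v < y else (y, v)
            if e1 in edge_set or e2 in edge_set:
                continue  # parallel edge
            edge_set.remove(edges[a])
            edge_set.remove(edges[b])
            edge_set.add(e1)
            edge_set.add(e2)
            edges[a] = e1
            edges[b] = e2
            done += 1
            if attempts >= n_swaps:
                break
    return edges, done


def rewire_configuration(
    net: CorrelationNetwork,
    seed: int | np.random.SeedSequence,
    n_swaps: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One configuration-model replicate of ``net``.

    Performs up to ``n_swaps`` double-edge swap attempts (default 10x the edge
    count) with rejection of self-loops and parallel edges, then permutes the
    observed weight multiset over the rewired edge set.  Deterministic given
    ``seed``.  Degenerate inputs that admit no successful swap (fewer than two
    edges, or a forced topology such as a complete graph) are returned with
    their original wiring and a logged warning.

    Returns
    -------
    ``(edge_i, edge_j, edge_r)`` parallel arrays with ``edge_i < edge_j``.
    """
    rng = np.random.default_rng(seed)
    m = net.n_edges
    if n_swaps is None:
        n_swaps = SWAP_FACTOR * m
    edges = [(int(i), int(j)) for i, j in zip(net.edge_i, net.edge_j)]
    if m < 2:
        logger.warning(
            "rewire_configuration: network %r has %d edge(s); returning it unchanged",
            net.group, m,
        )
        return net.edge_i.copy(), net.edge_j.copy(), net.edge_r.copy()
    edges, done = _swap_edges(edges, rng, n_swaps)
    if done == 0:
        logger.warning(
            "rewire_configuration: no successful swap in %d attempts on network %r "
            "(forced topology); returning original wiring", n_swaps, net.group,
        )
    weights = rng.permutation(net.edge_r)
    ei = np.array([e[0] for e in edges], dtype=np.intp)
    ej = np.array([e[1] for e in edges], dtype=np.intp)
    return ei, ej, weights


def generate_ensemble(
    net: CorrelationNetwork,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    n_swaps: int | None = None,
) -> NullEnsemble:
    """Generate B configuration-model replicates of a group network.

    Replicate ``b`` uses the ``b``-th child of ``SeedSequence(seed)``, so the
    ensemble is bit-reproducible for fixed ``(seed, B)`` and replicates are
    independent of generation order.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(B)
    replicates = tuple(rewire_configuration(net, child, n_swaps) for child in children)
    root_seed = root.entropy if isinstance(root.entropy, int) else -1
    return NullEnsemble(
        source_group=net.group,
        B=B,
        seed=int(root_seed),
        n_nodes=net.n_nodes,
        replicates=replicates,
    )
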