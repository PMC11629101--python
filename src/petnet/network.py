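"""Group-level metabolic connectivity networks.

A group network is built from an :class:`~petnet.ingest.UptakeMatrix` by
computing the pairwise Pearson correlation of every VOI pair across subjects
and retaining the edges whose correlation magnitude reaches a threshold tau
(default 0.7, keeping both positively and negatively correlated region pairs;
the signed coefficient is stored on the edge).

Node "hubness" is summarized by degree centrality.  Because retained edges
carry correlation weights, the default degree is the weighted degree — the sum
of |r| over a node's incident edges — which is what produces the non-integer
degree-centrality scores reported downstream.  A plain edge-count degree is
available via ``mode="count"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_TAU = 0.7


@dataclass(frozen=True)
class CorrelationNetwork:
    """VOI nodes with signed retained edges and the correlation matrix they came from.

    ``edge_i``/``edge_j``/``edge_r`` are parallel arrays of the retained edges
    with ``edge_i < edge_j`` and ``|edge_r| >= tau``; ``edge_r`` keeps the sign.
    """

    voi_labels: tuple[str, ...]
    corr: np.ndarray
    tau: float
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_r: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "voi_labels", tuple(str(v) for v in self.voi_labels))
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        object.__setattr__(self, "edge_i", np.asarray(self.edge_i, dtype=np.intp))
        object.__setattr__(self, "edge_j", np.asarray(self.edge_j, dtype=np.intp))
        object.__setattr__(self, "edge_r", np.asarray(self.edge_r, dtype=float))
        _validate_corr(self.corr, len(self.voi_labels))
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if not (len(self.edge_i) == len(self.edge_j) == len(self.edge_r)):
            raise ValueError("edge arrays must have equal length")
        if np.any(self.edge_i >= self.edge_j):
            raise ValueError("edges must satisfy i < j (no self-loops, upper triangle)")
        if np.any(np.abs(self.edge_r) < self.tau):
            raise ValueError("every retained edge must satisfy |r| >= tau")
        if not np.array_equal(self.corr[self.edge_i, self.edge_j], self.edge_r):
            raise ValueError("edge weights must equal the correlation matrix entries")

    @property
    def n_nodes(self) -> int:
        return len(self.voi_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_r)

    def edges(self) -> list[tuple[int, int, float]]:
        """Retained edges as (i, j, r) tuples with i < j."""
        return [
            (int(i), int(j), float(r))
            for i, j, r in zip(self.edge_i, self.edge_j, self.edge_r)
        ]


@dataclass(frozen=True)
class DegreeProfile:
    """Per-node degree centrality plus the network-level mean degree."""

    voi_labels: tuple[str, ...]
    degree: np.ndarray
    mean_degree: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "voi_labels", tuple(str(v) for v in self.voi_labels))
        object.__setattr__(self, "degree", np.asarray(self.degree, dtype=float))
        if self.degree.shape != (len(self.voi_labels),):
            raise ValueError("degree must be 1-D with one entry per VOI")
        if np.any(self.degree < 0):
            raise ValueError("degrees are nonnegative")
        if abs(self.mean_degree - float(self.degree.mean())) > 1e-12:
            raise ValueError("mean_degree must equal the arithmetic mean of degree")


def _validate_corr(corr: np.ndarray, v: int) -> None:
    if corr.shape != (v, v):
        raise ValueError(f"correlation matrix must be {v}x{v}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have a unit diagonal")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")


def correlation_matrix(m, *, zero_variance_policy: str = "fail") -> np.ndarray:
    """Pairwise Pearson correlation of VOIs across a group's subjects.

    Parameters
    ----------
    m : UptakeMatrix with at least 3 subjects.
    zero_variance_policy : ``"fail"`` (default) raises if any VOI is constant
        across subjects; ``"zero"`` sets that VOI's correlations to 0 instead.

    Returns
    -------
    Symmetric V x V matrix with unit diagonal, entries clipped to [-1, 1].
    """
    if zero_variance_policy not in ("fail", "zero"):
        raise ValueError(f"unknown zero_variance_policy {zero_variance_policy!r}")
    if m.n_subjects < 3:
        raise ValueError(f"need >= 3 subjects for a correlation network, got {m.n_subjects}")
    values = m.values
    sd = values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size and zero_variance_policy == "fail":
        names = [m.voi_labels[i] for i in flat]
        raise ValueError(f"zero-variance VOI(s) {names}; correlation undefined (policy 'fail')")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    if flat.size:
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def threshold_network(
    corr: np.ndarray,
    voi_labels: Sequence[str],
    tau: float = DEFAULT_TAU,
    group: str = "",
) -> CorrelationNetwork:
    """Retain every VOI pair with |r| >= tau as a signed-weight edge.

    The comparison is closed (>=) and uses direct floating-point comparison:
    a pair at exactly |r| = tau is retained.  The diagonal is ignored.
    """
    corr = np.asarray(corr, dtype=float)
    voi_labels = tuple(str(v) for v in voi_labels)
    _validate_corr(corr, len(voi_labels))
    if not 0 < tau <= 1:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    iu, ju = np.triu_indices(len(voi_labels), k=1)
    r = corr[iu, ju]
    keep = np.abs(r) >= tau
    return CorrelationNetwork(
        voi_labels=voi_labels,
        corr=corr,
        tau=tau,
        edge_i=iu[keep],
        edge_j=ju[keep],
        edge_r=r[keep],
        group=group,
    )


def degrees_from_edges(
    n_nodes: int,
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    edge_r: np.ndarray,
    mode: str = "weighted",
) -> np.ndarray:
    """Degree vector of an edge list: sum of |r| ("weighted") or edge count ("count")."""
    if mode not in ("weighted", "count"):
        raise ValueError(f"unknown degree mode {mode!r}")
    w = np.abs(np.asarray(edge_r, dtype=float)) if mode == "weighted" else np.ones(len(edge_r))
    deg = np.zeros(n_nodes)
    np.add.at(deg, np.asarray(edge_i, dtype=np.intp), w)
    np.add.at(deg, np.asarray(edge_j, dtype=np.intp), w)
    return deg


def degree_profile(net: CorrelationNetwork, mode: str = "weighted") -> DegreeProfile:
    """Degree centrality of every node, isolated nodes included as 0.

    The default weighted degree is the sum of |r| over incident retained
    edges; ``mode="count"`` counts incident edges instead.
    """
    deg = degrees_from_edges(net.n_nodes, net.edge_i, net.edge_j, net.edge_r, mode)
    return DegreeProfile(net.voi_labels, deg, float(deg.mean()))


def write_edge_list(net: CorrelationNetwork, path: str | Path) -> None:
    """Export the retained edges as a TSV (voi_a, voi_b, r), full precision."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("voi_a\tvoi_b\tr\n")
        for i, j, r in net.edges():
            fh.write(f"{net.voi_labels[i]}\t{net.voi_labels[j]}\t{r!r}\n")


def write_correlation_matrix(net: CorrelationNetwork, path: str | Path) -> None:
    """Export the full square correlation matrix as a labelled TSV."""
    df = pd.DataFrame(net.corr, index=list(net.voi_labels), columns=list(net.voi_labels))
    df.rename_axis("voi").to_csv(Path(path), sep="\t")
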