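"""Synthetic two-group PET uptake cohorts with controlled correlation structure.

The patient-level data behind the published analysis are not publicly
available, so calibration, power and recovery experiments run on simulated
cohorts.  Each group's subject x VOI table is drawn from a multivariate normal
whose correlation matrix is assembled from

* an identity base (independent VOIs),
* correlated blocks — sets of VOIs sharing a common within-block correlation,
  emulating coherent metabolic subnetworks, and
* differential hubs — a hub VOI whose correlations with a target set differ
  between the groups (``rho_A`` vs ``rho_B``), the planted effect the
  pipeline should detect.

A multivariate normal is used because a Pearson-correlation pipeline is
exactly parameterized by the correlation matrix; positivity of uptake values
is obtained by a mean shift (with logged clipping of the rare residual
negatives) rather than an exponential transform, which would distort the
target correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import RunConfig
from .differential import DifferentialResult, run_differential_analysis
from .ingest import UptakeMatrix

logger = logging.getLogger("petnet")

_CLIP_FLOOR = 1e-6
_MAX_CLIP_FRACTION = 0.01


@dataclass(frozen=True)
class Block:
    """VOIs sharing a common within-block correlation rho (both groups)."""

    members: tuple[int, ...]
    rho: float


@dataclass(frozen=True)
class DifferentialHub:
    """Hub VOI correlated with its targets at rho_A in group A, rho_B in B."""

    hub: int
    targets: tuple[int, ...]
    rho_A: float
    rho_B: float


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a two-group cohort.

    V : number of VOIs (94 matches the published VOI scheme).
    n_A, n_B : subjects per group (130/130 at patient scale, 84/84 at
        control scale).
    blocks : shared correlated blocks.
    differential_hubs : planted group differences on the correlation scale.
    noise_sd : residual standard deviation of every VOI.
    baseline_mean : positive mean uptake level; must be large relative to
        noise_sd so positivity clipping stays negligible.
    seed : root seed for sampling.
    """

    V: int = 94
    n_A: int = 130
    n_B: int = 130
    blocks: tuple[Block, ...] = ()
    differential_hubs: tuple[DifferentialHub, ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "differential_hubs", tuple(self.differential_hubs))
        if self.V < 3:
            raise ValueError("V must be >= 3")
        if self.n_A < 4 or self.n_B < 4:
            raise ValueError("each group needs at least 4 subjects")
        if self.noise_sd <= 0 or self.baseline_mean <= 0:
            raise ValueError("noise_sd and baseline_mean must be positive")
        for blk in self.blocks:
            if not all(0 <= m < self.V for m in blk.members):
                raise ValueError(f"block members out of range: {blk}")
            if len(set(blk.members)) < 2:
                raise ValueError(f"a block needs >= 2 distinct members: {blk}")
            if not abs(blk.rho) < 1:
                raise ValueError(f"|rho| must be < 1: {blk}")
        for hub in self.differential_hubs:
            nodes = (hub.hub, *hub.targets)
            if not all(0 <= m < self.V for m in nodes):
                raise ValueError(f"hub nodes out of range: {hub}")
            if hub.hub in hub.targets or not hub.targets:
                raise ValueError(f"hub must have >= 1 target distinct from itself: {hub}")
            if not (abs(hub.rho_A) < 1 and abs(hub.rho_B) < 1):
                raise ValueError(f"|rho| must be < 1: {hub}")
        # fail fast on non-positive-definite structure
        for group in ("A", "B"):
            build_covariance(self, group)

    def differential_nodes(self) -> set[int]:
        """Nodes involved in any planted group difference (hub or target)."""
        out: set[int] = set()
        for hub in self.differential_hubs:
            out.add(hub.hub)
            out.update(hub.targets)
        return out


def build_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Assemble one group's V x V correlation matrix from the spec.

    Identity base; blocks fill their within-block off-diagonals with rho;
    differential hubs then overwrite the hub-target entries with the group's
    rho.  The result is validated symmetric positive definite.
    """
    if group not in ("A", "B"):
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    corr = np.eye(spec.V)
    for blk in spec.blocks:
        for a in blk.members:
            for b in blk.members:
                if a != b:
                    corr[a, b] = blk.rho
    for hub in spec.differential_hubs:
        rho = hub.rho_A if group == "A" else hub.rho_B
        for t in hub.targets:
            corr[hub.hub, t] = rho
            corr[t, hub.hub] = rho
    corr = (corr + corr.T) / 2.0
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"group {group} correlation matrix is not positive definite; "
            f"check blocks {spec.blocks} and hubs {spec.differential_hubs}"
        ) from None
    return corr


def _sample_group(
    spec: CohortSpec,
    group: str,
    n: int,
    tag: str,
    seed: np.random.SeedSequence,
) -> UptakeMatrix:
    rng = np.random.default_rng(seed)
    corr = build_covariance(spec, group)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, spec.V))
    values = spec.baseline_mean + spec.noise_sd * (z @ chol.T)
    n_clip = int(np.sum(values < _CLIP_FLOOR))
    if n_clip:
        frac = n_clip / values.size
        if frac > _MAX_CLIP_FRACTION:
            raise ValueError(
                f"positivity clipping would affect {frac:.1%} of values "
                f"(> {_MAX_CLIP_FRACTION:.0%}); increase baseline_mean or lower noise_sd"
            )
        logger.warning("clipped %d nonpositive value(s) (%.3g%%) in group %s", n_clip, 100 * frac, tag)
        values = np.maximum(values, _CLIP_FLOOR)
    subject_ids = tuple(f"{tag}-{k+1:04d}" for k in range(n))
    voi_labels = tuple(f"VOI{v+1:03d}" for v in range(spec.V))
    return UptakeMatrix(subject_ids, voi_labels, values, group=tag, normalized=False)


def sample_cohort(spec: CohortSpec) -> tuple[UptakeMatrix, UptakeMatrix]:
    """Draw both groups' uptake tables; deterministic given ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    seed_A, seed_B = root.spawn(2)
    a = _sample_group(spec, "A", spec.n_A, "A", seed_A)
    b = _sample_group(spec, "B", spec.n_B, "B", seed_B)
    return a, b


def null_cohort_spec(V: int = 30, n: int = 60, seed: int = 0) -> CohortSpec:
    """Desk-scale no-difference spec used for type-I calibration.

    Both groups share six (for V = 30) 5-VOI blocks at rho = 0.8 — above the
    0.7 retention threshold, so group networks have edges and no node is
    structurally isolated — and there is no planted group difference.
    """
    block_size = 5
    blocks = tuple(
        Block(tuple(range(s, min(s + block_size, V))), 0.8)
        for s in range(0, V - 1, block_size)
        if min(s + block_size, V) - s >= 2
    )
    return CohortSpec(V=V, n_A=n, n_B=n, blocks=blocks, seed=seed)


def hub_recovery_spec(seed: int = 0) -> CohortSpec:
    """Patient-scale spec with one planted differential hub.

    V = 94 VOIs, 130 subjects per group; the hub is correlated at 0.85 with
    12 targets in group A and uncorrelated with them in group B.  Twelve
    variables each correlated at 0.85 with a common hub are mathematically
    forced to be strongly mutually correlated (an uncorrelated 12-spoke star
    at 0.85 is not positive definite), so the targets carry the one-factor
    within-block correlation 0.85^2 = 0.7225 in both groups; the planted
    group difference is confined to the hub-target entries.
    """
    targets = tuple(range(1, 13))
    return CohortSpec(
        V=94,
        n_A=130,
        n_B=130,
        blocks=(Block(targets, 0.85**2),),
        differential_hubs=(DifferentialHub(0, targets, 0.85, 0.0),),
        seed=seed,
    )


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate outcome of repeated sample-and-analyze runs."""

    runs: int
    top_ranked_fraction: dict[int, float]
    significant_fraction: dict[int, float]
    type_i_proportion: float
    n_null_tests: int
    results: tuple[DifferentialResult, ...] = field(repr=False, default=())


def recovery_experiment(
    spec: CohortSpec,
    runs: int,
    dna_config: RunConfig | None = None,
    *,
    alpha: float = 0.05,
    keep_results: bool = False,
) -> RecoverySummary:
    """Repeat sample -> differential analysis over independent seeds.

    For each planted hub, reports the fraction of runs in which it attains
    the maximum node statistic and in which its q-value falls below ``alpha``;
    also reports the proportion of nominal p <= alpha among VOIs not involved
    in any planted difference (the empirical node-level type-I proportion).
    Run ``r`` derives its cohort seed and analysis seed deterministically from
    ``(spec.seed, r)``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    dna_config = dna_config or RunConfig(B=199)
    hubs = sorted(h.hub for h in spec.differential_hubs)
    diff_nodes = spec.differential_nodes()
    null_nodes = [v for v in range(spec.V) if v not in diff_nodes]

    top_counts = dict.fromkeys(hubs, 0)
    sig_counts = dict.fromkeys(hubs, 0)
    null_hits = 0
    null_total = 0
    results: list[DifferentialResult] = []

    root = np.random.SeedSequence(spec.seed)
    for child in root.spawn(runs):
        run_seed = int(child.generate_state(2)[0] % (2**31))
        res = run_differential_analysis(
            *sample_cohort(replace(spec, seed=run_seed)),
            replace(dna_config, seed=run_seed + 1),
        )
        top = float(res.node_stat.max())
        for h in hubs:
            if res.node_stat[h] == top:
                top_counts[h] += 1
            if res.node_q[h] < alpha:
                sig_counts[h] += 1
        if null_nodes:
            null_hits += int(np.sum(res.node_p[null_nodes] <= alpha))
            null_total += len(null_nodes)
        if keep_results:
            results.append(res)

    return RecoverySummary(
        runs=runs,
        top_ranked_fraction={h: top_counts[h] / runs for h in hubs},
        significant_fraction={h: sig_counts[h] / runs for h in hubs},
        type_i_proportion=(null_hits / null_total) if null_total else float("nan"),
        n_null_tests=null_total,
        results=tuple(results),
    )
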