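# Methods

## Model and procedure

`petnet` treats a group's metabolic connectivity as the Pearson correlation
structure of VOI-level normalized uptake across subjects. The pipeline is:

1. **Ingest** (`petnet.ingest`). Subject × VOI tables are validated (unique
   subject IDs, numeric cells, ≥ 3 subjects — the minimum for a non-degenerate
   correlation) and values must be strictly positive, as uptake is a physical
   quantity. Missing data are governed by a policy: `fail` (default) or
   `drop-subject`. Correlating different subject subsets per VOI pair would
   silently bias the networks, so pairwise deletion is deliberately not
   offered. When only VOI tables exist, whole-brain-mean normalization uses
   the volume-weighted VOI mean; with weights equal to atlas voxel counts this
   is exactly the voxel-level whole-brain mean over the union of VOIs (the
   "whole brain" is defined as that union, so the operation is reproducible
   without a separate brain mask). VOI means can also be extracted from a PET
   volume with an integer-labelled atlas; spatial normalization, smoothing and
   voxel-level statistics are out of scope (established neuroimaging tool
   chains do them).
2. **Network construction** (`petnet.network`). Pearson correlation for every
   VOI pair; edges retained iff |r| ≥ τ with τ = 0.7 by default. The
   comparison is closed and uses direct floating-point comparison — no epsilon
   — so a pair at exactly 0.7 is retained. Both signs are kept because
   strongly anti-correlated regions are as "connected" as correlated ones; the
   signed r is stored on the edge. A zero-variance VOI makes r undefined;
   policy `fail` (default) or `zero` (its correlations set to 0).
3. **Degree centrality.** The degree of node i is Σ|r| over its incident
   retained edges ("weighted", default) or the plain edge count ("count").
   The weighted definition is the primary one: published degree-centrality
   scores in this literature are non-integer (e.g. 2.156 with three plausible
   incident edges near |r| ≈ 0.72), which an edge count cannot produce, and
   Σ|r| is the most parsimonious measure lying just above the edge count
   times τ. Isolated nodes have degree 0 and are included in the
   network-level mean.
4. **Differential statistics** (`petnet.differential`). Node level:
   T(i) = |d_A(i) − d_B(i)| (absolute difference → two-sided test). Network
   level: |mean degree A − mean degree B|.
5. **Configuration-model null** (`petnet.nulls`). Each group network is
   rewired by repeated double-edge swaps — two edges (u,v), (x,y) are replaced
   by (u,x),(v,y) or (u,y),(v,x) — with rejection of any swap creating a
   self-loop or parallel edge. The default budget is 10 swap attempts per
   edge, a standard mixing heuristic. Each swap preserves all four endpoint
   degrees, so every node's binary degree is preserved exactly (a hard
   invariant, asserted for 100% of replicates in the tests). The observed
   edge-weight multiset is then permuted uniformly over the rewired edges, so
   null networks have the source's weight distribution and total connectivity
   mass. Degenerate inputs that admit no successful swap (fewer than two
   edges; forced topologies such as a complete graph) are returned with their
   original wiring and a logged warning.
6. **Empirical p-values.** Replicate b of network A is paired with replicate
   b of network B; p = (1 + #{b : T_b ≥ T_obs}) / (B + 1). The add-one
   estimator makes p = 0 impossible and gives 1/(B+1) as the attainable
   floor — with B = 1000, 0.001 at three decimals. Ties count toward the
   numerator; statistics are rounded to 12 decimals before comparison so that
   mathematically tied values computed in different summation orders register
   as ties rather than resolving by floating-point jitter.
7. **Multiple testing.** Benjamini–Hochberg step-up across the V node tests
   (q-values); e.g. two smallest of 94 p-values tied at 0.001 adjust to
   0.001·94/2 = 0.047. The network-level p is reported unadjusted.

## Reproducibility

Every source of randomness descends from one root seed through numpy
`SeedSequence` spawning: the root spawns one child per group ensemble, and
each ensemble spawns one child per replicate, so results are bit-identical
across machines and independent of generation order, and ensemble generation
could be parallelized without changing output. `RunConfig` is serialized
verbatim into the run manifest together with a SHA-256 checksum of every
artifact; two runs with equal manifests produce byte-identical outputs.

## Synthetic cohorts

`petnet.synthetic` draws each group from a multivariate normal whose
correlation matrix is assembled from an identity base, within-block
equicorrelations, and hub–target entries that differ between groups. A
multivariate normal is the natural generative family here because a
Pearson-correlation pipeline is parameterized exactly by the correlation
matrix. Values are shifted by `baseline_mean` (default 10, in arbitrary
uptake units) with residual scale `noise_sd` (default 1), making negative
draws — clipped, with a logged count, and a hard error beyond 1% of values —
about a 10-sigma event. Correlations are unaffected by this affine scaling.

Two ready-made specifications fix the study conditions of the experiments:

* **No-difference (calibration) spec**: V = 30 VOIs fully covered by six
  5-VOI blocks at ρ = 0.8, n = 60 subjects per group. ρ = 0.8 lies above the
  τ = 0.7 retention threshold so the group networks have edges and no node is
  structurally isolated, mimicking coherent metabolic subnetworks
  (homologous-pair and within-system coupling) at a desk-scale problem size.
* **Hub-recovery spec**: V = 94 VOIs, n = 130 per group — the published
  cohort scale — with one hub correlated at 0.85 with 12 targets in group A
  and 0 in group B. A 12-spoke star at ρ = 0.85 over an independent base is
  not a valid correlation matrix (Σρ² = 8.67 > 1), and any 12 variables each
  correlated at 0.85 with a common hub are forced to be mutually correlated
  above ≈ 0.70; the targets therefore carry the one-factor within-block value
  0.85² = 0.7225 in **both** groups, confining the planted group difference
  to the hub–target entries.

What the generator does **not** emulate: voxel-level noise and partial-volume
effects, spatial autocorrelation, heavy-tailed or skewed uptake
distributions, site/scanner batch effects, and covariate structure (age,
sex) — so passing tests demonstrate the statistical machinery on idealized
correlation structure, not robustness to those features of real PET data.

Whole-brain normalization interacts with the generative model: dividing by
the row mean removes part of any shared block signal, attenuating in-block
sample correlations below the generative ρ (the attenuation grows with the
fraction of the "brain" occupied by the correlated cluster). This mirrors
what intensity normalization does to real uptake data and is covered by a
dedicated test.

## Statistical properties and known limitations

* **The network-level test is degenerate under this null.** Any rewiring that
  preserves the edge count and the weight multiset preserves the mean (binary
  or weighted) degree exactly, so the network-level statistic is identical in
  every replicate and its paired-null p equals 1 by construction. The test is
  reported for completeness; detecting mean-degree differences requires a
  null that does not fix total connectivity mass (out of scope here).
* **Node-level calibration holds exactly under exchangeable weights.** Since
  rewiring preserves every node's binary degree, the node-level null varies
  only through the weight permutation. When edge weights are exchangeable
  (e.g. iid), the observed assignment is one uniform draw from the
  permutation distribution and the empirical p-value is exactly calibrated —
  measured type-I proportion 0.050 at nominal 0.05 on iid-weight random
  graphs (a dedicated test asserts the binomial envelope).
* **On block-structured cohorts the node-level test is anti-conservative.**
  Within a correlated block, a node's incident sample correlations share
  subject-level noise and are mutually positively dependent, so the observed
  |Δdegree| has larger variance than the weight-permutation null allows;
  on the no-difference calibration spec the measured type-I proportion at
  nominal 0.05 is ≈ 0.19. This is a property of configuration-model nulls
  applied to correlation networks, not of the implementation (the iid-weight
  experiment isolates the machinery), and it means q-values on strongly
  block-structured data should be read as rankings rather than exact FDR
  guarantees.
* **Binary-degree ties make the count-mode node test vacuous** under this
  null (every replicate reproduces the observed degrees exactly, p ≡ 1);
  count mode is provided for descriptive comparisons only.
* **Numerical choices.** Correlations are clipped to [−1, 1] and symmetrized
  against floating-point asymmetry; the diagonal is set to exactly 1. The
  threshold comparison is exact (no epsilon). Post-normalization row means
  are verified to equal 1 within 1e-9 relative tolerance. BH adjustment
  delegates to statsmodels and is cross-checked against a hand-rolled step-up
  recursion to 1e-12.

## Problem sizes

The bundled experiments run on one CPU in about a minute total: type-I
calibration uses 50 repeats of the V = 30, n = 60/60 spec with B = 199
replicates; hub recovery uses 20 repeats of the V = 94, n = 130/130 spec with
B = 199; the hard-invariant scan uses B = 1000 on a 30-node fixture network.
B = 199 keeps the empirical p floor at 0.005 while making repeated-run
experiments cheap; single production runs should use the default B = 1000.
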