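"""Node/network statistics, empirical p-values, BH adjustment, full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_brute_force
from petnet import (
    CohortSpec,
    DegreeProfile,
    RunConfig,
    adjust_bh,
    empirical_pvalue,
    network_statistic,
    node_statistic,
    run_differential_analysis,
    sample_cohort,
)
from petnet.synthetic import Block, DifferentialHub


def _profile(degrees, labels=None):
    degrees = np.asarray(degrees, dtype=float)
    labels = labels or tuple(f"v{i}" for i in range(degrees.size))
    return DegreeProfile(labels, degrees, float(degrees.mean()))


class TestNodeStatistic:
    def test_published_degree_differences(self):
        """The printed statistics are exact differences of the group degree scores."""
        a = _profile([15.979, 2.156])
        b = _profile([1.578, 0.0])
        stat = node_statistic(a, b)
        assert stat[0] == pytest.approx(14.401, abs=1e-12)
        assert stat[1] == pytest.approx(2.156, abs=1e-12)

    def test_equal_profiles_zero(self):
        p = _profile([1.0, 2.0, 3.0])
        assert np.all(node_statistic(p, p) == 0)

    def test_label_mismatch(self):
        with pytest.raises(ValueError, match="label"):
            node_statistic(_profile([1.0], ("a",)), _profile([1.0], ("b",)))


class TestNetworkStatistic:
    def test_identical_zero(self):
        p = _profile([1.0, 2.0])
        assert network_statistic(p, p) == 0.0

    def test_node_effects_can_cancel(self):
        assert network_statistic(_profile([0, 0, 3]), _profile([1, 1, 1])) == pytest.approx(0.0)

    def test_constant_shift(self):
        assert network_statistic(_profile([2, 2, 2]), _profile([0, 0, 0])) == pytest.approx(2.0)


class TestEmpiricalPvalue:
    def test_add_one_floor_at_b1000(self):
        p = empirical_pvalue(10.0, np.zeros(1000))
        assert p == pytest.approx(1 / 1001)
        assert round(p, 3) == 0.001

    def test_observed_below_all_nulls(self):
        assert empirical_pvalue(0.0, np.ones(50)) == 1.0

    def test_direct_count_with_add_one(self):
        nulls = np.concatenate([np.full(5, 2.0), np.full(94, 0.5)])
        assert empirical_pvalue(1.0, nulls) == pytest.approx(6 / 100)

    def test_tie_counts_toward_numerator(self):
        assert empirical_pvalue(1.0, np.array([1.0, 0.5])) == pytest.approx(2 / 3)

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), b=st.integers(1, 200))
    def test_bounds(self, seed, b):
        rng = np.random.default_rng(seed)
        p = empirical_pvalue(rng.normal(), rng.normal(size=b))
        assert 1 / (b + 1) <= p <= 1.0


class TestAdjustBH:
    def test_two_tied_smallest_of_94(self):
        p = np.concatenate([[0.001, 0.001], np.linspace(0.5, 1.0, 92)])
        q = adjust_bh(p)
        assert q[0] == pytest.approx(0.001 * 94 / 2, abs=1e-12)
        assert q[1] == pytest.approx(0.047, abs=1e-9)

    def test_identity_at_m1(self):
        assert adjust_bh([0.05])[0] == pytest.approx(0.05)

    def test_step_up_recursion_by_hand(self):
        q = adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_bh(bad)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_against_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-9, 1.0, size=rng.integers(1, 60))
            assert np.allclose(adjust_bh(p), bh_brute_force(p), atol=1e-12)


def _tiny_spec(seed=0, hub=False):
    # a hub at rho = 0.9 forces its targets mutually correlated; one-factor 0.81
    hubs = (DifferentialHub(0, (1, 2, 3), 0.9, 0.0),) if hub else ()
    blocks = (Block((4, 5, 6), 0.85),) + ((Block((1, 2, 3), 0.81),) if hub else ())
    return CohortSpec(V=8, n_A=25, n_B=25, blocks=blocks, differential_hubs=hubs, seed=seed)


class TestRunDifferentialAnalysis:
    def test_self_comparison_all_null(self):
        a, _ = sample_cohort(_tiny_spec(seed=4))
        res = run_differential_analysis(a, a, RunConfig(B=49, seed=1))
        assert np.all(res.node_stat == 0)
        assert np.all(res.node_p == 1.0)
        assert np.all(res.node_q == 1.0)
        assert res.network_stat == 0.0

    def test_bit_reproducible_given_config(self):
        a, b = sample_cohort(_tiny_spec(seed=5))
        cfg = RunConfig(B=49, seed=77)
        r1 = run_differential_analysis(a, b, cfg)
        r2 = run_differential_analysis(a, b, cfg)
        assert np.array_equal(r1.node_stat, r2.node_stat)
        assert np.array_equal(r1.node_p, r2.node_p)
        assert np.array_equal(r1.node_q, r2.node_q)
        assert r1.network_p == r2.network_p
        assert r1.config_fingerprint == r2.config_fingerprint

    def test_injected_hub_attains_max_statistic(self):
        a, b = sample_cohort(_tiny_spec(seed=6, hub=True))
        res = run_differential_analysis(a, b, RunConfig(B=99, seed=3))
        assert int(np.argmax(res.node_stat)) == 0

    def test_label_mismatch_rejected(self):
        a, b = sample_cohort(_tiny_spec(seed=7))
        bad = type(b)(b.subject_ids, tuple(reversed(b.voi_labels)), b.values)
        with pytest.raises(ValueError, match="VOI labels"):
            run_differential_analysis(a, bad, RunConfig(B=9))

    def test_report_frame_sorted_by_q_then_stat(self):
        a, b = sample_cohort(_tiny_spec(seed=8, hub=True))
        df = run_differential_analysis(a, b, RunConfig(B=49, seed=2)).to_frame()
        assert list(df.columns) == [
            "node", "test_statistic", "nominal_p", "q_value", "degree_A", "degree_B",
        ]
        q = df["q_value"].to_numpy()
        assert np.all(np.diff(q) >= 0)


class TestCalibrationUnderExchangeableWeights:
    def test_type_i_exact_for_iid_weight_graphs(self):
        """With iid edge weights the weight-permutation null is exactly calibrated.

        Two independent random graphs with iid weights per replicate; the
        observed weight assignment is exchangeable with the permuted ones, so
        P(p <= 0.05) should sit at 0.05 up to binomial noise.  (On cohorts
        with correlated blocks the same test is anti-conservative, because a
        node's incident sample correlations are mutually dependent.)
        """
        from petnet.network import degrees_from_edges, threshold_network
        from petnet.nulls import generate_ensemble

        rng = np.random.default_rng(314)
        V, B, reps = 30, 199, 30
        hits = total = 0
        labels = [f"n{i}" for i in range(V)]
        for _ in range(reps):
            nets = []
            for _g in range(2):
                iu, ju = np.triu_indices(V, k=1)
                keep = rng.random(iu.size) < 0.15
                w = 0.7 + 0.25 * rng.random(int(keep.sum()))
                corr = np.eye(V)
                corr[iu[keep], ju[keep]] = w
                corr[ju[keep], iu[keep]] = w
                nets.append(threshold_network(corr, labels, 0.7))
            obs = np.abs(
                degrees_from_edges(V, nets[0].edge_i, nets[0].edge_j, nets[0].edge_r)
                - degrees_from_edges(V, nets[1].edge_i, nets[1].edge_j, nets[1].edge_r)
            )
            stacks = []
            for net in nets:
                ens = generate_ensemble(net, B=B, seed=int(rng.integers(2**31)))
                stacks.append(np.vstack([degrees_from_edges(V, *r) for r in ens.replicates]))
            null = np.abs(stacks[0] - stacks[1])
            p = (1 + (np.round(null, 12) >= np.round(obs, 12)).sum(axis=0)) / (B + 1)
            hits += int((p <= 0.05).sum())
            total += V
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], total, 0.05) / total
        assert lo <= hits / total <= hi
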