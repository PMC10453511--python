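"""Perturbation protocol, regulatory values, probability transform, AUC."""

import warnings

import numpy as np
import pytest

import aesgrn
from aesgrn.environment import AES, PerturbationSpec, StateMatrix, perturbation_value
from aesgrn.errors import DataError, SpecError
from aesgrn.inference import (
    PerturbationConfig,
    _one_sided_probability,
    auc_roc,
    build_probability_matrix,
    build_regulatory_matrix,
    edge_probability,
    perturb_and_record,
    regulatory_value,
    run_to_steady_state,
    thresholds,
)
from tests.conftest import StubAgent, copy_last_agents


def ols_arctan_oracle(y):
    """Brute-force normal equations: slope of y on 0..len-1, then arctan."""
    t = np.arange(len(y), dtype=float)
    A = np.vstack([t, np.ones_like(t)]).T
    slope = np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))[0]
    return np.arctan(slope)


class TestRegulatoryValue:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0, 0.1, 0.2, 0.3], np.arctan(0.1)),
            ([0.4, 0.4, 0.4, 0.4], 0.0),
            ([0, 1, 2, 3], np.pi / 4),
        ],
    )
    def test_known_slopes(self, column, expected):
        assert regulatory_value(column) == pytest.approx(expected, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.normal(size=rng.integers(2, 40))
            assert regulatory_value(y) == pytest.approx(ols_arctan_oracle(y), abs=1e-9)

    def test_bounded_by_half_pi(self):
        assert abs(regulatory_value([0, 1e6])) < np.pi / 2


class TestSteadyState:
    def test_fixed_point_converges_immediately(self):
        n, m = 3, 5
        aes = AES(copy_last_agents(n, m))
        state = StateMatrix(np.full((n, m), 0.4), t=m - 1)
        result = run_to_steady_state(aes, state)
        assert result.converged

    def test_oscillator_hits_t_max_with_warning(self):
        aes = AES([StubAgent(lambda X: 1.0 - X[0, -1], 1, 3)])
        state = StateMatrix(np.array([[0.0, 1.0, 0.0]]), t=2)
        with pytest.warns(UserWarning, match="no steady state"):
            result = run_to_steady_state(aes, state, eps=1e-3, t_max=60)
        assert not result.converged

    def test_geometric_decay_converges_quickly(self):
        aes = AES([StubAgent(lambda X: 0.5 * X[0, -1], 1, 3)])
        state = StateMatrix(np.full((1, 3), 1.0), t=2)
        result = run_to_steady_state(aes, state, eps=1e-3, t_max=100)
        assert result.converged and result.t_f <= 25


class TestPerturbAndRecord:
    def test_instability_interval_length(self):
        n, m = 4, 10
        aes = AES(copy_last_agents(n, m))
        snapshot = StateMatrix(np.full((n, m), 0.2), t=m - 1)
        spec = PerturbationSpec("instant", 1, baseline=0.2, width=0.3, duration=10)
        x_r = perturb_and_record(aes, snapshot, 1, spec)
        assert x_r.shape == (2 * m + 10, n)

    def test_zero_width_perturbation_keeps_constant_trace(self):
        n, m = 3, 4
        aes = AES([StubAgent(lambda X: 0.5, n, m) for _ in range(n)])
        snapshot = StateMatrix(np.full((n, m), 0.5), t=m - 1)
        spec = PerturbationSpec("instant", 0, baseline=0.5, width=0.0, duration=4)
        x_r = perturb_and_record(aes, snapshot, 0, spec)
        assert np.allclose(x_r, 0.5)

    def test_perturbed_rows_follow_profile(self):
        n, m = 3, 5
        aes = AES(copy_last_agents(n, m))
        snapshot = StateMatrix(np.full((n, m), 0.1), t=m - 1)
        spec = PerturbationSpec(
            "trapezium", 2, baseline=0.1, width=0.6, duration=6, peak_steps=2
        )
        x_r = perturb_and_record(aes, snapshot, 2, spec)
        window = x_r[m : m + 6, 2]
        expected = [perturbation_value(spec, s) for s in range(6)]
        np.testing.assert_allclose(window, expected)


class TestThresholds:
    def test_hand_example_medians_and_extrema(self):
        col = np.array([0.3, -0.1, 0.2, -0.5, 0.0])
        R = col[:, None]
        ts = thresholds(R)
        assert ts.tau_pos[0] == pytest.approx(0.25)
        assert ts.tau_neg[0] == pytest.approx(-0.3)
        assert ts.r_max[0] == pytest.approx(0.3)
        assert ts.r_min[0] == pytest.approx(-0.5)
        assert not ts.pos_degenerate[0] and not ts.neg_degenerate[0]

    def test_all_positive_column_flags_degenerate(self):
        with pytest.warns(UserWarning, match="no negative"):
            ts = thresholds(np.array([[0.1], [0.2], [0.3]]))
        assert ts.neg_degenerate[0]

    def test_singleton_median(self):
        with pytest.warns(UserWarning):
            ts = thresholds(np.array([[0.4], [-0.0], [0.0]]))
        assert ts.tau_pos[0] == pytest.approx(0.4)

    def test_matches_bruteforce_medians(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(12, 7))
        ts = thresholds(R)
        for j in range(7):
            pos = sorted(v for v in R[:, j] if v > 0)
            neg = sorted(v for v in R[:, j] if v < 0)
            assert ts.tau_pos[j] == pytest.approx(np.median(pos), abs=1e-15)
            assert ts.tau_neg[j] == pytest.approx(np.median(neg), abs=1e-15)


class TestEdgeProbability:
    def test_zero_response_gives_zero_probability(self):
        assert edge_probability(0.0, 0.2, -0.2, 0.6, -0.6) == 0.0

    def test_half_at_thresholds(self):
        for tau_n, tau_p in [(-0.2, 0.2), (-0.05, 0.3)]:
            assert edge_probability(tau_p, tau_p, tau_n, 0.9, -0.9) == pytest.approx(0.5)
            assert edge_probability(tau_n, tau_p, tau_n, 0.9, -0.9) == pytest.approx(0.5)

    def test_hand_evaluated_branches(self):
        assert edge_probability(0.1, 0.2, -0.2, 0.6, -0.6) == pytest.approx(0.125)
        assert edge_probability(0.4, 0.2, -0.2, 0.6, -0.6) == pytest.approx(0.75)

    def test_continuous_at_thresholds(self):
        tau_p, tau_n, r_max, r_min = 0.3, -0.15, 0.8, -0.7
        for tau in (tau_p, tau_n):
            lo = edge_probability(tau - 1e-9, tau_p, tau_n, r_max, r_min)
            hi = edge_probability(tau + 1e-9, tau_p, tau_n, r_max, r_min)
            assert abs(lo - hi) < 1e-6

    def test_bounded_on_dense_grid(self):
        tau_p, tau_n, r_max, r_min = 0.25, -0.4, 1.1, -1.3
        for r in np.linspace(r_min, r_max, 2001):
            p = edge_probability(float(r), tau_p, tau_n, r_max, r_min)
            assert 0.0 <= p <= 1.0

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = edge_probability(2.0, 0.2, -0.2, 0.6, -0.6)
        assert p == 1.0

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(SpecError):
            edge_probability(0.0, -0.2, 0.2, 0.6, -0.6)

    def test_one_sided_collapse_is_continuous(self):
        assert _one_sided_probability(0.0, 0.3, 0.9) == 0.0
        assert _one_sided_probability(0.3, 0.3, 0.9) == pytest.approx(0.5)
        assert _one_sided_probability(0.9, 0.3, 0.9) == pytest.approx(1.0)
        lo = _one_sided_probability(0.3 - 1e-9, 0.3, 0.9)
        assert abs(lo - 0.5) < 1e-6


class TestProbabilityMatrix:
    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        R = rng.normal(scale=0.3, size=(9, 9))
        ts = thresholds(R)
        P = build_probability_matrix(R, ts)
        for i in range(9):
            for j in range(9):
                expected = edge_probability(
                    R[i, j], ts.tau_pos[j], ts.tau_neg[j], ts.r_max[j], ts.r_min[j]
                )
                assert P[i, j] == pytest.approx(expected, abs=1e-15)

    def test_zero_matrix_maps_to_zero(self):
        R = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            ts = thresholds(R)
        assert np.all(build_probability_matrix(R, ts) == 0.0)

    def test_threshold_entries_map_to_half(self):
        # column 1 has an odd number of positives, so tau_pos is an entry
        R = np.array([[0.2, -0.1], [-0.4, 0.3], [0.6, -0.2], [-0.2, 0.5],
                      [0.1, 0.7]])
        ts = thresholds(R)
        assert ts.tau_pos[1] == pytest.approx(0.5)
        P = build_probability_matrix(R, ts)
        assert P[3, 1] == pytest.approx(0.5)


class TestAuc:
    def test_pairwise_example(self):
        gold = aesgrn.GoldNetwork(
            ["a", "b"], {("a", "b"): 1, ("b", "a"): 0}, include_self_loops=True
        )
        gold.labels.update({("a", "a"): 1, ("b", "b"): 0})
        P = np.array([[0.9, 0.8], [0.4, 0.2]])
        # labels row-major: aa=1, ab=0... rebuild for clarity below
        gold = aesgrn.GoldNetwork(
            ["a", "b"],
            {("a", "a"): 1, ("a", "b"): 0, ("b", "a"): 1, ("b", "b"): 0},
            include_self_loops=True,
        )
        assert auc_roc(P, gold) == pytest.approx(0.75)

    def test_perfect_separation(self):
        gold = aesgrn.GoldNetwork(["a", "b"], {("a", "b"): 1})
        P = np.array([[0.0, 0.9], [0.1, 0.0]])
        assert auc_roc(P, gold) == 1.0

    def test_all_ties_give_half(self):
        gold = aesgrn.GoldNetwork(["a", "b", "c"], {("a", "b"): 1})
        assert auc_roc(np.full((3, 3), 0.4), gold) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        gold = aesgrn.GoldNetwork(["a", "b"], {})
        with pytest.raises(DataError):
            auc_roc(np.zeros((2, 2)), gold)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            names = [f"g{i}" for i in range(n)]
            P = rng.random((n, n))
            labels = {}
            for r in names:
                for t in names:
                    if r != t and rng.random() < 0.3:
                        labels[(r, t)] = 1
            gold = aesgrn.GoldNetwork(names, labels)
            lv = gold.label_vector()
            if lv.min() == lv.max():
                continue
            scores = np.array(
                [P[names.index(r), names.index(t)]
                 for r, t in aesgrn.datasets.ordered_pairs(names)]
            )
            pos = scores[lv == 1]
            neg = scores[lv == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (len(pos) * len(neg))
            assert auc_roc(P, gold) == pytest.approx(oracle, abs=1e-12)


class TestEndToEndStub:
    def test_known_causal_link_outranks_median(self):
        # gene 1 copies gene 0's last value; all other genes relax to 0.3
        n, m = 5, 6
        agents = [StubAgent(lambda X: 0.5 * X[0, -1] + 0.15, n, m),
                  StubAgent(lambda X: X[0, -1], n, m)]
        agents += [StubAgent(lambda X, j=j: 0.5 * X[j, -1] + 0.15, n, m)
                   for j in range(2, n)]
        aes = AES(agents)
        init = StateMatrix(np.full((n, m), 0.3), t=m - 1)
        config = PerturbationConfig(kind="trapezium", gene_max=np.ones(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate columns may warn
            R, _ = build_regulatory_matrix(aes, init, config)
            P = build_probability_matrix(R, thresholds(R))
        mask = ~np.eye(n, dtype=bool)
        assert P[0, 1] > np.median(P[mask])

    def test_regulatory_matrix_shape_and_constant_zero(self):
        n, m = 4, 5
        aes = AES([StubAgent(lambda X: 0.25, n, m) for _ in range(n)])
        init = StateMatrix(np.full((n, m), 0.25), t=m - 1)
        config = PerturbationConfig(kind="instant", width=0.0, gene_max=np.ones(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R, _ = build_regulatory_matrix(aes, init, config)
        assert R.shape == (n, n)
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_upward_perturbation_of_driver_gives_positive_value(self):
        n, m = 3, 5
        agents = [StubAgent(lambda X: 0.5 * X[0, -1] + 0.1, n, m),
                  StubAgent(lambda X: X[0, -1], n, m),
                  StubAgent(lambda X: 0.2, n, m)]
        aes = AES(agents)
        init = StateMatrix(np.full((n, m), 0.2), t=m - 1)
        config = PerturbationConfig(kind="instant", gene_max=np.ones(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R, _ = build_regulatory_matrix(aes, init, config)
        assert R[0, 1] > 0
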