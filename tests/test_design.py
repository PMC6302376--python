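"""MOCU, experiment scoring/selection, sequential design, benchmark harness."""

import numpy as np
import pytest

from grndesign import (
    BenchmarkConfig,
    ControlProblem,
    DesignConfig,
    UncertaintyClass,
    bnp_tpm,
    compare_outcomes,
    cpms_from_tpm,
    effective_tpm,
    evaluate_determination,
    expected_cost,
    mocu,
    random_bnp,
    realize_cpms,
    run_benchmark,
    score_experiment,
    select_experiment,
    sequential_design,
    tpm_from_cpms,
    value_iteration,
)
from grndesign.cpm_uncertainty import CPMSet
from grndesign.design import run_sequential_benchmark


def make_instance(seed, n=2, k=1, p=0.05, n_unknown=1):
    """Random network + CPMs + uniform-prior unknowns + a control problem."""
    rng = np.random.default_rng(seed)
    net = random_bnp(n=n, k=k, p=p, rng=rng)
    cpms = cpms_from_tpm(bnp_tpm(net), net.regulators)
    positions = []
    while len(positions) < n_unknown:
        pos = (int(rng.integers(n)), int(rng.integers(2 ** k)))
        if pos not in positions:
            positions.append(pos)
    unc = UncertaintyClass.uniform(positions)
    prob = ControlProblem(
        n_genes=n,
        control_gene=int(rng.integers(n)),
        undesirable=[int(rng.integers(2 ** n))],
        zeta=0.2,
    )
    return cpms, unc, prob


def quadrature_score(cpms, unc, prob, index, n_points=1001, vi_iterations=None):
    """Trapezoid-rule oracle for the expected post-experiment robust cost
    (uniform Beta(1,1) marginal)."""
    ts = np.linspace(0.0, 1.0, n_points)
    vals = []
    for t in ts:
        cond = unc.condition_on(index, float(t))
        etpm = effective_tpm(cpms, cond)
        pol = value_iteration(etpm, prob, iterations=vi_iterations)
        vals.append(expected_cost(etpm, pol, prob))
    return float(np.trapezoid(vals, ts))


class TestMocu:
    def test_empty_class_is_zero(self, bnp6_cpms, synthetic_problem):
        assert mocu(bnp6_cpms, UncertaintyClass(()), synthetic_problem, 10, 0) == 0.0

    def test_nonnegative(self):
        for seed in range(5):
            cpms, unc, prob = make_instance(seed, n_unknown=2)
            assert mocu(cpms, unc, prob, n_samples=40, rng=seed) >= 0.0

    def test_agrees_with_quadrature_on_one_unknown(self):
        """MC MOCU matches a fine-grid quadrature of the per-model regret."""
        cpms, unc, prob = make_instance(3)
        ts = np.linspace(0, 1, 1001)
        etpm = effective_tpm(cpms, unc)
        robust = value_iteration(etpm, prob, iterations=None)
        regret = []
        for t in ts:
            P_t = tpm_from_cpms(realize_cpms(cpms, unc, np.array([t])))
            r = expected_cost(P_t, robust, prob) - expected_cost(
                P_t, value_iteration(P_t, prob, iterations=None), prob
            )
            regret.append(r)
        quad = np.trapezoid(regret, ts)
        draws = np.array(
            [mocu(cpms, unc, prob, n_samples=200, rng=s) for s in range(8)]
        )
        sem = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - quad) < 3 * sem + 1e-4


class TestScoring:
    def test_stratified_score_matches_quadrature(self):
        cpms, unc, prob = make_instance(7)
        cfg = DesignConfig(method="optimal", n_samples=500, vi_iterations=None)
        got = score_experiment(cpms, unc, prob, 0, cfg, rng=0)
        want = quadrature_score(cpms, unc, prob, 0)
        assert abs(got - want) < 1e-3

    def test_random_mc_score_within_noise_of_quadrature(self):
        cpms, unc, prob = make_instance(7)
        want = quadrature_score(cpms, unc, prob, 0)
        cfg = DesignConfig(
            method="optimal", n_samples=400, vi_iterations=None, stratified=False
        )
        draws = np.array(
            [score_experiment(cpms, unc, prob, 0, cfg, rng=s) for s in range(8)]
        )
        sem = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - want) < 3 * sem + 1e-4

    def test_conditioning_cannot_hurt_in_model_space(self):
        """Information never hurts, measured on realized models: for every
        outcome, the conditioned-optimal policy is no worse than the
        unconditioned robust policy on that model (quadrature-exact)."""
        for seed in range(10):
            cpms, unc, prob = make_instance(seed)
            etpm = effective_tpm(cpms, unc)
            robust = value_iteration(etpm, prob, iterations=None)
            for t in np.linspace(0, 1, 101):
                P_t = tpm_from_cpms(realize_cpms(cpms, unc, np.array([t])))
                opt = value_iteration(P_t, prob, iterations=None)
                assert expected_cost(P_t, opt, prob) <= expected_cost(
                    P_t, robust, prob
                ) + 1e-9

    def test_scoring_revealed_parameter_rejected(self):
        cpms, unc, prob = make_instance(2)
        cond = unc.condition_on(0, 0.5)
        with pytest.raises(ValueError):
            score_experiment(cpms, cond, prob, 0)


class TestSelection:
    def test_single_unknown_is_selected(self):
        cpms, unc, prob = make_instance(5)
        rep = select_experiment(cpms, unc, prob, DesignConfig(), rng=0)
        assert rep.selected == 0
        assert rep.ranking == (0,)

    def test_reproducible_bit_for_bit(self):
        cpms, unc, prob = make_instance(9, n=2, n_unknown=2)
        cfg = DesignConfig(method="mfpt", rollout_n=200)
        a = select_experiment(cpms, unc, prob, cfg, rng=42)
        b = select_experiment(cpms, unc, prob, cfg, rng=42)
        assert a.scores == b.scores
        assert a.ranking == b.ranking and a.selected == b.selected

    def test_agrees_with_quadrature_oracle_on_skewed_instance(self):
        """One unknown sits in a rarely-consulted regulator context, the other
        drives the dynamics: selection must match the quadrature oracle."""
        # X1 | X2, X2 | X2; X2 is sticky, and the undesirable corner needs
        # X2=1, so the X2=0 row of X1 hardly ever routes mass into U while
        # the X2=1 row controls it directly.
        tables = (
            np.array([[0.5, 0.5], [0.5, 0.5]]),      # X1 | X2 (both rows unknown)
            np.array([[0.98, 0.02], [0.02, 0.98]]),  # X2 holds its value
        )
        cpms = CPMSet(tables, ((1,), (1,)))
        unc = UncertaintyClass.uniform([(0, 0), (0, 1)])
        prob = ControlProblem(n_genes=2, control_gene=1, undesirable=[3], zeta=0.2)
        cfg = DesignConfig(method="optimal", n_samples=200, vi_iterations=None)
        rep = select_experiment(cpms, unc, prob, cfg, rng=0)
        oracle = {
            i: quadrature_score(cpms, unc, prob, i, n_points=401) for i in (0, 1)
        }
        assert rep.selected == min(oracle, key=oracle.get)
        # the influential context (X2=1, row 1) is the one worth measuring
        assert rep.selected == 1


class TestCompareOutcomes:
    @pytest.mark.parametrize(
        "diff,expected",
        [
            (-0.003, "success"),
            (0.001, "tie"),
            (0.0025, "failure"),
            (-0.002, "tie"),
            (0.002, "tie"),
        ],
    )
    def test_classification(self, diff, expected):
        assert compare_outcomes(diff, 0.0) == expected

    def test_requires_positive_tolerance(self):
        with pytest.raises(ValueError):
            compare_outcomes(1.0, 1.0, tol=0.0)


class TestEvaluateDetermination:
    def test_zero_cost_table(self):
        cpms, unc, prob = make_instance(4)
        prob.cost = np.zeros((4, 4, 2))
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, np.array([0.4])))
        got = evaluate_determination(true_P, cpms, unc, 0, 0.4, prob, 500, 6, 0)
        assert got == 0.0

    def test_absorbing_undesirable_geometric_sum(self):
        """When every state is undesirable and the policy never acts, the
        horizon-6 discounted cost is 5(1 - 0.2^6)/0.8 = 6.2496 exactly."""
        tables = (np.array([[0.5, 0.5], [0.5, 0.5]]),)
        cpms = CPMSet(tables, ((0,),))
        unc = UncertaintyClass.uniform([(0, 0)])
        prob = ControlProblem(n_genes=1, control_gene=0, undesirable=[0, 1], zeta=0.2)
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, np.array([0.3])))
        got = evaluate_determination(true_P, cpms, unc, 0, 0.3, prob, 200, 6, 1)
        assert got == pytest.approx(6.2496)


class TestSequentialDesign:
    def test_full_budget_identifies_the_network(self):
        cpms, unc, prob = make_instance(11, n=2, n_unknown=2)
        truths = np.array([0.35, 0.8])
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, truths))
        rep = sequential_design(
            true_P, cpms, unc, truths, prob, DesignConfig(), budget=2,
            eval_n=200, rng=0, eval_exact=True,
        )
        assert len(rep.step_costs) == 3
        assert sorted(rep.selections) == [0, 1]
        # after full identification the recorded cost is that of the true
        # network's own value-iteration policy
        final_pol = value_iteration(true_P, prob, iterations=4)
        assert rep.step_costs[-1] == pytest.approx(
            expected_cost(true_P, final_pol, prob)
        )

    def test_zero_budget_reports_only_initial_cost(self):
        cpms, unc, prob = make_instance(11, n=2, n_unknown=2)
        truths = np.array([0.35, 0.8])
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, truths))
        rep = sequential_design(
            true_P, cpms, unc, truths, prob, DesignConfig(), budget=0,
            eval_n=200, rng=0,
        )
        assert len(rep.step_costs) == 1
        assert rep.selections == []

    def test_budget_cannot_exceed_unknowns(self):
        cpms, unc, prob = make_instance(11, n=2, n_unknown=2)
        truths = np.array([0.35, 0.8])
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, truths))
        with pytest.raises(ValueError):
            sequential_design(
                true_P, cpms, unc, truths, prob, DesignConfig(), budget=3
            )

    def test_common_eval_seeds_pin_the_endpoints(self):
        cpms, unc, prob = make_instance(13, n=2, n_unknown=2)
        truths = np.array([0.2, 0.9])
        true_P = tpm_from_cpms(realize_cpms(cpms, unc, truths))
        seeds = [101, 102, 103]
        a = sequential_design(
            true_P, cpms, unc, truths, prob, DesignConfig(), budget=2,
            eval_n=500, rng=1, eval_seeds=seeds,
        )
        b = sequential_design(
            true_P, cpms, unc, truths, prob, DesignConfig(), budget=2,
            selection="random", eval_n=500, rng=2, eval_seeds=seeds,
        )
        assert a.step_costs[0] == b.step_costs[0]
        assert a.step_costs[-1] == b.step_costs[-1]


class TestBenchmarkHarness:
    def test_single_experiment_makes_all_policies_equal(self):
        cfg = BenchmarkConfig(
            n_networks=1, n_truth_sets=1, T=1, eval_n=300, design_samples=4,
            score_rollout_n=50, seed=5,
        )
        res = run_benchmark(cfg)
        sel = res["selection_costs"]["mean_cost"]
        assert sel["random"] == sel["optimal"] == sel["approximate"]

    def test_deterministic_under_seed(self):
        cfg = BenchmarkConfig(
            n_networks=1, n_truth_sets=2, T=2, eval_n=200, design_samples=4,
            score_rollout_n=50, seed=6,
        )
        a = run_benchmark(cfg)["raw"]
        b = run_benchmark(cfg)["raw"]
        assert a.equals(b)

    def test_posterior_update_path_runs(self):
        cfg = BenchmarkConfig(
            n_networks=1, n_truth_sets=1, T=2, L=10, eval_n=200,
            design_samples=4, score_rollout_n=50, seed=8,
        )
        res = run_benchmark(cfg)
        assert len(res["raw"]) == 1

    def test_sequential_curves_share_endpoints(self):
        cfg = BenchmarkConfig(
            n_networks=2, n_truth_sets=1, T=2, eval_n=300, design_samples=4,
            score_rollout_n=50, seed=9,
        )
        res = run_sequential_benchmark(cfg, eval_exact=True)
        curves = res["curves"]
        assert curves.shape == (3, 3)
        for m in ("optimal", "mfpt"):
            assert curves[m].iloc[0] == curves["random"].iloc[0]
            assert curves[m].iloc[-1] == curves["random"].iloc[-1]
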