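import numpy as np
import pytest

from oracles import brute_force_optimal_loss
from stoptask.belief import BeliefState, GenerativeParams, init_belief
from stoptask.policy import (
    CostParams,
    GridSpec,
    PolicyTable,
    compute_policy,
    exact_policy_loss,
    q_go,
    q_wait,
    simulate_trial,
    simulate_trials,
    terminal_value,
)


def _b(p_d=0.5, p_s=0.25, t=1):
    return BeliefState(t=t, p_d=p_d, w0=1 - p_s, w1=p_s, w2=0.0)


class TestCostPieces:
    def test_terminal_value(self):
        cost = CostParams(c=0.002, c_s=0.4)
        assert terminal_value(_b(p_s=1.0), cost, D=50) == pytest.approx(0.1)
        assert terminal_value(_b(p_s=0.0), cost, D=50) == pytest.approx(0.1 + 1.0)
        assert terminal_value(_b(p_s=0.3), cost, D=50) == pytest.approx(0.8)

    def test_q_go(self):
        cost = CostParams(c=0.002, c_s=0.4)
        assert q_go(_b(p_s=1.0), 7, cost) == pytest.approx(0.002 * 7 + 0.4)
        assert q_go(_b(p_d=0.5, p_s=0.0), 7, cost) == pytest.approx(0.014 + 0.5)
        assert q_go(_b(p_d=0.9, p_s=0.45), 10, cost) == pytest.approx(0.255)

    def test_q_wait_deadline_branch(self):
        gen = GenerativeParams(D=50)
        cost = CostParams(c=0.002, c_s=0.4)
        assert q_wait(_b(p_s=0.25, t=49), 49, None, gen, cost) == pytest.approx(0.85)

    def test_q_wait_uninformative_channels_no_onset(self):
        # q_d=q_s=0.5 and q tiny: belief barely moves, so waiting at D-2
        # chains into the deadline branch at D-1
        gen = GenerativeParams(q_d=0.5, q_s=0.5, q=1e-12, D=10)
        cost = CostParams(c=0.002, c_s=0.4)
        b = _b(p_s=0.3, t=gen.D - 2)
        v_next = lambda nb: cost.c * gen.D + 1.0 - nb.p_s  # noqa: E731
        expected = cost.c * gen.D + 1.0 - b.p_s
        assert q_wait(b, gen.D - 2, v_next, gen, cost) == pytest.approx(expected, abs=1e-9)

    def test_q_wait_requires_next_values_before_deadline(self):
        gen = GenerativeParams(D=10)
        with pytest.raises(ValueError):
            q_wait(_b(), 3, None, gen, CostParams())


class TestComputePolicy:
    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(1, 1)

    def test_costly_delay_goes_immediately(self):
        # with c huge and c_s negligible, waiting only accrues cost
        gen = GenerativeParams(D=10)
        with pytest.warns(UserWarning):
            table = compute_policy(gen, CostParams(c=0.5, c_s=1e-9), GridSpec(20, 20))
        assert table.action[0].all()

    def test_free_delay_waits_until_final_step(self):
        # c=0: information is free, so Wait weakly dominates at t <= D-2
        # (Go can only become optimal at D-1, where the deadline forfeits
        # the response).  Exact in the history recursion; on the grid any
        # apparent early Go advantage is within discretization slack.
        gen = GenerativeParams(D=6)
        cost = CostParams(c=1e-12, c_s=0.4)

        from stoptask.belief import predictive_obs_dist, step_belief

        def value(b):
            if b.t + 1 == gen.D:
                qw = cost.c * gen.D + 1.0 - b.p_s
            else:
                P = predictive_obs_dist(b, gen)
                qw = sum(
                    P[x, y] * value(step_belief(b, x, y, gen))
                    for x in (0, 1)
                    for y in (0, 1)
                )
            if 1 <= b.t <= gen.D - 2:
                # slack: the residual delay cost c*(D-t) plus roundoff
                assert qw <= q_go(b, b.t, cost) + cost.c * gen.D + 1e-12
            return qw if b.t == 0 else min(q_go(b, b.t, cost), qw)

        value(init_belief(gen))

        table = compute_policy(gen, cost, GridSpec(20, 20))
        early = table.action[: gen.D - 2]
        if early.any():
            gap = (table.Q_wait[: gen.D - 2] - table.Q_go[: gen.D - 2])[early]
            assert gap.max() < 0.05  # discretization slack, not a real advantage
        assert table.action[gen.D - 2].any()

    def test_paper_parameters_region_structure(self, paper_gen, paper_cost):
        table = compute_policy(paper_gen, paper_cost, GridSpec(200, 200))
        for t in range(paper_gen.D - 1):
            assert table.action[t].any(), f"no Go region at t={t + 1}"
            assert not table.action[t].all(), f"no Wait region at t={t + 1}"
        # Go fires at extreme p_d / small p_s; Wait holds the center
        assert table.action[30, 0, 0] and table.action[30, -1, 0]
        mid = table.grid.n_pd // 2
        assert not table.action[30, mid, 100]

    def test_value_function_invariants(self, paper_gen, paper_cost):
        table = compute_policy(paper_gen, paper_cost, GridSpec(50, 50))
        assert np.allclose(table.V, np.minimum(table.Q_go, table.Q_wait))
        for t in range(1, paper_gen.D):
            assert (table.V[t - 1] >= paper_cost.c * t - 1e-12).all()

    def test_export_roundtrip_shape(self, paper_gen, paper_cost):
        table = compute_policy(paper_gen, paper_cost, GridSpec(5, 5))
        frame = table.to_frame()
        assert len(frame) == (paper_gen.D - 1) * 25
        assert set(frame["action"]) <= {"go", "wait"}


class TestOracleEquivalence:
    """Backward induction on exact beliefs vs generative enumeration."""

    @pytest.mark.parametrize(
        "D, q, r, c, c_s",
        [
            (3, 0.3, 0.3, 0.05, 0.5),
            (4, 0.3, 0.3, 0.02, 0.5),
            (4, 0.5, 0.2, 0.01, 0.8),
            (4, 0.2, 0.45, 0.03, 0.4),
        ],
    )
    def test_exact_dp_matches_brute_force(self, D, q, r, c, c_s):
        gen = GenerativeParams(q_d=0.62, q_s=0.7, q=q, r=r, D=D, step_ms=22.0)
        cost = CostParams(c=c, c_s=c_s)
        assert exact_policy_loss(gen, cost) == pytest.approx(
            brute_force_optimal_loss(gen, cost), abs=1e-9
        )

    def test_grid_policy_loss_near_optimum(self):
        """The 200x200 grid policy's Monte-Carlo loss is close to exact."""
        gen = GenerativeParams(q_d=0.62, q_s=0.72, q=0.25, r=0.3, D=8, step_ms=22.0)
        cost = CostParams(c=0.002, c_s=0.5)
        optimum = exact_policy_loss(gen, cost)
        table = compute_policy(gen, cost, GridSpec(200, 200), keep_values=False)
        rng = np.random.default_rng(5)
        n = 200000
        s = (rng.random(n) < gen.r).astype(int)
        theta = np.where(s == 1, rng.geometric(gen.q, n), 0)
        d = rng.integers(0, 2, n)
        out = simulate_trials(table, gen, d, s, theta, rng)
        loss = (
            cost.c * out["tau"]
            + cost.c_s * (out["responded"] & (s == 1))
            + (out["responded"] & (s == 0) & (out["choice"] != d))
            + (~out["responded"] & (s == 0))
        )
        mc = loss.mean()
        sem = loss.std() / np.sqrt(n)
        assert mc == pytest.approx(optimum, abs=max(5 * sem, 2e-3))
        assert mc > optimum - 5 * sem  # cannot genuinely beat the optimum


def _forced_policy(gen: GenerativeParams, go: bool) -> PolicyTable:
    grid = GridSpec(10, 10)
    action = np.full((gen.D - 1, 10, 10), go, dtype=bool)
    return PolicyTable(gen=gen, cost=CostParams(), grid=grid, action=action)


class TestSimulateTrial:
    def test_all_go_policy_fires_immediately(self, paper_gen, rng):
        table = _forced_policy(paper_gen, go=True)
        out = simulate_trial(table, paper_gen, (0, 0, None), rng)
        assert out.tau == 1 and out.responded
        assert out.rt_ms == pytest.approx(paper_gen.step_ms)

    def test_all_wait_policy_runs_to_deadline(self, paper_gen, rng):
        table = _forced_policy(paper_gen, go=False)
        stop = simulate_trial(table, paper_gen, (1, 1, 5), rng)
        go = simulate_trial(table, paper_gen, (1, 0, None), rng)
        assert stop.tau == paper_gen.D and stop.outcome == "stop_success"
        assert go.outcome == "omission" and go.rt_ms is None

    def test_inconsistent_truth_rejected(self, paper_gen, rng):
        table = _forced_policy(paper_gen, go=True)
        with pytest.raises(ValueError):
            simulate_trial(table, paper_gen, (0, 0, 7), rng)
        with pytest.raises(ValueError):
            simulate_trial(table, paper_gen, (0, 1, None), rng)

    def test_choice_tracks_likelier_identity(self, paper_gen, paper_cost, rng):
        table = compute_policy(paper_gen, paper_cost, GridSpec(100, 100), keep_values=False)
        n = 3000
        d = rng.integers(0, 2, n)
        out = simulate_trials(
            table, paper_gen, d, np.zeros(n, dtype=int), np.zeros(n, dtype=int), rng
        )
        resp = out["responded"]
        # responses favor the true identity well above chance
        assert (out["choice"][resp] == d[resp]).mean() > 0.6
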