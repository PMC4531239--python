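"""Optimal Go/Wait stopping policy by backward induction.

On each trial the observer chooses, at every time step up to the
deadline ``D``, between committing to a Go response (choosing the more
probable go-stimulus identity) and waiting for one more observation.
Costs are normalized to the go-error cost: ``c`` per step of delay and
``c_s`` for responding on a stop trial; an omission (no response on a
go trial) costs 1.  The Q-factors over the belief state ``b = (p_d,
p_s)`` are

    Q_go(t, b)   = c t + c_s p_s + (1 - p_s) min(p_d, 1 - p_d)
    Q_wait(t, b) = E[ V^{t+1}(b^{t+1}) | b ]          for t + 1 < D
                 = c (t+1) + 1 - p_s                  for t + 1 = D

with terminal value ``V^D(b) = c D + (1 - p_s)``, and
``V^t = min(Q_go, Q_wait)``.  The value function is tabulated on an
equal-width grid over ``(p_d, p_s) ∈ [0,1]²`` (200 x 200 by default),
sweeping backwards from ``t = D - 1`` to ``t = 1``.

Because the grid state carries only the marginal ``p_s``, the Wait
expectation splits ``p_s`` into pre-/post-onset components using the
prior onset dynamics, ``P(signal on | stop trial, t) = 1 - (1-q)^t``.
:func:`exact_policy_loss` instead runs the dynamic program on the exact
three-component belief by recursing over observation histories; it is
exponential in ``D`` and intended for small-deadline validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from stoptask.belief import (
    BeliefState,
    GenerativeParams,
    init_belief,
    predictive_obs_dist,
    step_belief,
)

__all__ = [
    "CostParams",
    "GridSpec",
    "PolicyTable",
    "terminal_value",
    "q_go",
    "q_wait",
    "compute_policy",
    "exact_policy_loss",
    "simulate_trial",
    "simulate_trials",
    "TrialOutcome",
]


@dataclass(frozen=True)
class CostParams:
    """Behavioral cost parameters, normalized to a unit go-error cost.

    ``c`` is the cost per time step of response delay; ``c_s`` the
    penalty for responding on a stop trial.
    """

    c: float = 0.002
    c_s: float = 0.4

    def __post_init__(self) -> None:
        if self.c <= 0 or self.c_s <= 0:
            raise ValueError("c and c_s must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Equal-width discretization of the (p_d, p_s) belief square."""

    n_pd: int = 200
    n_ps: int = 200

    def __post_init__(self) -> None:
        if self.n_pd < 2 or self.n_ps < 2:
            raise ValueError("grid needs at least 2 bins per axis")

    @property
    def pd_mid(self) -> np.ndarray:
        return (np.arange(self.n_pd) + 0.5) / self.n_pd

    @property
    def ps_mid(self) -> np.ndarray:
        return (np.arange(self.n_ps) + 0.5) / self.n_ps

    def pd_index(self, p: np.ndarray | float) -> np.ndarray | int:
        return np.clip((np.asarray(p) * self.n_pd).astype(np.int64), 0, self.n_pd - 1)

    def ps_index(self, p: np.ndarray | float) -> np.ndarray | int:
        return np.clip((np.asarray(p) * self.n_ps).astype(np.int64), 0, self.n_ps - 1)


@dataclass
class PolicyTable:
    """Backward-induction solution on the belief grid.

    ``action[t-1, i, j]`` is True where Go is optimal at step ``t`` in
    bin ``(i, j)`` of the ``(p_d, p_s)`` grid.  ``V``, ``Q_go`` and
    ``Q_wait`` (same indexing) are kept when the table was computed
    with ``keep_values=True``; ``V_terminal[j]`` is the deadline value
    ``c D + 1 - p_s`` (a function of ``p_s`` only).
    """

    gen: GenerativeParams
    cost: CostParams
    grid: GridSpec
    action: np.ndarray
    V: np.ndarray | None = None
    Q_go: np.ndarray | None = None
    Q_wait: np.ndarray | None = None
    V_terminal: np.ndarray | None = None

    def action_at(self, t: int, p_d: float, p_s: float) -> bool:
        """Optimal action (True = Go) at step ``t`` by nearest-bin lookup."""
        if not 1 <= t <= self.gen.D - 1:
            raise ValueError(f"t must lie in [1, D-1], got {t}")
        return bool(self.action[t - 1, self.grid.pd_index(p_d), self.grid.ps_index(p_s)])

    def to_frame(self) -> pd.DataFrame:
        """Flat table (t, pd_bin, ps_bin, action, V, Q_go, Q_wait)."""
        if self.V is None:
            raise ValueError("policy was computed without keep_values=True")
        D = self.gen.D
        g = self.grid
        t_idx, i_idx, j_idx = np.meshgrid(
            np.arange(1, D), np.arange(g.n_pd), np.arange(g.n_ps), indexing="ij"
        )
        return pd.DataFrame(
            {
                "t": t_idx.ravel(),
                "pd_bin": g.pd_mid[i_idx.ravel()],
                "ps_bin": g.ps_mid[j_idx.ravel()],
                "action": np.where(self.action.ravel(), "go", "wait"),
                "V": self.V.ravel(),
                "Q_go": self.Q_go.ravel(),
                "Q_wait": self.Q_wait.ravel(),
            }
        )


def terminal_value(b: BeliefState, cost: CostParams, D: int) -> float:
    """Expected cost at the deadline: ``c D`` delay plus omission risk."""
    return cost.c * D + (1.0 - b.p_s)


def q_go(b: BeliefState, t: int, cost: CostParams) -> float:
    """Expected cost of responding now (choosing the likelier identity)."""
    return cost.c * t + cost.c_s * b.p_s + (1.0 - b.p_s) * min(b.p_d, 1.0 - b.p_d)


def q_wait(
    b: BeliefState,
    t: int,
    next_values: Callable[[BeliefState], float] | None,
    gen: GenerativeParams,
    cost: CostParams,
) -> float:
    """Expected cost of waiting one more step at time ``t``.

    ``next_values`` maps the successor belief to ``V^{t+1}``; it may be
    None only on the deadline branch ``t + 1 = D``, where the
    expectation of the terminal value reduces to ``c (t+1) + 1 - p_s``
    (``p_s`` is a martingale under the predictive distribution).
    """
    if t >= gen.D:
        raise ValueError(f"t must be < D, got t={t}, D={gen.D}")
    if t + 1 == gen.D:
        return cost.c * (t + 1) + 1.0 - b.p_s
    if next_values is None:
        raise ValueError("next_values required when t + 1 < D")
    P = predictive_obs_dist(b, gen)
    total = 0.0
    for x in (0, 1):
        for y in (0, 1):
            total += P[x, y] * next_values(step_belief(b, x, y, gen))
    return total


def compute_policy(
    gen: GenerativeParams,
    cost: CostParams,
    grid: GridSpec | None = None,
    keep_values: bool = True,
) -> PolicyTable:
    """Solve the stopping problem by backward induction on the belief grid.

    Ties ``Q_go == Q_wait`` resolve to Wait (act only when strictly
    beneficial).  With ``keep_values=False`` only the action table is
    retained, which is all trial simulation needs.
    """
    grid = grid or GridSpec()
    D = gen.D
    if cost.c * D >= 1.0 + cost.c_s:
        warnings.warn(
            "c*D >= 1 + c_s: waiting to the deadline is never competitive; "
            "the policy degenerates to always-Go",
            stacklevel=2,
        )

    n_pd, n_ps = grid.n_pd, grid.n_ps
    pd = grid.pd_mid
    ps = grid.ps_mid

    # Go-stimulus channel: t-independent transition of p_d under x
    px1 = pd * (1.0 - gen.q_d) + (1.0 - pd) * gen.q_d
    Px = np.stack([1.0 - px1, px1], axis=1)  # (n_pd, 2)
    pd_next = np.empty((n_pd, 2))
    for x in (0, 1):
        f1 = (1.0 - gen.q_d) if x == 1 else gen.q_d
        f0 = gen.q_d if x == 1 else (1.0 - gen.q_d)
        pd_next[:, x] = pd * f1 / (pd * f1 + (1.0 - pd) * f0)
    ipd = np.asarray(grid.pd_index(pd_next))  # (n_pd, 2)

    action = np.zeros((D - 1, n_pd, n_ps), dtype=bool)
    if keep_values:
        V_all = np.empty((D - 1, n_pd, n_ps))
        Qg_all = np.empty_like(V_all)
        Qw_all = np.empty_like(V_all)
    V_terminal = cost.c * D + 1.0 - ps

    base_go = cost.c_s * ps[None, :] + (1.0 - ps[None, :]) * np.minimum(pd, 1.0 - pd)[:, None]

    V_next: np.ndarray | None = None
    for t in range(D - 1, 0, -1):
        Q_go_t = cost.c * t + base_go
        if t + 1 == D:
            Q_wait_t = np.broadcast_to(cost.c * D + 1.0 - ps, (n_pd, n_ps)).copy()
        else:
            # split p_s by prior onset dynamics at time t, then propagate
            rho = (1.0 - gen.q) ** (t + 1)  # P(signal still pending | stop, t+1)
            w0 = 1.0 - ps
            w1 = ps * rho
            w2 = ps * (1.0 - rho)
            Py = np.empty((n_ps, 2))
            ps_next = np.empty((n_ps, 2))
            for y in (0, 1):
                g0 = gen.q_s if y == 1 else 1.0 - gen.q_s
                g1 = (1.0 - gen.q_s) if y == 1 else gen.q_s
                a0, a1, a2 = w0 * g0, w1 * g0, w2 * g1
                norm = a0 + a1 + a2
                Py[:, y] = norm
                ps_next[:, y] = (a1 + a2) / norm
            ips = np.asarray(grid.ps_index(ps_next))  # (n_ps, 2)
            Q_wait_t = np.zeros((n_pd, n_ps))
            for x in (0, 1):
                for y in (0, 1):
                    Q_wait_t += (
                        Px[:, x][:, None]
                        * Py[:, y][None, :]
                        * V_next[np.ix_(ipd[:, x], ips[:, y])]
                    )
        V_t = np.minimum(Q_go_t, Q_wait_t)
        action[t - 1] = Q_go_t < Q_wait_t
        if keep_values:
            V_all[t - 1] = V_t
            Qg_all[t - 1] = Q_go_t
            Qw_all[t - 1] = Q_wait_t
        V_next = V_t

    return PolicyTable(
        gen=gen,
        cost=cost,
        grid=grid,
        action=action,
        V=V_all if keep_values else None,
        Q_go=Qg_all if keep_values else None,
        Q_wait=Qw_all if keep_values else None,
        V_terminal=V_terminal,
    )


def exact_policy_loss(gen: GenerativeParams, cost: CostParams) -> float:
    """Minimal expected loss by exact dynamic programming on belief triples.

    Recurses over all observation histories, filtering the exact
    ``(p_d, w0, w1, w2)`` belief along each branch — no grid, no
    marginalization of the onset status.  Cost is ``O(4^D)``; use for
    small deadlines only (validation of the grid solver).
    """
    D = gen.D

    def value(b: BeliefState) -> float:
        t = b.t
        if t + 1 == D:
            qw = cost.c * D + 1.0 - b.p_s
        else:
            P = predictive_obs_dist(b, gen)
            qw = 0.0
            for x in (0, 1):
                for y in (0, 1):
                    qw += P[x, y] * value(step_belief(b, x, y, gen))
        if t == 0:
            return qw  # first action only after the first observation
        return min(q_go(b, t, cost), qw)

    return value(init_belief(gen))


@dataclass(frozen=True)
class TrialOutcome:
    """Result of simulating one trial under a policy.

    ``tau`` is the termination step (``D`` if no response); ``choice``
    the selected identity when a Go response was made, else None.
    """

    tau: int
    responded: bool
    choice: int | None
    rt_ms: float | None
    outcome: str
    p_d_final: float = field(default=np.nan)
    p_s_final: float = field(default=np.nan)


def _classify(s: int, d: int, responded: bool, choice: int | None) -> str:
    if s == 1:
        return "stop_error" if responded else "stop_success"
    if not responded:
        return "omission"
    return "go_correct" if choice == d else "discrim_error"


def simulate_trial(
    policy: PolicyTable,
    gen: GenerativeParams,
    truth: tuple[int, int, int | None],
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate one trial with true state ``(d, s, θ)`` under ``policy``.

    Observations are sampled from the generative model (the stop
    channel switches rate at the true onset ``θ``); the belief is
    filtered exactly and the policy consulted by nearest-bin lookup at
    each step ``1 .. D-1``.  ``θ`` is required (>= 1) when ``s = 1``
    and must be None on go trials.
    """
    d, s, theta = truth
    if s == 1 and (theta is None or theta < 1):
        raise ValueError("stop trial requires onset theta >= 1")
    if s == 0 and theta is not None:
        raise ValueError("go trial must have theta=None")
    out = simulate_trials(
        policy,
        gen,
        np.array([d]),
        np.array([s]),
        np.array([theta if theta is not None else 0]),
        rng,
    )
    return TrialOutcome(
        tau=int(out["tau"][0]),
        responded=bool(out["responded"][0]),
        choice=int(out["choice"][0]) if out["responded"][0] else None,
        rt_ms=float(out["rt_ms"][0]) if out["responded"][0] else None,
        outcome=str(out["outcome"][0]),
        p_d_final=float(out["p_d"][0]),
        p_s_final=float(out["p_s"][0]),
    )


def simulate_trials(
    policy: PolicyTable,
    gen: GenerativeParams,
    d: np.ndarray,
    s: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized trial simulation; ``theta`` is ignored where ``s = 0``.

    Returns arrays ``tau`` (steps), ``responded``, ``choice``,
    ``rt_ms`` (NaN without a response), ``outcome`` (str), and the
    final marginal beliefs.
    """
    n = len(d)
    D = gen.D
    grid = policy.grid
    w0 = np.full(n, 1.0 - gen.r)
    w1 = np.full(n, gen.r)
    w2 = np.zeros(n)
    p_d = np.full(n, 0.5)
    active = np.ones(n, dtype=bool)
    tau = np.full(n, D, dtype=np.int64)
    choice = np.full(n, -1, dtype=np.int64)

    for t in range(1, D):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        # sample observations from the true state
        px1 = np.where(d[idx] == 1, 1.0 - gen.q_d, gen.q_d)
        x = (rng.random(idx.size) < px1).astype(np.int64)
        z = (s[idx] == 1) & (t >= theta[idx])
        py1 = np.where(z, 1.0 - gen.q_s, gen.q_s)
        y = (rng.random(idx.size) < py1).astype(np.int64)

        # exact belief update (vectorized step_belief)
        a0 = w0[idx]
        a1 = (1.0 - gen.q) * w1[idx]
        a2 = w2[idx] + gen.q * w1[idx]
        g0 = np.where(y == 1, gen.q_s, 1.0 - gen.q_s)
        g1 = np.where(y == 1, 1.0 - gen.q_s, gen.q_s)
        a0, a1, a2 = a0 * g0, a1 * g0, a2 * g1
        norm = a0 + a1 + a2
        w0[idx], w1[idx], w2[idx] = a0 / norm, a1 / norm, a2 / norm
        f1 = np.where(x == 1, 1.0 - gen.q_d, gen.q_d)
        f0 = np.where(x == 1, gen.q_d, 1.0 - gen.q_d)
        num = p_d[idx] * f1
        p_d[idx] = num / (num + (1.0 - p_d[idx]) * f0)

        ps = w1[idx] + w2[idx]
        go = policy.action[t - 1, grid.pd_index(p_d[idx]), grid.ps_index(ps)]
        if go.any():
            hit = idx[go]
            tau[hit] = t
            pdh = p_d[hit]
            ch = (pdh > 0.5).astype(np.int64)
            ties = pdh == 0.5
            if ties.any():
                ch[ties] = rng.integers(0, 2, size=int(ties.sum()))
            choice[hit] = ch
            active[hit] = False

    responded = tau < D
    rt_ms = np.where(responded, tau * gen.step_ms, np.nan)
    outcome = np.array(
        [
            _classify(int(si), int(di), bool(ri), int(ci) if ri else None)
            for si, di, ri, ci in zip(s, d, responded, choice)
        ]
    )
    return {
        "tau": tau,
        "responded": responded,
        "choice": choice,
        "rt_ms": rt_ms,
        "outcome": outcome,
        "p_d": p_d,
        "p_s": w1 + w2,
    }
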