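"""Synthetic stop-signal sessions and closed-loop observer simulation.

:func:`generate_session` reproduces the experimental design: 12 blocks
of 75 trials, stop trials with probability 0.25, SSD drawn uniformly
from {100, ..., 600} ms, response deadline 1100 ms.

:func:`simulate_observer` runs the full model over a session: before
each trial the DBM predictive mean supplies the prior stop probability
r and the Kalman prior mean supplies the expected onset 1/q; the
matching Go/Wait policy (cached on a discrete (r, 1/q) lattice) then
generates the trial's response and RT; afterwards the DBM assimilates
the trial label and the Kalman filter the SSD (stop trials only; go
trials diffuse).

The across-trial learners are driven by the experienced stop/go labels
and SSDs only — not by the agent's own responses — so the per-trial
predictors can be computed in one forward pass and trials sharing a
policy simulated in vectorized batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from stoptask.belief import GenerativeParams
from stoptask.dbm import DBMParams, dbm_pstop_series
from stoptask.kalman import KFParams, essd_to_hazard, kf_init, kf_step
from stoptask.policy import CostParams, GridSpec, PolicyTable, compute_policy, simulate_trials

__all__ = [
    "SessionConfig",
    "ObserverParams",
    "PolicyCache",
    "generate_session",
    "simulate_observer",
    "simulate_cohort",
    "classify_outcome",
    "score_session",
    "write_trial_log",
    "read_trial_log",
    "TRIAL_LOG_COLUMNS",
]

TRIAL_LOG_COLUMNS = [
    "subject",
    "block",
    "trial",
    "trial_type",
    "ssd_ms",
    "d",
    "response",
    "rt_ms",
    "outcome",
    "pstop",
    "essd_s",
]


@dataclass(frozen=True)
class SessionConfig:
    """Experimental-design parameters of one session."""

    n_blocks: int = 12
    block_len: int = 75
    stop_prob: float = 0.25
    ssd_set: tuple[int, ...] = (100, 200, 300, 400, 500, 600)
    deadline_ms: float = 1100.0
    exact_count: bool = False  # force round(stop_prob*block_len) stops per block

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_prob < 1.0:
            raise ValueError("stop_prob must lie strictly in (0, 1)")
        if any(ssd >= self.deadline_ms for ssd in self.ssd_set):
            raise ValueError("every SSD must be shorter than the deadline")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_len


@dataclass(frozen=True)
class ObserverParams:
    """Full parameterization of the simulated ideal observer."""

    dbm: DBMParams = field(default_factory=DBMParams)
    kf: KFParams = field(default_factory=KFParams)
    cost: CostParams = field(default_factory=CostParams)
    q_d: float = 0.55
    q_s: float = 0.72
    D: int = 50

    def step_ms(self, deadline_ms: float) -> float:
        """Step duration so that D steps span the response deadline."""
        return deadline_ms / self.D


def generate_session(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one session's trial specs (types, SSDs, go identities).

    Stop assignment is iid Bernoulli(stop_prob) by default; with
    ``exact_count`` each block gets exactly round(stop_prob*block_len)
    stop trials at random positions.
    """
    n = config.n_trials
    if config.exact_count:
        k = round(config.stop_prob * config.block_len)
        stop = np.zeros(n, dtype=bool)
        for b in range(config.n_blocks):
            pos = rng.choice(config.block_len, size=k, replace=False)
            stop[b * config.block_len + pos] = True
    else:
        stop = rng.random(n) < config.stop_prob
    ssd = np.where(stop, rng.choice(config.ssd_set, size=n), np.nan)
    d = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(config.n_blocks), config.block_len),
            "trial": np.arange(n),
            "trial_type": np.where(stop, "stop", "go"),
            "ssd_ms": ssd,
            "d": d,
        }
    )


class PolicyCache:
    """Policies precomputed on a discrete lattice of (P(stop), E[SSD]).

    The learned r and 1/q vary smoothly from trial to trial; rather
    than re-solving the dynamic program each trial, policies are
    computed at lattice points (defaults: r in 0.10..0.75 step 0.0125,
    E[SSD] in 5..27 steps, spanning the values the learners produce
    under the default session design) and each trial uses the nearest
    one.  The r spacing is kept well below the across-trial standard
    deviation of the learned P(stop) (~0.04 under the default design)
    so the simulated RT responds smoothly rather than in a staircase.
    Requests outside the lattice clamp to its edge.  Tables are
    computed lazily, so only requested lattice points cost anything.
    """

    def __init__(
        self,
        r_values: np.ndarray | None = None,
        essd_steps: np.ndarray | None = None,
        grid: GridSpec | None = None,
    ) -> None:
        self.r_values = np.asarray(
            r_values if r_values is not None else np.round(np.arange(0.10, 0.7501, 0.0125), 4)
        )
        self.essd_steps = np.asarray(
            essd_steps if essd_steps is not None else np.arange(5, 28, dtype=float)
        )
        self.grid = grid or GridSpec()
        self._tables: dict[tuple[float, float, float, float, float, int, float], PolicyTable] = {}

    def key(self, r: float, q: float) -> tuple[float, float]:
        """Nearest lattice point for a requested (r, hazard q)."""
        ri = int(np.argmin(np.abs(self.r_values - r)))
        ei = int(np.argmin(np.abs(self.essd_steps - 1.0 / q)))
        return float(self.r_values[ri]), float(self.essd_steps[ei])

    def get(
        self, r: float, q: float, observer: ObserverParams, step_ms: float
    ) -> PolicyTable:
        r_bin, essd_bin = self.key(r, q)
        full_key = (r_bin, essd_bin, observer.q_d, observer.q_s,
                    observer.cost.c, observer.D, observer.cost.c_s)
        table = self._tables.get(full_key)
        if table is None:
            gen = GenerativeParams(
                q_d=observer.q_d,
                q_s=observer.q_s,
                q=1.0 / essd_bin,
                r=r_bin,
                D=observer.D,
                step_ms=step_ms,
            )
            table = compute_policy(gen, observer.cost, self.grid, keep_values=False)
            self._tables[full_key] = table
        return table


def _predictor_series(
    labels: np.ndarray,
    ssd_ms: np.ndarray,
    observer: ObserverParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass of DBM and Kalman learners over a session.

    Returns, per trial, the predictive P(stop) and the Kalman prior
    mean of SSD (seconds), both strictly prior to the trial's outcome.
    """
    ps = dbm_pstop_series(labels, observer.dbm)
    kf = kf_init(observer.kf)
    essd = np.empty(len(labels))
    for k, s_k in enumerate(labels):
        # diffuse first; the resulting prior mean drives this trial
        obs = ssd_ms[k] / 1000.0 if s_k == 1 else None
        kf = kf_step(kf, obs, observer.kf)
        essd[k] = kf.h_prior
    return ps, essd


def simulate_observer(
    session: pd.DataFrame,
    observer: ObserverParams,
    rng: np.random.Generator,
    config: SessionConfig | None = None,
    cache: PolicyCache | None = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Simulate the ideal observer over one session's trial sequence.

    Returns a trial log with one row per trial (see
    ``TRIAL_LOG_COLUMNS``): the realized response, RT and outcome class
    together with the model predictors P(stop) and E[SSD] attached as
    strictly-prior quantities.
    """
    config = config or SessionConfig()
    cache = cache or PolicyCache()
    step_ms = observer.step_ms(config.deadline_ms)
    labels = (session["trial_type"].to_numpy() == "stop").astype(int)
    ssd_ms = session["ssd_ms"].to_numpy(dtype=float)
    d = session["d"].to_numpy(dtype=np.int64)
    n = len(session)

    ps_series, essd_series = _predictor_series(labels, ssd_ms, observer)
    # guard: hazard conversion needs a positive mean; floor at one step
    essd_floor = np.maximum(essd_series, step_ms / 1000.0)
    q_series = np.array(
        [essd_to_hazard(h, step_ms, observer.D) for h in essd_floor]
    )

    theta = np.zeros(n, dtype=np.int64)
    is_stop = labels == 1
    theta[is_stop] = np.maximum(1, np.round(ssd_ms[is_stop] / step_ms).astype(np.int64))

    keys = [cache.key(ps_series[k], q_series[k]) for k in range(n)]
    tau = np.empty(n, dtype=np.int64)
    responded = np.empty(n, dtype=bool)
    choice = np.empty(n, dtype=np.int64)
    rt_ms = np.empty(n)
    outcome = np.empty(n, dtype=object)
    for key in sorted(set(keys)):
        idx = np.flatnonzero([k == key for k in keys])
        table = cache.get(key[0], 1.0 / key[1], observer, step_ms)
        out = simulate_trials(table, table.gen, d[idx], labels[idx], theta[idx], rng)
        tau[idx] = out["tau"]
        responded[idx] = out["responded"]
        choice[idx] = out["choice"]
        rt_ms[idx] = out["rt_ms"]
        outcome[idx] = out["outcome"]

    response = np.where(~responded, "none", np.where(choice == 1, "right", "left"))
    return pd.DataFrame(
        {
            "subject": subject,
            "block": session["block"].to_numpy(),
            "trial": session["trial"].to_numpy(),
            "trial_type": session["trial_type"].to_numpy(),
            "ssd_ms": ssd_ms,
            "d": d,
            "response": response,
            "rt_ms": rt_ms,
            "outcome": outcome,
            "pstop": ps_series,
            "essd_s": essd_series,
        }
    )


def _jittered(observer: ObserverParams, jitter: dict, rng: np.random.Generator) -> ObserverParams:
    """Per-subject parameter draw from uniform jitter ranges."""
    def draw(name, current):
        if name not in jitter:
            return current
        lo, hi = jitter[name]
        return float(rng.uniform(lo, hi))

    dbm = observer.dbm
    kf = observer.kf
    cost = observer.cost
    if "alpha" in jitter:
        dbm = replace(dbm, alpha=draw("alpha", dbm.alpha))
    if "Q" in jitter or "R" in jitter:
        kf = replace(
            kf,
            Q=draw("Q", kf.Q) if "Q" in jitter else kf.Q,
            R=draw("R", kf.R) if "R" in jitter else kf.R,
        )
    if "c" in jitter or "c_s" in jitter:
        cost = CostParams(
            c=draw("c", cost.c) if "c" in jitter else cost.c,
            c_s=draw("c_s", cost.c_s) if "c_s" in jitter else cost.c_s,
        )
    return replace(observer, dbm=dbm, kf=kf, cost=cost)


def simulate_cohort(
    n_subjects: int,
    config: SessionConfig,
    observer: ObserverParams,
    seed: int,
    jitter: dict | None = None,
    cache: PolicyCache | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of subjects, one independent session each.

    ``jitter`` optionally maps parameter names (alpha, Q, R, c, c_s)
    to uniform ranges for between-subject heterogeneity; the policy
    cache is shared across subjects whenever their cost/channel
    parameters coincide.
    """
    cache = cache or PolicyCache()
    logs = []
    root = np.random.SeedSequence(seed)
    for subj, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        obs_s = _jittered(observer, jitter, rng) if jitter else observer
        session = generate_session(config, rng)
        logs.append(
            simulate_observer(session, obs_s, rng, config=config, cache=cache, subject=subj)
        )
    return pd.concat(logs, ignore_index=True)


def classify_outcome(
    trial_type: str,
    response: str,
    rt_ms: float | None,
    d: int | None = None,
    deadline_ms: float = 1100.0,
) -> str:
    """Five-way outcome classification of a trial.

    Stop trials: any response is a stop error, none a stop success.
    Go trials: no response is an omission; otherwise correct or
    discrimination error depending on whether the response matches the
    go identity ``d`` (0 = left, 1 = right).
    """
    responded = response != "none"
    if responded:
        if rt_ms is None or not np.isfinite(rt_ms):
            raise ValueError("a response requires an RT")
        if rt_ms > deadline_ms:
            raise ValueError(f"RT {rt_ms} exceeds the deadline {deadline_ms}")
    if trial_type == "stop":
        return "stop_error" if responded else "stop_success"
    if trial_type != "go":
        raise ValueError(f"unknown trial type {trial_type!r}")
    if not responded:
        return "omission"
    if d is None:
        raise ValueError("go-trial classification requires the identity d")
    correct = (response == "right") == (d == 1)
    return "go_correct" if correct else "discrim_error"


def score_session(records: pd.DataFrame, deadline_ms: float = 1100.0) -> float:
    """Point total under the task's incentive scheme (always <= 0).

    50 points are lost for each discrimination error, omission or stop
    error, and 3 points per 100 ms of response delay (delay accrues to
    the deadline on trials with no response, i.e. 33 points at an
    1100-ms deadline).
    """
    if len(records) == 0:
        return 0.0
    errors = records["outcome"].isin(["discrim_error", "omission", "stop_error"]).sum()
    delay_ms = records["rt_ms"].fillna(deadline_ms).to_numpy(dtype=float)
    return float(-(50.0 * errors) - 3.0 * delay_ms.sum() / 100.0)


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write a trial log as tab-separated text (empty = missing)."""
    records.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_log(path) -> pd.DataFrame:
    """Read a tab-separated trial log written by :func:`write_trial_log`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns and c not in ("pstop", "essd_s")]
    if missing:
        raise ValueError(f"trial log missing required columns: {missing}")
    return df
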