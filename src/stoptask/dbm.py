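"""Dynamic Belief Model (DBM) for the stop-trial rate.

The rate γ_k with which stop trials occur is treated as volatile: on
each trial it persists with probability α or is redrawn from a fixed
Beta(a, b) prior with probability 1 - α.  Observing the trial label
s_k ∈ {0, 1} (stop/go) updates a discretized posterior over γ; the
mean of the *predictive* distribution before trial k is the model's
P(stop), which feeds the within-trial generative model as the prior
stop probability r.

With α = 1 the model collapses to conjugate Beta-Bernoulli updating;
with α < 1 the influence of past observations decays geometrically,
producing the sequential effects seen in human response times.
Defaults α = 0.75, Beta(2.5, 7.5) (prior mean 0.25 matching the
nominal stop frequency, prior strength a + b = 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DBMParams", "DBMState", "dbm_init", "dbm_predict", "dbm_observe", "pstop"]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class DBMParams:
    """α: per-trial persistence of γ; (a, b): Beta prior; n_grid: γ bins."""

    alpha: float = 0.75
    a: float = 2.5
    b: float = 7.5
    n_grid: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.n_grid < 10:
            raise ValueError("n_grid must be >= 10")

    @property
    def grid(self) -> np.ndarray:
        """Midpoints of ``n_grid`` equal-width bins on (0, 1)."""
        return (np.arange(self.n_grid) + 0.5) / self.n_grid

    @property
    def p0(self) -> np.ndarray:
        """Generic Beta(a, b) prior evaluated on the grid, normalized."""
        w = stats.beta.pdf(self.grid, self.a, self.b)
        return w / w.sum()


@dataclass(frozen=True)
class DBMState:
    """Posterior and predictive pmfs over the γ grid before/after trial k."""

    k: int
    posterior: np.ndarray
    predictive: np.ndarray

    @property
    def p_stop(self) -> float:
        return pstop(self.predictive, None)


def dbm_init(params: DBMParams) -> DBMState:
    """Session-start state: predictive (and posterior) equal the prior p0."""
    p0 = params.p0
    return DBMState(k=0, posterior=p0.copy(), predictive=p0.copy())


def _check_pmf(p: np.ndarray) -> None:
    if abs(float(np.sum(p)) - 1.0) > _NORM_TOL or np.any(p < 0):
        raise ValueError("pmf must be nonnegative and sum to 1")


def dbm_predict(posterior: np.ndarray, params: DBMParams) -> np.ndarray:
    """Predictive pmf for the next trial: α·posterior + (1-α)·p0."""
    _check_pmf(posterior)
    pred = params.alpha * posterior + (1.0 - params.alpha) * params.p0
    return pred / pred.sum()


def dbm_observe(predictive: np.ndarray, s_k: int, params: DBMParams) -> np.ndarray:
    """Condition the predictive pmf on the trial label via Bernoulli(γ)."""
    if s_k not in (0, 1):
        raise ValueError(f"s_k must be binary, got {s_k}")
    _check_pmf(predictive)
    g = params.grid
    lik = g if s_k == 1 else (1.0 - g)
    post = predictive * lik
    z = post.sum()
    if z <= 0:
        raise RuntimeError("degenerate DBM posterior (zero normalizer)")
    return post / z


def pstop(predictive: np.ndarray, params: DBMParams | None = None) -> float:
    """Mean of the predictive pmf over γ — the model's P(stop).

    This value is handed to the within-trial model as the prior stop
    probability ``r`` for the upcoming trial.
    """
    _check_pmf(predictive)
    n = len(predictive)
    grid = params.grid if params is not None else (np.arange(n) + 0.5) / n
    return float(np.dot(grid, predictive))


def dbm_step(state: DBMState, s_k: int, params: DBMParams) -> DBMState:
    """Advance one trial: observe the label, then form the next predictive."""
    post = dbm_observe(state.predictive, s_k, params)
    pred = dbm_predict(post, params)
    return DBMState(k=state.k + 1, posterior=post, predictive=pred)


def dbm_pstop_series(labels: np.ndarray, params: DBMParams) -> np.ndarray:
    """Predictive P(stop) ahead of each trial for a 0/1 label sequence.

    Entry ``k`` uses only labels ``0 .. k-1`` (strictly prior
    information); entry 0 is the prior mean ``a / (a + b)`` up to grid
    quantization.
    """
    labels = np.asarray(labels)
    g = params.grid
    p0 = params.p0
    pred = p0.copy()
    out = np.empty(len(labels))
    lik1 = g
    lik0 = 1.0 - g
    for k, s_k in enumerate(labels):
        out[k] = float(np.dot(g, pred))
        post = pred * (lik1 if s_k == 1 else lik0)
        post /= post.sum()
        pred = params.alpha * post + (1.0 - params.alpha) * p0
        pred /= pred.sum()
    return out
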