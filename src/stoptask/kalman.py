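"""Scalar Kalman filter for trial-by-trial learning of expected SSD.

The latent expected stop-signal delay h_k (seconds) performs a Gaussian
random walk with per-trial diffusion variance Q; on stop trials the
scheduled SSD z_k is observed with Gaussian noise variance R.  Go
trials carry no SSD observation: the prior diffuses (P grows by Q) and
the posterior equals the prior, so the influence of past SSDs fades
with intervening go trials.

The predictive prior mean ĥ⁻ sets the expected onset 1/q (in steps) of
the within-trial generative model via :func:`essd_to_hazard`.  Defaults
Q = 0.03 s², R = 0.15 s², h0 = 0.35 s, P0 = 1 s².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KFParams",
    "KFState",
    "kf_init",
    "kf_predict",
    "kf_update",
    "kf_step",
    "essd_to_hazard",
    "riccati_fixed_point",
]


@dataclass(frozen=True)
class KFParams:
    Q: float = 0.03
    R: float = 0.15
    h0: float = 0.35
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.R <= 0 or self.P0 <= 0:
            raise ValueError("Q, R and P0 must be strictly positive")


@dataclass(frozen=True)
class KFState:
    """Prior (ĥ⁻, P⁻) and posterior (ĥ, P) for trial k; K is the last gain."""

    k: int
    h_prior: float
    P_prior: float
    h_post: float
    P_post: float
    K: float = 0.0


def kf_init(params: KFParams) -> KFState:
    """State before any trial: posterior = the h0/P0 prior over h_1."""
    return KFState(k=0, h_prior=params.h0, P_prior=params.P0,
                   h_post=params.h0, P_post=params.P0)


def kf_predict(state: KFState, params: KFParams) -> KFState:
    """Diffusion step: mean carries over, variance grows by Q."""
    return KFState(
        k=state.k + 1,
        h_prior=state.h_post,
        P_prior=state.P_post + params.Q,
        h_post=state.h_post,
        P_post=state.P_post + params.Q,
        K=0.0,
    )


def kf_update(prior: KFState, z: float, params: KFParams) -> KFState:
    """Assimilate an observed SSD ``z`` (seconds) into the prior.

    K = P⁻/(P⁻+R); ĥ = ĥ⁻ + K (z - ĥ⁻); P = (1-K) P⁻ — the posterior is
    a linear compromise between the predictive prior and the datum.
    """
    if not np.isfinite(z):
        raise ValueError(f"observation must be finite, got {z}")
    K = prior.P_prior / (prior.P_prior + params.R)
    h = prior.h_prior + K * (z - prior.h_prior)
    P = (1.0 - K) * prior.P_prior
    return KFState(k=prior.k, h_prior=prior.h_prior, P_prior=prior.P_prior,
                   h_post=h, P_post=P, K=K)


def kf_step(state: KFState, observation: float | None, params: KFParams) -> KFState:
    """One trial: always diffuse; correct only when an SSD was observed.

    ``observation`` is the SSD in seconds on a stop trial and None on a
    go trial (posterior = prior there).
    """
    if observation is not None and observation < 0:
        raise ValueError(f"SSD observation must be nonnegative, got {observation}")
    prior = kf_predict(state, params)
    if observation is None:
        return prior
    return kf_update(prior, observation, params)


def essd_to_hazard(
    h_prior_s: float, step_ms: float, D: int | None = None
) -> float:
    """Convert a prior mean SSD (seconds) to the per-step onset hazard q.

    q = 1 / (expected SSD in steps); clipped into (1/D, 1) when a
    deadline is given, so the geometric onset prior stays
    non-degenerate.
    """
    if h_prior_s <= 0:
        raise ValueError(f"prior mean SSD must be positive, got {h_prior_s}")
    steps = h_prior_s * 1000.0 / step_ms
    q = 1.0 / steps
    if D is not None:
        eps = 1e-9
        q = float(np.clip(q, 1.0 / D + eps, 1.0 - eps))
    return q


def riccati_fixed_point(params: KFParams) -> float:
    """Steady-state prior variance P⁻ of the scalar predict/update cycle.

    Solves P⁻ = (1-K) P⁻ + Q with K = P⁻/(P⁻+R), i.e. the quadratic
    P⁻² - Q P⁻ - Q R = 0, taking the positive root.
    """
    Q, R = params.Q, params.R
    return 0.5 * (Q + np.sqrt(Q * Q + 4.0 * Q * R))
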