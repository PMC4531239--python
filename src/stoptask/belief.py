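"""Within-trial generative model and exact Bayesian evidence filtering.

Each trial presents two independent Bernoulli evidence streams, sampled
once per discrete time step:

* ``x`` carries information about the go-stimulus identity
  ``d ∈ {0, 1}`` (left/right): ``P(x=1 | d=0) = q_d`` and
  ``P(x=1 | d=1) = 1 - q_d``.
* ``y`` carries information about the stop signal.  On a stop trial
  (``s = 1``) the signal switches on at a latent onset step ``θ`` with
  geometric distribution ``P(θ = t | s=1) = q (1-q)^(t-1)``, so that
  ``1/q`` is the expected stop-signal delay in steps.  Before onset
  (and on go trials) ``P(y=1 | z=0) = q_s``; after onset
  ``P(y=1 | z=1) = 1 - q_s``.

The observer's belief about the stop status is a three-component
posterior ``(w0, w1, w2)`` over {go trial, stop trial/signal not yet
on, stop trial/signal on}; this triple is the exact sufficient
statistic of the filtering problem.  The conventional two-dimensional
belief state ``(p_d, p_s)`` is exposed as ``p_d`` plus
``p_s = w1 + w2``: the pair alone is not Markov, because the ``y``
likelihood differs before and after onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GenerativeParams",
    "BeliefState",
    "init_belief",
    "step_belief",
    "predictive_obs_dist",
    "geometric_onset_pmf",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the within-trial generative model.

    Parameters
    ----------
    q_d
        Bernoulli rate of the go-evidence channel under ``d = 0``
        (``1 - q_d`` under ``d = 1``).  Values near 0.5 make the go
        stimulus hard to discriminate.
    q_s
        Bernoulli rate of the stop-evidence channel while the signal is
        absent (``1 - q_s`` once it is on).
    q
        Per-step hazard of stop-signal onset; the prior mean SSD is
        ``1/q`` steps.
    r
        Prior probability that the trial is a stop trial, i.e. P(stop).
    D
        Response deadline in time steps.
    step_ms
        Duration of one time step in milliseconds (the deadline in
        milliseconds is ``D * step_ms``).
    """

    q_d: float = 0.55
    q_s: float = 0.72
    q: float = 0.1
    r: float = 0.25
    D: int = 50
    step_ms: float = 22.0

    def __post_init__(self) -> None:
        for name in ("q_d", "q_s", "q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if self.D < 2:
            raise ValueError(f"D must be an integer >= 2, got {self.D}")
        if self.step_ms <= 0:
            raise ValueError(f"step_ms must be positive, got {self.step_ms}")

    @property
    def expected_ssd_steps(self) -> float:
        """Prior mean of the stop-signal onset, ``1/q``, in steps."""
        return 1.0 / self.q

    @property
    def deadline_ms(self) -> float:
        return self.D * self.step_ms


@dataclass(frozen=True)
class BeliefState:
    """Posterior over the trial's hidden state after ``t`` observations.

    ``p_d`` is the posterior probability of ``d = 1``.  The stop-status
    posterior is the triple ``(w0, w1, w2)`` = P(go trial),
    P(stop trial, signal not yet on), P(stop trial, signal on); it sums
    to one.  ``p_s = w1 + w2`` is the posterior probability of a stop
    trial.
    """

    t: int
    p_d: float
    w0: float
    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not 0.0 <= self.p_d <= 1.0:
            raise ValueError(f"p_d out of [0, 1]: {self.p_d}")
        w = (self.w0, self.w1, self.w2)
        if min(w) < -_NORM_TOL:
            raise ValueError(f"negative stop-posterior component: {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"stop posterior not normalized: sum={sum(w)}")

    @property
    def p_s(self) -> float:
        """Posterior probability that this is a stop trial."""
        return self.w1 + self.w2


def init_belief(params: GenerativeParams) -> BeliefState:
    """Belief before any evidence: unbiased over ``d``, prior ``r`` on stop.

    The onset satisfies ``θ >= 1``, so at ``t = 0`` no signal can be on
    yet and the stop posterior is ``(1 - r, r, 0)``.
    """
    return BeliefState(t=0, p_d=0.5, w0=1.0 - params.r, w1=params.r, w2=0.0)


def _transition_stop(w0: float, w1: float, w2: float, q: float) -> tuple[float, float, float]:
    """One step of the onset dynamics: hazard ``q`` moves mass w1 -> w2."""
    return w0, (1.0 - q) * w1, w2 + q * w1


def step_belief(b: BeliefState, x: int, y: int, params: GenerativeParams) -> BeliefState:
    """Assimilate one observation pair ``(x, y)`` by Bayes' rule.

    The update is exact: (1) propagate the onset dynamics (mass
    ``q * w1`` transfers from "signal pending" to "signal on"); (2)
    weight the stop components by the ``y`` likelihood (``Bernoulli(q_s)``
    pre-onset and on go trials, ``Bernoulli(1 - q_s)`` post-onset) and
    renormalize; (3) update ``p_d`` with the ``x`` likelihood
    (``Bernoulli(q_d)`` under ``d = 0``, ``Bernoulli(1 - q_d)`` under
    ``d = 1``).
    """
    if x not in (0, 1) or y not in (0, 1):
        raise ValueError(f"observations must be binary, got x={x}, y={y}")

    w0, w1, w2 = _transition_stop(b.w0, b.w1, b.w2, params.q)

    # y likelihoods: g0 applies to the signal-absent components (w0, w1)
    g0 = params.q_s if y == 1 else 1.0 - params.q_s
    g1 = (1.0 - params.q_s) if y == 1 else params.q_s
    w0 *= g0
    w1 *= g0
    w2 *= g1
    z = w0 + w1 + w2
    w0, w1, w2 = w0 / z, w1 / z, w2 / z

    f0 = params.q_d if x == 1 else 1.0 - params.q_d
    f1 = (1.0 - params.q_d) if x == 1 else params.q_d
    num = b.p_d * f1
    p_d = num / (num + (1.0 - b.p_d) * f0)

    return BeliefState(t=b.t + 1, p_d=p_d, w0=w0, w1=w1, w2=w2)


def predictive_obs_dist(b: BeliefState, params: GenerativeParams) -> np.ndarray:
    """One-step predictive distribution over the observation pair.

    Returns a 2x2 array ``P[x, y]``.  Given the belief, ``x`` and ``y``
    are independent: ``x`` depends only on ``p_d`` and ``y`` on the
    onset-propagated stop posterior.  This is the expectation measure in
    the Wait branch of the Bellman recursion.
    """
    px1 = b.p_d * (1.0 - params.q_d) + (1.0 - b.p_d) * params.q_d
    _, w1, w2 = _transition_stop(b.w0, b.w1, b.w2, params.q)
    # components with the signal absent at t+1: w0 + transitioned w1
    py1 = (1.0 - w2) * params.q_s + w2 * (1.0 - params.q_s)
    px = np.array([1.0 - px1, px1])
    py = np.array([1.0 - py1, py1])
    return np.outer(px, py)


def geometric_onset_pmf(q: float, t: int) -> float:
    """P(stop-signal onset at step ``t``) = ``q (1-q)^(t-1)``; mean 1/q."""
    if not 0.0 < q < 1.0:
        if q == 1.0 and t >= 1:
            return 1.0 if t == 1 else 0.0
        raise ValueError(f"hazard q must lie in (0, 1], got {q}")
    if t < 1:
        raise ValueError(f"onset step must be >= 1, got {t}")
    return q * (1.0 - q) ** (t - 1)


def posterior_brute_force(
    obs: list[tuple[int, int]], params: GenerativeParams, theta_max: int | None = None
) -> BeliefState:
    """Posterior by explicit enumeration over ``(d, s, θ)``.

    Sums the exact joint probability of the observation sequence under
    every latent configuration (onsets beyond ``theta_max`` collapsed
    into a single never-on-by-now atom).  Serves as an independent
    cross-check of the iterative filter; cost is linear in
    ``len(obs) * theta_max``.
    """
    T = len(obs)
    if theta_max is None:
        theta_max = T
    f = {0: lambda x: params.q_d if x == 1 else 1.0 - params.q_d,
         1: lambda x: (1.0 - params.q_d) if x == 1 else params.q_d}
    g = {0: lambda y: params.q_s if y == 1 else 1.0 - params.q_s,
         1: lambda y: (1.0 - params.q_s) if y == 1 else params.q_s}

    def y_lik(theta: float) -> float:
        # likelihood of the y sequence given onset at theta (inf = never)
        lik = 1.0
        for i, (_, y) in enumerate(obs, start=1):
            lik *= g[1](y) if i >= theta else g[0](y)
        return lik

    x_lik = {d: float(np.prod([f[d](x) for x, _ in obs])) if T else 1.0 for d in (0, 1)}

    # d and (s, θ) factorize given the data: x informs only d, y only (s, θ)
    w_go = (1.0 - params.r) * y_lik(float("inf"))
    w_on = params.r * sum(
        geometric_onset_pmf(params.q, th) * y_lik(th)
        for th in range(1, min(T, theta_max) + 1)
    )
    w_pending = params.r * (1.0 - params.q) ** T * y_lik(float("inf"))
    z = w_go + w_pending + w_on
    p_d = 0.5 * x_lik[1] / (0.5 * x_lik[0] + 0.5 * x_lik[1])
    return BeliefState(t=T, p_d=p_d, w0=w_go / z, w1=w_pending / z, w2=w_on / z)


def with_r(params: GenerativeParams, r: float) -> GenerativeParams:
    """Copy of ``params`` with a new prior stop probability."""
    return replace(params, r=r)
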