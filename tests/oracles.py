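"""Independent oracles used by the tests.

The brute-force policy oracle computes the minimal expected loss of the
stopping problem by direct enumeration over the generative joint
distribution — latent states (d, s, onset step) and complete
observation sequences — optimizing the action at every observation
history.  It never touches the belief filter or the Bellman Q-factor
formulas, so agreement with the package's dynamic program validates
both the filtering and the backward induction.  Cost is O(4^D).
"""

from __future__ import annotations

from stoptask.belief import GenerativeParams
from stoptask.policy import CostParams


def brute_force_optimal_loss(gen: GenerativeParams, cost: CostParams) -> float:
    D = gen.D
    # latent atoms (d, s, theta, prior weight); onsets past the window
    # collapse into a single "not yet on by D" atom
    atoms = []
    for d in (0, 1):
        atoms.append((d, 0, None, 0.5 * (1.0 - gen.r)))
        for th in range(1, D + 1):
            atoms.append((d, 1, th, 0.5 * gen.r * gen.q * (1.0 - gen.q) ** (th - 1)))
        atoms.append((d, 1, D + 1, 0.5 * gen.r * (1.0 - gen.q) ** D))

    def obs_lik(d: int, s: int, th, t: int, x: int, y: int) -> float:
        px1 = (1.0 - gen.q_d) if d == 1 else gen.q_d
        fx = px1 if x == 1 else 1.0 - px1
        on = s == 1 and th is not None and t >= th
        py1 = (1.0 - gen.q_s) if on else gen.q_s
        gy = py1 if y == 1 else 1.0 - py1
        return fx * gy

    def best(weights: list, t: int) -> float:
        """Optimal E[loss · P(history)] over continuations of this history."""
        total = sum(w for *_, w in weights)
        if t == D:
            # deadline: delay cost plus omission on go trials
            return cost.c * D * total + sum(w for d, s, th, w in weights if s == 0)
        wait = 0.0
        for x in (0, 1):
            for y in (0, 1):
                nxt = [
                    (d, s, th, w * obs_lik(d, s, th, t + 1, x, y))
                    for d, s, th, w in weights
                ]
                wait += best(nxt, t + 1)
        if t == 0:
            return wait  # no action before the first observation
        go_losses = []
        for delta in (0, 1):
            loss = cost.c * t * total
            loss += cost.c_s * sum(w for d, s, th, w in weights if s == 1)
            loss += sum(w for d, s, th, w in weights if s == 0 and d != delta)
            go_losses.append(loss)
        return min(min(go_losses), wait)

    return best(atoms, 0)
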