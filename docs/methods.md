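# Methods

## The model

`stoptask` implements a rational-observer account of behavior in the
stop-signal task (SST): a 2AFC discrimination task (respond left/right to a
go stimulus within an 1100-ms deadline) in which, on ~25% of trials, an
auditory stop signal arriving at a stop-signal delay (SSD, uniform over
100–600 ms) instructs the subject to withhold the response. The model has
two nested time scales.

### Within a trial: Bayesian filtering and optimal stopping

Time is discretized into `D` steps spanning the deadline (`step_ms =
deadline / D`; 22 ms at the default `D = 50`). Two conditionally
independent Bernoulli evidence streams arrive each step: `x_t` about the
go identity `d` (rate `q_d` under `d = 0`, `1 − q_d` under `d = 1`) and
`y_t` about the stop signal (rate `q_s` while the signal is absent,
`1 − q_s` once it is on). On a stop trial the signal switches on at a
latent onset `θ ~ Geometric(q)`, so `1/q` is the expected SSD in steps.

The observer's sufficient statistic is `p_d = P(d = 1 | x_{1:t})` together
with the three-component stop posterior `(w0, w1, w2)` over {go trial,
stop trial/signal pending, stop trial/signal on}; `p_s = w1 + w2`. The
two-dimensional summary `(p_d, p_s)` alone is not Markov — the `y`
likelihood differs before and after onset — so the filter carries the
exact triple and exposes `p_s` as the derived marginal.

Actions are Go (commit to the likelier identity) or Wait. Costs,
normalized to a unit go-error cost: `c` per step of delay and `c_s` for
responding on a stop trial; failing to respond on a go trial costs 1.
The Q-factors are

    Q_go(t, b)   = c·t + c_s·p_s + (1 − p_s)·min(p_d, 1 − p_d)
    Q_wait(t, b) = E[ V^{t+1}(b^{t+1}) | b ]        (t + 1 < D)
                 = c·(t+1) + 1 − p_s                (t + 1 = D)

with terminal value `V^D = c·D + (1 − p_s)` and `V^t = min(Q_go, Q_wait)`.
The deadline branch is the exact expectation of the terminal value
because `p_s` is a martingale under the predictive distribution. The
value function is tabulated on a 200×200 equal-width grid over
`(p_d, p_s)` by backward induction from `t = D − 1` to `t = 1`. Because
the grid carries only the marginal `p_s`, the Wait expectation splits it
into pending/on components with the prior onset dynamics,
`P(on | stop, t) = 1 − (1 − q)^t`. Bin lookup is nearest-midpoint, no
interpolation; ties `Q_go = Q_wait` resolve to Wait (act only when
strictly beneficial). Response choice is `argmax p_d`, with an exact tie
broken by the seeded RNG. RT is `τ · step_ms` with no non-decision
offset.

Two validation paths exist for the dynamic program: `exact_policy_loss`
recurses over observation histories with the exact belief triple
(O(4^D), for small deadlines), and the test suite contains an
independent brute-force oracle that enumerates the raw generative joint
(latents × observation sequences) without using the filter or the
Bellman recursion. The two agree to ~1e-15 at `D = 3–4`, and the
200×200 grid policy's Monte-Carlo expected loss matches the exact
optimum within sampling error at `D = 8–9`.

### Across trials: learning P(stop) and E[SSD]

*P(stop).* A Dynamic Belief Model: the stop rate `γ_k` persists from
trial to trial with probability `α` and is redrawn from `Beta(a, b)`
with probability `1 − α`. The posterior over `γ` is tracked on 100
equal-width bins (midpoint evaluation; quantization error ≤ 1/100, far
below the effects of interest). The predictive mean is P(stop), and it
becomes the prior `r` of the within-trial model on the next trial. With
`α = 1` the model reduces to conjugate Beta–Bernoulli updating, which
the tests exploit as a closed-form oracle. Defaults: `α = 0.75`,
`Beta(2.5, 7.5)` (prior mean 0.25 = nominal stop frequency, strength
`a + b = 10`). The DBM is *not* reset at block boundaries (the analyses
treat the session as continuous and instead exclude block-initial go
runs); a reset flag is available via re-initialization.

*E[SSD].* A scalar Kalman filter: the latent expected SSD `h_k`
(seconds) diffuses with variance `Q` per trial; on stop trials the
scheduled SSD is observed with noise variance `R`. On go trials the
prior diffuses and the posterior equals the prior, so the influence of
past SSDs fades with intervening go trials. The prior mean feeds the
within-trial onset hazard, `q = 1 / (ĥ⁻ · 1000 / step_ms)`, clipped
into `(1/D, 1)` to keep the geometric prior non-degenerate (clipping
prevents a nonpositive or absurdly large mean from producing an invalid
hazard; the mean itself is not clamped). Updates use the scheduled SSD
on every stop trial, including stop errors where the response preceded
the signal — the learner consumes the experienced stop/SSD sequence,
not the subject's own outcomes. Defaults: `Q = 0.03 s²`, `R = 0.15 s²`,
`h0 = 0.35 s`, `P0 = 1 s²`.

### Closed-loop simulation

`simulate_observer` chains the pieces per trial: DBM predictive mean →
`r`; Kalman prior mean → `q`; the matching policy generates the
response and RT; then the DBM assimilates the trial label and the
Kalman filter the SSD. Since the learners are driven only by the
experienced stop/go labels and SSDs (not the agent's responses), the
predictor series are computed in one forward pass and trials sharing a
policy are simulated in vectorized batches.

Policies are cached on a lattice of `(r, E[SSD])` values and looked up
by nearest point. The lattice spans r = 0.10–0.75 in steps of 0.0125
and E[SSD] = 5–27 steps in steps of 1, chosen to cover the values the
learners actually produce under the default design (P(stop) ≈
0.15–0.45, E[SSD] ≈ 5.6–26 steps) with spacing well below the
across-trial standard deviation of each predictor (≈0.04 and ≈2.5
steps). A coarser r spacing makes the simulated RT respond to P(stop)
in a visible staircase, and a narrower E[SSD] range clips a third of
the trials at the lattice edge; both artifacts distort the binned
regressions, which is why the density was fixed at these values. Tables
are computed lazily (~0.08 s each at 200×200, D = 50), so a full
20-subject cohort costs ~300 policy solves plus the trial simulation
(≈30 s total on one CPU).

## Synthetic sessions

`generate_session` reproduces the experimental design: 12 blocks × 75
trials, iid stop trials at probability 0.25 (an exact-count-per-block
option exists), SSD uniform on {100, …, 600} ms, go identity fair. The
onset in steps is `round(ssd_ms / step_ms)`. The point scheme (−50 per
error, −3 per 100 ms of delay, delay accruing to the deadline without a
response) is implemented in `score_session`. Subject heterogeneity is
available as uniform jitter on (α, Q, R, c, c_s); the default cohort is
homogeneous, so that recovery experiments have a well-defined truth.

What the generator does *not* emulate: perceptual-coherence differences
between the four go-stimulus types (a single `q_d` is used), training
sessions, fatigue or attentional drift, any meta-learning of α over the
session, and non-decision time. Passing tests therefore show that the
pipeline recovers the structure this model family generates — not that
human data contain no other RT structure.

## Analysis pipeline

All Go-RT analyses use correct go trials and, per block, exclude the
leading run of go trials before the first stop trial (beliefs before
any stop evidence are poorly constrained; the mean excluded run is 3
trials, none at all a quarter of the time). Model predictors are
attached strictly causally: the value for trial k uses trials 1..k−1
only.

* **Pattern tables** (`pattern_rts`): mean RT of the correct go trial
  immediately following each three-trial go/stop pattern (and the mean
  model P(stop) of the following trial), pooled over subjects; windows
  must be contiguous trials.
* **Experienced-SSD predictor** (`recent_ssd_predictor`): mean SSD of
  the two most recent stop trials, restricted to go trials directly
  following a stop trial with the two stops separated by at most three
  go trials. Model-free; independent of the Kalman filter.
* **Binned regressions** (`binned_linear_regression`): equal-count bins
  on the predictor (populations differ by ≤1), OLS on the bin means,
  reporting slope, R² and the F-test p-value. Default 10 bins.
* **Variance partition** (`variance_partition`): P(stop) and E[SSD]
  each discretized into 5 equal-count bins; the response is mean RT per
  occupied cell; nested OLS fits (P(stop)-only vs both predictors) on
  the same response give `R²_pstop ≤ R²_combined` by construction, and
  the ratio is the reported fraction.

### Fitting the learning parameters

`fit_dbm_alpha` and `fit_kf_params` grid-search α and (Q, R) against
the RT series, holding (a, b) and (h0, P0) fixed. Two objectives are
provided. `method="binned"` scores each candidate by the group binned
R² of RT vs the candidate predictor — the obvious choice, but recovery
experiments on synthetic cohorts show it is not identifying at this
noise level: with few bins the linear-fit R² rewards *smoother*
candidate series (higher α, higher R/Q), because they linearize the
deadline-compressed (concave) RT response, and the other learner's
smooth RT component acts as spuriously correlated noise between
candidates. The default `method="residual"` therefore scores each
candidate by the per-subject Spearman correlation between the candidate
predictor and RT residualized on a quadratic in the *other* learner's
predictor, averaged over subjects: the rank correlation is insensitive
to the saturating response shape, and residualization removes the
dominant structured-noise component. On homogeneous 20-subject cohorts
generated at (α, Q, R) = (0.75, 0.03, 0.15), this objective returns
α̂ ∈ {0.70, 0.75} and exactly the generating ratio R/Q = 5 across
seeds (only the ratio is identified: it sets the steady-state Kalman
gain, and candidates with equal R/Q score identically to ~1e-4).

## Numerical notes and known limitations

* Belief updates renormalize each step; the stop posterior stays
  normalized to 1e-12 over arbitrary sequences (property-tested).
* The filter-vs-enumeration oracle, the Beta–Bernoulli and Riccati
  closed forms, and the hand-worked Kalman update pin the learners to
  their exact references at tolerances 1e-10–1e-12.
* At the default parameterization (`c = 0.002` makes waiting nearly
  free), simulated go RTs concentrate in the 700–1050 ms range, later
  than every possible SSD. A consequence is that stop errors are
  dominated by *post-onset* responses under misleading stop evidence
  rather than fast pre-onset escapes, so the simulated mean stop-error
  RT slightly *exceeds* the mean correct-go RT (by ~20–35 ms) — the
  opposite of the classical empirical ordering. The inhibition function
  (stop-error rate rising steeply with SSD) is reproduced. The
  corresponding acceptance test asserts the classical ordering and is
  expected to fail at these parameters; the effect appears in this
  model family only when delay is costly enough to pull responses
  forward of the SSD range.
* Problem sizes used by the test suite and the acceptance script: 2,000
  simulated go trials per condition for the RT sweeps, 4,000 stop
  trials per SSD for the inhibition function, and one 20-subject ×
  900-trial cohort for recovery and sequential-effect analyses.
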