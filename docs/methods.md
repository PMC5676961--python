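# Methods

This note records the modelling choices behind `actinf`: the inference
scheme, the task constructions, the numerical conventions, and what the
synthetic studies do and do not establish.

## Belief updating

Hidden states factorise mean-field style (independent posteriors per factor,
combined multiplicatively inside likelihood lookups). Per policy, the
"message sum" that drives the gradient descent `ν ← ν + κ·ε` is evaluated
from the policy-conditioned smoothing distribution over the joint factor
product space, computed by forward–backward over the chain. At the scales in
scope this joint space is small (≤ 40 states at the saccade level, ≤ 630 at
the report level), so the messages are exact: the descent's fixed point is
the optimal marginal posterior, and converged beliefs agree with brute-force
enumeration to machine precision. The error/gradient form is retained
because its transients are the package's electrophysiological observables
(`ν̇` as simulated ERPs).

The per-policy free energy is evaluated against the marginal decomposition
of the generative model:

    F(π) = −ln P(o₁..t | π) + Σ_{τ observed} Σ_f KL(Q(s_τ,f|π) ‖ Q*(s_τ,f|π)).

This is an upper bound on surprise for the factorised posterior, is tight
exactly at the optimal marginals, and is the Lyapunov function of the
descent — it decreases monotonically within every update block. (The naive
product-form evaluation of the joint expectation is not monotone under
these dynamics and saturates its bound only when the true posterior
factorises; we verified both failure modes numerically before adopting the
marginal decomposition.)

Expected free energy is evaluated per future time point as
pragmatic + epistemic: the pragmatic part scores predicted outcomes against
`softmax(C)`; the epistemic part is the negative mutual information between
states and outcomes under the predictive distribution, computed by exact
Bayes inversion of `A`. Summing per-τ terms ignores redundancy between
successive observations of the same state; for greedy saccade selection this
is a monotone transform and does not change the chosen target.

### Policy structure

Two policy conventions coexist, selected by
`InferenceConfig.condition_past_on_executed`:

* **Replanned constant policies** (saccade level): four "fixate quadrant q"
  policies; past transitions are conditioned on the actions actually
  executed, so the policy set is re-evaluated afresh at every step.
* **Committed sequences** (report level): thirteen "withhold until step k,
  then report same/different and hold" policies that own their entire action
  path. Policies whose past actions were not executed accrue evidence
  against them through F (their predicted feedback never arrives). This is
  what gives the precision dynamics something to work with: the posterior
  over policies can then diverge from the prior.

### Precision (simulated dopamine)

β = 1/γ follows the damped fixed point `β ← β₀ + (Q(π) − P(π))·G`,
re-deriving `Q(π) = σ(ln E − γG − F)` and `P(π) = σ(ln E − γG)` with
γ = 1/β at each iterate; β is carried across time steps and anchored at its
prior. A limitation worth stating plainly: because the evidence stream is
shared by all policies consistent with the executed past, `Q(π) → P(π)` as
γ → ∞, so the baseline-subtracted phasic excursion vanishes at very high
precision and peaks at intermediate γ. The attenuation that the precision
sweep tests is therefore measured on the probe-locked γ signal itself
(whose scale is 1/β and which falls strictly with rising β), with the
baseline-subtracted excursion reported alongside.

## The delay-period retrocue task

Seven slow steps: delay, scene 1, scene 2, retrocue, delay, probe, feedback.
The terminal feedback slot exists because an action taken at the probe step
can only influence outcomes one step later; premature responses draw
"incorrect" feedback, which makes withholding optimal until the probe.
Preference log-weights are 0 / +3 / −6 for none / correct / incorrect.

Scene layouts (quadrants TL, TR, LL, LR; every scene places two images):

| scene | TL   | TR    | LL | LR    |
|-------|------|-------|----|-------|
| s1    | bird | seeds | —  | —     |
| s2    | bird | cat   | —  | —     |
| s3    | cat  | —     | —  | seeds |
| s4    | cat  | seeds | —  | —     |
| s5    | cat  | —     | —  | bird  |

The lower-left quadrant is blank everywhere (never informative); the
top-right distinguishes all three core scenes; the lower-right identifies a
scene only when seeds are there. The extra scenes for set sizes 4 and 5
collide with the core set quadrant by quadrant so that an out-of-pair probe
needs one extra fixation per added scene.

Each epoch begins with the eye at the lower-left quadrant (a re-fixation
convention between displays) and ends when the entropy of the
Bayesian-model-average scene belief falls below 0.25 nats, or after 4
steps. At high precision this yields exactly two fixations per scene: the
uninformative inherited one, then a single saccade to the most informative
quadrant. The retrocue display is self-identifying (visible from any
quadrant), so cue and delay epochs resolve in one step.

The retrocue's semantics: cue k raises the probability that the probe
matches the k-th presented scene (validity 0.9 by default, encoded in the
slow level's likelihood), while leaving the marginal probability that the
probe is in the remembered pair untouched — the Monty Hall structure
(2/3 with three scenes and a uniform probe prior) survives the cue.

Reaction time counts every log-belief component updated between probe onset
and report selection, across both levels. This is the deterministic
analogue of "compute time": a bare iteration count is fixed per step by
construction and cannot express the extra work larger hypothesis spaces
demand, whereas the unit-weighted count grows with both the fixation count
and the state-space size, producing the linear set-size effect
(R² ≈ 0.96 over set sizes 3/4/5 at the defaults).

### Simulated ERPs

ERPs are the raw, unfiltered `ν̇` of chosen units, policy-averaged, on a
global iteration clock in which each slow step comprises its epoch's fast
iterations followed by the slow level's own block; slow units are silent
while the fast level updates. One iteration maps to 16 ms for display — a
convention only. The context experiment locks at retrocue onset and splits
the remainder of the trial in half: the early half contains the retrocue
updating (present only when the cue is informative), the late half the probe
response (smaller when the cue already reduced the effective load) — hence
the sign reversal of the difference waveform. The load experiment locks at
probe onset; the valid/invalid difference appears only once the fast level
has finished interrogating the probe, i.e. ~2 fast epochs (≈ 500 ms) in.

## The orientation / volatility model

A single level with 20 circular orientation bins × visibility. Transition
and likelihood kernels are discretised exponential bands
`exp(−precision·d²)` over (wrapped) index distance; column entropy falls
strictly with precision, the identity and uniform matrices being the two
limits. The initial prior peaks near π radians (bin 10, kernel precision 2);
the stimulus appears near π/2 radians (bin 5) during steps 4–5 and is
scripted deterministically, so likelihood precision acts purely through the
agent's updating. Orientation-space circularity is a flag; the default is
circular (an orientation space has no edges), and none of the tested
contrasts depend on the choice. Belief decay is measured as the drop of the
maximum belief over the pre-stimulus steps, stimulus updating as the gain in
belief at the stimulus bin across its presentation.

## Numerical conventions

* Probabilities are floored at 1e−16 before logs; deterministic arrays are
  exactly representable.
* 16 gradient iterations per time step, step size 0.25 (residual per block
  ≈ 0.75¹⁶ ≈ 1%); oracle-comparison tests use 64–300 iterations to reach
  their tolerances.
* 8 damped precision iterations per step; β clamped at 1e−3.
* Action ties break to the lowest action index; a seeded sampling mode is
  available and is used by the precision sweep (with deterministic argmax
  the lesion would be invisible — a flat policy posterior still argmaxes to
  the best saccade).
* All randomness flows through labelled `SeedSequence` streams; scripted
  trials consume no randomness during execution, so precision-sweep rows
  share their world exactly.

## What the synthetic studies do and do not show

The generative processes here are the agent's own model family with scripted
or sampled trajectories: the studies demonstrate the internal consistency of
the scheme (optimal evidence accumulation, epistemic saccade selection,
set-size costs, cue-dependent updating) — not fits to any empirical
recording. Timing is iteration-based and mapped to milliseconds by
convention, so ERP and RT comparisons are qualitative patterns (orderings,
sign changes, linear trends), not latencies. Learning of the arrays
themselves (A/B known, not learned), continuous-state formulations, and
more than two hierarchical levels are out of scope.
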