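"""Single-level variational inference for categorical MDP generative models.

Belief updating is a gradient descent on log-space state beliefs ``nu``: at
each iteration the error ``eps = (message sum) - nu`` is formed and
``nu <- nu + step * eps``, with the posterior read out through a softmax.
The message sum combines the forward (transition) message, the backward
message and the likelihood message for each hidden-state factor; it is
evaluated from the policy-conditioned smoothing distribution over the joint
state space (exact for the chain models in scope), so that at the fixed
point ``eps = 0`` the beliefs coincide with the optimal marginal update and
expected states cease to change.

Policy evaluation combines the variational free energy ``F`` of the past
with the expected free energy ``G`` of the future,
``Q(pi) = sigma(ln E - gamma * G - F)``, where the inverse temperature
``gamma = 1/beta`` is itself optimised (the simulated dopamine signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    GenerativeLevel,
    LOG_FLOOR,
    ln,
    normalise,
    softmax,
)

__all__ = [
    "BeliefState",
    "TrialRecord",
    "InferenceConfig",
    "MDPProcess",
    "init_beliefs",
    "state_error",
    "gradient_update",
    "free_energy",
    "expected_free_energy",
    "policy_posterior",
    "bayesian_model_average",
    "update_precision",
    "select_action",
    "run_level_trial",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class InferenceConfig:
    """Tunable settings of the belief-updating scheme."""

    n_iter: int = 16          # gradient iterations per time step
    step_size: float = 0.25   # kappa in nu <- nu + kappa * eps
    beta_prior: float = 1.0   # prior expectation of 1/gamma
    precision_iters: int = 8  # fixed-point iterations for beta
    update_precision: bool = True
    action_mode: str = "argmax"   # "argmax" (deterministic) or "sample"
    prune_threshold_scale: float = 1.0 / 16.0  # freeze below scale/n_policies
    prune: bool = False
    #: When True, past transitions are conditioned on the actions actually
    #: executed (policies only plan the future; suits replanned "constant
    #: action" policy sets). When False, each policy owns its whole action
    #: sequence, so policies inconsistent with the executed past accrue
    #: evidence against them through F — the substrate of precision
    #: (dopamine) dynamics.
    condition_past_on_executed: bool = True


@dataclass
class BeliefState:
    """Sufficient statistics of the approximate posterior at one level.

    ``nu[f]`` has shape ``[n_policies, T, n_states_f]`` and holds log-space
    beliefs; ``s_bar`` its softmax; ``q_pi`` the policy posterior; ``beta``
    the inverse precision over policies; ``bma[f]`` the policy-averaged
    (Bayesian model average) state posterior per time.
    """

    nu: list
    s_bar: list
    q_pi: np.ndarray
    beta: float
    bma: list
    prior_E: np.ndarray
    active: np.ndarray  # bool mask: policies still updated
    joint_pred: np.ndarray = None  # [n_policies, T, n_joint] smoothed/predicted


@dataclass
class TrialRecord:
    """Time- and iteration-indexed log of one trial at one level."""

    level_name: str
    T: int
    observations: list = field(default_factory=list)   # per step: list per modality (index or vector)
    actions: list = field(default_factory=list)        # per executed transition: tuple
    # per gradient iteration (global index across the trial):
    iter_time: list = field(default_factory=list)      # time step each iteration belongs to
    nu_log: list = field(default_factory=list)         # list per iter: list per factor [n_pol, T, n_f]
    nu_dot_log: list = field(default_factory=list)     # same shape: step*eps increments
    F_iter: list = field(default_factory=list)         # per iter: [n_pol]
    q_pi_iter: list = field(default_factory=list)      # per iter: [n_pol] (posterior in effect)
    # per time step:
    F_step: list = field(default_factory=list)
    G_step: list = field(default_factory=list)
    q_pi_step: list = field(default_factory=list)
    gamma_traj: list = field(default_factory=list)     # per step: per precision-iteration gamma
    bma_step: list = field(default_factory=list)       # per step: list per factor [T, n_f]
    events: dict = field(default_factory=dict)         # label -> global iteration index
    steps_executed: int = 0

    @property
    def n_iterations(self):
        return len(self.nu_log)

    def step_window(self, t):
        """(start, stop) global iteration indices of time step ``t``."""
        idx = [i for i, ti in enumerate(self.iter_time) if ti == t]
        if not idx:
            raise ValueError(f"time step {t} was not executed")
        return idx[0], idx[-1] + 1

    def final_bma(self):
        return self.bma_step[-1]

    def to_frame(self):
        """Tidy table of belief trajectories: one row per
        (iteration, factor, time, state) holding the BMA expectation."""
        import pandas as pd

        rows = []
        for it, (nus, qp) in enumerate(zip(self.nu_log, self.q_pi_iter)):
            for f, nu_f in enumerate(nus):
                sbar = softmax(nu_f, axis=-1)
                avg = np.tensordot(qp, sbar, axes=(0, 0))  # [T, n_f]
                for tt in range(avg.shape[0]):
                    for s in range(avg.shape[1]):
                        rows.append(
                            dict(level=self.level_name, iteration=it,
                                 time=tt, factor=f, unit=s, value=avg[tt, s])
                        )
        return pd.DataFrame(rows)


class DivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# generative process (the true world the agent samples from)
# ---------------------------------------------------------------------------

class MDPProcess:
    """Samples outcomes/transitions from true A/B arrays (which may differ
    from the agent's model). True state trajectories can also be scripted."""

    def __init__(self, A, B, init_states, rng, scripted_states=None,
                 scripted_outcomes=None):
        self.A = A
        self.B = B
        self.states = list(init_states)
        self.rng = rng
        self.scripted_states = scripted_states  # optional: per step list of state tuples
        self.scripted_outcomes = scripted_outcomes  # optional: per step list per modality
        self.t = 0

    def _joint_index(self, dims):
        return np.ravel_multi_index(tuple(self.states), dims)

    def _draw(self, p):
        """Categorical draw; deterministic columns consume no randomness so
        that scripted ("same trial") comparisons stay aligned."""
        p = normalise(p, axis=0)
        if p.max() >= 1.0 - 1e-12:
            return int(np.argmax(p))
        return int(self.rng.choice(len(p), p=p))

    def observe(self):
        if self.scripted_outcomes is not None and self.scripted_outcomes[self.t] is not None:
            return list(self.scripted_outcomes[self.t])
        out = []
        dims = tuple(b.shape[0] for b in self.B)
        j = self._joint_index(dims)
        for a in self.A:
            out.append(self._draw(a.reshape(a.shape[0], -1)[:, j]))
        return out

    def step(self, action):
        self.t += 1
        if self.scripted_states is not None:
            self.states = list(self.scripted_states[self.t])
            return
        self.states = [self._draw(b[:, self.states[f], action[f]])
                       for f, b in enumerate(self.B)]


# ---------------------------------------------------------------------------
# observation handling
# ---------------------------------------------------------------------------

def _obs_vector(level, g, o):
    """Outcome index or soft-evidence vector -> likelihood weights over outcomes."""
    n = level.outcome_dims[g]
    if o is None:
        return None
    if np.isscalar(o):
        v = np.zeros(n)
        v[int(o)] = 1.0
        return v
    v = np.asarray(o, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"modality {g}: evidence length {v.shape} != {n}")
    return v


def _joint_log_likelihood(level, obs_t):
    """Sum over observed modalities of ln sum_o w(o) A[o, s] over joint s."""
    L = np.zeros(level.n_joint)
    for g in range(level.n_modalities):
        w = _obs_vector(level, g, obs_t[g]) if obs_t is not None else None
        if w is None:
            continue
        lik = w @ level.A_flat(g)
        L += ln(lik)
    return L


# ---------------------------------------------------------------------------
# exact policy-conditioned smoothing (the message-sum target)
# ---------------------------------------------------------------------------

def _effective_action(policy, t, executed):
    """Action applied at transition t -> t+1: the executed action for past
    transitions, the policy's prescription for future ones."""
    if executed is not None and t < len(executed):
        return tuple(executed[t])
    return tuple(policy.action_at(t))


def _policy_targets(level, policy, observations, executed=None):
    """Per-time smoothing/prediction over the joint state for one policy.

    Observed steps (entries of ``observations`` that are not None) are
    combined by forward-backward over the joint chain; steps beyond the last
    observation are predicted through B. Returns (q_joint [T, n_joint],
    log-evidence ln P(o_1..t | pi)).
    """
    T = level.T
    nj = level.n_joint
    obs_times = [t for t, o in enumerate(observations[:T]) if o is not None]
    t_last = max(obs_times) if obs_times else -1

    logL = np.zeros((T, nj))
    for t in range(T):
        if t <= t_last and observations[t] is not None:
            logL[t] = _joint_log_likelihood(level, observations[t])

    trans = [level.joint_transition(_effective_action(policy, t, executed))
             for t in range(max(T - 1, 0))]

    q = np.zeros((T, nj))
    if t_last < 0:
        # pure prior prediction
        q[0] = level.joint_initial()
        for t in range(1, T):
            q[t] = trans[t - 1] @ q[t - 1]
        return q, 0.0

    # forward pass with per-step normalisation (log evidence accumulates)
    alpha = np.zeros((t_last + 1, nj))
    log_ev = 0.0
    prior = level.joint_initial()
    for t in range(t_last + 1):
        pred = prior if t == 0 else trans[t - 1] @ alpha[t - 1]
        a = pred * np.exp(logL[t] - logL[t].max())
        z = a.sum()
        if z <= 0:
            raise DivergenceError(f"zero-probability observation at time {t}")
        log_ev += np.log(z) + logL[t].max()
        alpha[t] = a / z

    # backward pass
    beta_v = np.ones(nj)
    q[t_last] = alpha[t_last]
    for t in range(t_last - 1, -1, -1):
        w = beta_v * np.exp(logL[t + 1] - logL[t + 1].max())
        beta_v = trans[t].T @ w
        beta_v = beta_v / beta_v.max() if beta_v.max() > 0 else beta_v
        q[t] = normalise(alpha[t] * beta_v, axis=0)

    # prediction beyond the last observation
    for t in range(t_last + 1, T):
        q[t] = trans[t - 1] @ q[t - 1]
    return q, float(log_ev)


def _log_normalise(nu):
    return nu - np.log(np.exp(nu - nu.max(axis=-1, keepdims=True)).sum(axis=-1, keepdims=True)) - nu.max(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# beliefs
# ---------------------------------------------------------------------------

def init_beliefs(level: GenerativeLevel, config: InferenceConfig,
                 prior_E=None) -> BeliefState:
    """Uniform log-beliefs for every policy/time/factor; uniform policy
    posterior unless a prior E (habit) is supplied."""
    n_pol = len(level.policies)
    nu, s_bar, bma = [], [], []
    for f, dim in enumerate(level.state_dims):
        v = np.full((n_pol, level.T, dim), -np.log(dim))
        nu.append(v)
        s_bar.append(softmax(v, axis=-1))
        bma.append(np.full((level.T, dim), 1.0 / dim))
    E = normalise(np.asarray(prior_E, dtype=float), axis=0) if prior_E is not None \
        else np.full(n_pol, 1.0 / n_pol)
    return BeliefState(
        nu=nu, s_bar=s_bar,
        q_pi=E.copy(), beta=config.beta_prior, bma=bma, prior_E=E,
        active=np.ones(n_pol, dtype=bool),
    )


def state_error(level, policy_idx, t, beliefs, observations, executed=None):
    """Log-space prediction error ``eps_{pi,t}`` per factor: the message sum
    (forward + backward + likelihood, with boundary terms from D) minus the
    current log belief. Zero exactly at the optimal marginal fixed point.

    Both terms are compared on the normalised log scale, so the error is
    invariant to additive constants in ``nu`` (the softmax readout discards
    them anyway)."""
    if not 0 <= t < level.T:
        raise ValueError(f"time index {t} outside horizon {level.T}")
    policy = level.policies[policy_idx]
    q_joint, _ = _policy_targets(level, policy, observations, executed=executed)
    marg = level.marginals_from_joint(q_joint[t])
    errs = []
    for f in range(level.n_factors):
        target = _log_normalise(ln(marg[f])[None, :])[0]
        nu_f = _log_normalise(beliefs.nu[f][policy_idx, t][None, :])[0]
        errs.append(target - nu_f)
    return errs


def gradient_update(beliefs, level, observations, n_iter=16, step_size=0.25,
                    record=None, t_now=None, executed=None):
    """Run ``n_iter`` gradient iterations ``nu <- nu + step * eps`` for all
    (active) policies and times; softmax readout after every iteration.

    ``nu`` itself is left unnormalised so that recorded increments
    ``nu_dot = step * eps`` are exactly the finite differences of the ``nu``
    snapshots. Appends per-iteration ``nu``, ``nu_dot`` and per-policy free
    energy to ``record`` when given. Raises DivergenceError if any belief
    becomes non-finite.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < step_size <= 1:
        raise ValueError("step_size must be in (0, 1]")
    n_pol = len(level.policies)
    targets = []       # per policy: per factor [T, n_f] normalised log targets
    marg_targets = []  # same in probability space (for the cached F)
    log_evidence = np.zeros(n_pol)
    joint_pred = np.zeros((n_pol, level.T, level.n_joint))
    for p in range(n_pol):
        q_joint, lev = _policy_targets(level, level.policies[p], observations,
                                       executed=executed)
        joint_pred[p] = q_joint
        log_evidence[p] = lev
        per_f, per_f_prob = [], []
        for m in zip(*[level.marginals_from_joint(q_joint[t])
                       for t in range(level.T)]):
            stacked = np.stack(m)
            per_f.append(_log_normalise(ln(stacked)))
            per_f_prob.append(stacked)
        targets.append(per_f)
        marg_targets.append(per_f_prob)
    beliefs.joint_pred = joint_pred

    obs_mask = [t < len(observations) and observations[t] is not None
                for t in range(level.T)]

    def cached_F(p):
        # free energy against the marginal decomposition, from cached targets
        F = -log_evidence[p]
        for t in range(level.T):
            if not obs_mask[t]:
                continue
            for f in range(level.n_factors):
                q = beliefs.s_bar[f][p, t]
                nz = q > 0
                F += float((q[nz] * (np.log(q[nz])
                                     - ln(marg_targets[p][f][t])[nz])).sum())
        return F

    for it in range(n_iter):
        nu_dot = [np.zeros_like(beliefs.nu[f]) for f in range(level.n_factors)]
        for p in range(n_pol):
            if not beliefs.active[p]:
                continue
            for f in range(level.n_factors):
                eps = targets[p][f] - _log_normalise(beliefs.nu[f][p])
                dd = step_size * eps
                nu_dot[f][p] = dd
                beliefs.nu[f][p] = beliefs.nu[f][p] + dd
                if not np.all(np.isfinite(beliefs.nu[f][p])):
                    raise DivergenceError(
                        f"non-finite belief for policy {p}, factor {f}")
        for f in range(level.n_factors):
            beliefs.s_bar[f] = softmax(beliefs.nu[f], axis=-1)
        if record is not None:
            record.iter_time.append(t_now)
            record.nu_log.append([beliefs.nu[f].copy() for f in range(level.n_factors)])
            record.nu_dot_log.append(nu_dot)
            record.F_iter.append(np.array([cached_F(p) for p in range(n_pol)]))
            record.q_pi_iter.append(beliefs.q_pi.copy())
    return beliefs


# ---------------------------------------------------------------------------
# free energy and expected free energy
# ---------------------------------------------------------------------------

def free_energy(level, policy_idx, beliefs, observations, executed=None):
    """Per-policy variational free energy over the observed time steps.

    Evaluated for the factorised posterior (product over times and factors)
    against the marginal decomposition of the generative model:

        F(pi) = -ln P(o_{1:t} | pi)
                + sum_{tau observed} sum_f KL(Q(s_tau,f | pi) || Q*(s_tau,f | pi))

    where Q* are the optimal marginals. F is an upper bound on the negative
    log evidence, saturated exactly when the beliefs reach the optimal
    marginal fixed point, and it is the Lyapunov function of the gradient
    descent in :func:`gradient_update`: non-increasing over iterations.
    """
    policy = level.policies[policy_idx]
    q_joint, log_ev = _policy_targets(level, policy, observations,
                                      executed=executed)
    F = -log_ev
    for t in range(level.T):
        if t >= len(observations) or observations[t] is None:
            continue
        targets = level.marginals_from_joint(q_joint[t])
        for f in range(level.n_factors):
            q = beliefs.s_bar[f][policy_idx, t]
            nz = q > 0
            F += float((q[nz] * (np.log(q[nz]) - ln(targets[f])[nz])).sum())
    return float(F)


def expected_free_energy(level, policy_idx, beliefs, tau):
    """G(pi, tau) and its pragmatic/epistemic parts for one future step.

    pragmatic = -E_{Q(o|pi)}[ln P(o)] with P(o) = softmax(C);
    epistemic = E[ln Q(s|pi) - ln P(s|o,pi)] = -I(s; o) <= 0, with the
    posterior obtained by exact Bayes inversion of A against the predictive
    state distribution.
    """
    if not 0 <= tau < level.T:
        raise ValueError(f"tau {tau} outside horizon {level.T}")
    if beliefs.joint_pred is None:
        raise ValueError("run gradient_update before expected_free_energy")
    q = beliefs.joint_pred[policy_idx, tau]
    pragmatic = 0.0
    epistemic = 0.0
    for g in range(level.n_modalities):
        A = level.A_flat(g)
        p_o = A @ q
        logC = level.C[g] - np.log(np.exp(level.C[g] - level.C[g].max()).sum()) \
            - level.C[g].max()
        pragmatic -= float(p_o @ logC)
        # mutual information I(s; o) under Q(s) P(o|s)
        p_so = A * q[None, :]
        nz = p_so > 0
        mi = float((p_so[nz] * (np.log(p_so[nz])
                                - ln(p_o)[np.nonzero(nz)[0]]
                                - ln(q)[np.nonzero(nz)[1]])).sum())
        epistemic -= max(mi, 0.0)
    return pragmatic + epistemic, pragmatic, epistemic


def total_expected_free_energy(level, policy_idx, beliefs, t_now):
    """G(pi) = sum over future steps tau > t_now of G(pi, tau)."""
    G = 0.0
    for tau in range(t_now + 1, level.T):
        g, _, _ = expected_free_energy(level, policy_idx, beliefs, tau)
        G += g
    return G


# ---------------------------------------------------------------------------
# policies, precision, action
# ---------------------------------------------------------------------------

def policy_posterior(F_per_policy, G_per_policy, gamma, prior_E=None):
    """Q(pi) = sigma(ln E - gamma * G - F); E uniform when absent."""
    F = np.asarray(F_per_policy, dtype=float)
    G = np.asarray(G_per_policy, dtype=float)
    if F.shape != G.shape:
        raise ValueError("F and G must have the same length")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    logE = ln(np.full(len(F), 1.0 / len(F)) if prior_E is None
              else normalise(np.asarray(prior_E, dtype=float), axis=0))
    return softmax(logE - gamma * G - F)


def bayesian_model_average(q_pi, s_bar_per_policy, t):
    """Q(s_t) = sum_pi Q(pi) Q(s_t | pi) (per factor)."""
    q_pi = np.asarray(q_pi, dtype=float)
    out = []
    for sb in s_bar_per_policy:
        if sb.shape[0] != len(q_pi):
            raise ValueError("policy cardinality mismatch")
        out.append(np.tensordot(q_pi, sb[:, t, :], axes=(0, 0)))
    return out


def update_precision(beta_prior, F_per_policy, G_per_policy, prior_E=None,
                     n_iter=8, beta_init=None, tol=1e-6):
    """Fixed-point updates of the inverse precision beta = 1/gamma.

    Iterates beta towards  beta_prior + (Q(pi) - P(pi)) . G, re-deriving the
    policy posterior Q(pi) = sigma(ln E - gamma G - F) and prior
    P(pi) = sigma(ln E - gamma G) with gamma = 1/beta at every iteration.
    A posterior shifted towards lower-G policies than the prior therefore
    lowers beta (raises gamma). Returns (beta, gamma trajectory, converged).
    """
    if not beta_prior > 0:
        raise ValueError("beta_prior must be positive")
    F = np.asarray(F_per_policy, dtype=float)
    G = np.asarray(G_per_policy, dtype=float)
    logE = ln(np.full(len(F), 1.0 / len(F)) if prior_E is None
              else normalise(np.asarray(prior_E, dtype=float), axis=0))
    beta = float(beta_init) if beta_init is not None else float(beta_prior)
    traj = []
    converged = False
    for _ in range(n_iter):
        gamma = 1.0 / beta
        q_pi = softmax(logE - gamma * G - F)
        p_pi = softmax(logE - gamma * G)
        err = (beta - beta_prior) - float((q_pi - p_pi) @ G)
        beta = max(beta - err / 2.0, 1e-3)
        traj.append(1.0 / beta)
        if abs(err) < tol:
            converged = True
            break
    return beta, traj, converged


def select_action(q_pi, policies, t, mode="argmax", rng=None):
    """Marginalise the policy posterior onto the action prescribed at step
    ``t`` and return the most probable composite action (ties: lowest action
    indices). ``mode='sample'`` draws from the marginal instead."""
    q_pi = np.asarray(q_pi, dtype=float)
    marg = {}
    for p, pol in enumerate(policies):
        a = tuple(pol.action_at(t))
        marg[a] = marg.get(a, 0.0) + q_pi[p]
    acts = sorted(marg)  # lexicographic: deterministic tie-break
    probs = np.array([marg[a] for a in acts])
    if mode == "sample":
        if rng is None:
            raise ValueError("sampling action selection needs an rng")
        return acts[int(rng.choice(len(acts), p=normalise(probs, axis=0)))]
    best = np.flatnonzero(probs >= probs.max() - 1e-12)
    return acts[best[0]]


# ---------------------------------------------------------------------------
# one full trial at a single level
# ---------------------------------------------------------------------------

def run_level_trial(level, process, config: InferenceConfig, prior_E=None,
                    agent_rng=None, terminate_fn=None, record=None,
                    beliefs=None, extra_obs_fn=None):
    """Simulate one trial: for each time step sample an outcome from the
    generative process, update beliefs by gradient descent, evaluate F and G,
    update the policy posterior and precision, form the Bayesian model
    average, and select/execute an action.

    ``terminate_fn(bma_t, t)`` may end the trial early (epoch termination in
    hierarchies). ``extra_obs_fn(t)`` may supply additional soft evidence
    (the hierarchical scheduler uses this to inject descending/ascending
    messages). Returns the TrialRecord.
    """
    if record is None:
        record = TrialRecord(level_name=level.name, T=level.T)
    if beliefs is None:
        beliefs = init_beliefs(level, config, prior_E=prior_E)
    observations = [None] * level.T
    n_pol = len(level.policies)

    for t in range(level.T):
        o_t = process.observe()
        if extra_obs_fn is not None:
            o_t = extra_obs_fn(t, o_t)
        observations[t] = o_t
        record.observations.append(o_t)

        executed = record.actions if config.condition_past_on_executed else None
        gradient_update(beliefs, level, observations,
                        n_iter=config.n_iter, step_size=config.step_size,
                        record=record, t_now=t, executed=executed)

        F = record.F_iter[-1]
        G = np.array([total_expected_free_energy(level, p, beliefs, t)
                      for p in range(n_pol)])

        if config.update_precision:
            beta, gtraj, _ = update_precision(
                config.beta_prior, F, G, prior_E=beliefs.prior_E,
                n_iter=config.precision_iters, beta_init=beliefs.beta)
            beliefs.beta = beta
        else:
            gtraj = [1.0 / beliefs.beta]
        gamma = 1.0 / beliefs.beta
        beliefs.q_pi = policy_posterior(F, G, gamma, prior_E=beliefs.prior_E)

        if config.prune:
            thresh = config.prune_threshold_scale / n_pol
            beliefs.active &= beliefs.q_pi >= thresh
            if not beliefs.active.any():
                beliefs.active[:] = True

        bma = [np.stack([bayesian_model_average(beliefs.q_pi, beliefs.s_bar, tt)[f]
                         for tt in range(level.T)])
               for f in range(level.n_factors)]
        beliefs.bma = bma

        record.F_step.append(F)
        record.G_step.append(G)
        record.q_pi_step.append(beliefs.q_pi.copy())
        record.gamma_traj.append(list(gtraj))
        record.bma_step.append([b.copy() for b in bma])
        record.steps_executed = t + 1

        if terminate_fn is not None and terminate_fn([b[t] for b in bma], t):
            break
        if t < level.T - 1:
            action = select_action(beliefs.q_pi, level.policies, t,
                                   mode=config.action_mode, rng=agent_rng)
            record.actions.append(action)
            process.step(action)

    record.final_beliefs = beliefs
    return record
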