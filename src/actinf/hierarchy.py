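"""Deep temporal composition of MDP levels.

Higher levels evolve on a slower clock: every higher-level time step spawns a
full lower-level trial (an *epoch*). Descending messages condition the lower
level's initial-state prior D and policy prior E on the higher-level state;
ascending messages return the evidence the lower level accumulated about
which higher-level state generated its epoch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core_model import HierarchicalModel, ln, normalise
from .inference import (
    InferenceConfig,
    TrialRecord,
    init_beliefs,
    run_level_trial,
)

__all__ = [
    "EpochSchedule",
    "HierarchicalConfig",
    "HierarchicalTrialResult",
    "descend",
    "ascend",
    "terminate_epoch",
    "run_hierarchical_trial",
]


@dataclass
class EpochSchedule:
    """Which lower-level steps/iterations each higher-level step spans."""

    lower_steps: list = field(default_factory=list)   # per upper step: count
    lower_iters: list = field(default_factory=list)   # per upper step: gradient iterations
    upper_iters: list = field(default_factory=list)   # per upper step: gradient iterations

    def global_offset(self, upper_t, within="upper"):
        """Global iteration index at which upper step ``upper_t``'s lower
        epoch ("lower") or its own update block ("upper") begins."""
        off = 0
        for t in range(upper_t):
            off += self.lower_iters[t] + self.upper_iters[t]
        if within == "upper":
            off += self.lower_iters[upper_t]
        return off

    @property
    def total_iterations(self):
        return sum(self.lower_iters) + sum(self.upper_iters)


@dataclass
class HierarchicalConfig:
    lower: InferenceConfig = field(default_factory=InferenceConfig)
    upper: InferenceConfig = field(default_factory=InferenceConfig)
    entropy_threshold: float = 0.25  # nats; epoch ends below this
    terminate_factor: int = 0        # lower factor whose BMA entropy gates the epoch


@dataclass
class HierarchicalTrialResult:
    upper_record: TrialRecord
    lower_records: list
    schedule: EpochSchedule
    events: dict = field(default_factory=dict)  # label -> upper step index


def descend(upper_belief, link_init, link_policy=None):
    """Condition the lower level on the superordinate state:
    lower D = link_init . upper_belief, lower E = link_policy . upper_belief."""
    upper_belief = np.asarray(upper_belief, dtype=float)
    if link_init.shape[1] != upper_belief.shape[0]:
        raise ValueError("link/belief cardinality mismatch")
    D = normalise(link_init @ upper_belief, axis=0)
    E = None
    if link_policy is not None:
        if link_policy.shape[1] != upper_belief.shape[0]:
            raise ValueError("link/belief cardinality mismatch")
        E = normalise(link_policy @ upper_belief, axis=0)
    return D, E


def ascend(lower_posterior, link_init, lower_prior=None):
    """Log-evidence over higher-level states from a completed epoch.

    The evidence the epoch accumulated about the lower initial state is its
    converged posterior with the descended prior divided out (the linked
    factor is static within an epoch, so posterior/prior is exactly the
    accumulated likelihood). The message is ln(link^T likelihood), invariant
    to adding a constant to the lower log-posterior.
    """
    q = np.asarray(lower_posterior, dtype=float)
    if lower_prior is not None:
        w = q / np.maximum(np.asarray(lower_prior, dtype=float), 1e-16)
    else:
        w = q.copy()
    if w.sum() <= 0:
        raise ValueError("lower posterior carries no mass")
    w = w / w.sum()
    return ln(link_init.T @ w)


def epoch_evidence_weights(lower_posterior, lower_prior):
    """Normalised likelihood weights over lower states (posterior with the
    descended prior divided out) — the soft-evidence form of ``ascend``."""
    w = np.asarray(lower_posterior, dtype=float) / np.maximum(
        np.asarray(lower_prior, dtype=float), 1e-16)
    return w / w.sum()


def terminate_epoch(lower_bma_factor, threshold):
    """True when the entropy of the lower level's scene-identity belief has
    fallen below ``threshold`` (uncertainty resolved; move to the next scene)."""
    p = np.asarray(lower_bma_factor, dtype=float)
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    return H < threshold


def run_hierarchical_trial(model: HierarchicalModel, process,
                           config: HierarchicalConfig,
                           agent_rng=None, linked_modality=0,
                           events=None):
    """Nested simulation of a two-level model.

    ``process`` must expose ``upper`` (an MDPProcess over the top level) and
    ``lower_factory(upper_t, upper_states)`` returning a generative process
    for the epoch spawned at upper step ``upper_t``.

    For each top-level step: descend to set the lower priors, run the lower
    trial (terminating early once scene uncertainty is resolved), convert the
    epoch's accumulated evidence into a soft observation on the upper level's
    linked modality, and complete the upper-level inference/policy/precision
    updates. Returns per-level records plus the epoch schedule.
    """
    if len(model.levels) < 2:
        raise ValueError("hierarchical trial needs at least two levels")
    lower, upper = model.levels[0], model.levels[1]
    link_init, link_policy = model.link_init[0], model.link_policy[0]
    schedule = EpochSchedule()
    lower_records = []
    upper_beliefs = init_beliefs(upper, config.upper)

    def upper_predictive(t2):
        """Joint predictive distribution over the upper state at step t2,
        policy-averaged, given observations before t2."""
        if upper_beliefs.joint_pred is None:
            return upper.joint_initial()
        q = np.tensordot(upper_beliefs.q_pi,
                         upper_beliefs.joint_pred[:, t2, :], axes=(0, 0))
        return normalise(q, axis=0)

    def extra_obs(t2, o_t):
        pred = upper_predictive(t2)
        D_low, E_low = descend(pred, link_init, link_policy)
        lower_t = dataclasses.replace(
            lower, D=[D_low if f == model.linked_factor else d
                      for f, d in enumerate(lower.D)])
        lp = process.lower_factory(t2, process.upper.states)
        lrec = run_level_trial(
            lower_t, lp, config.lower, prior_E=E_low, agent_rng=agent_rng,
            terminate_fn=lambda bma_t, t: terminate_epoch(
                bma_t[config.terminate_factor], config.entropy_threshold),
        )
        lower_records.append(lrec)
        schedule.lower_steps.append(lrec.steps_executed)
        schedule.lower_iters.append(lrec.n_iterations)
        w = epoch_evidence_weights(
            lrec.final_bma()[model.linked_factor][lrec.steps_executed - 1],
            D_low)
        o_t = list(o_t)
        o_t[linked_modality] = w
        return o_t

    upper_record = run_level_trial(
        upper, process.upper, config.upper, agent_rng=agent_rng,
        extra_obs_fn=extra_obs, beliefs=upper_beliefs)

    # upper iterations per step (lower counts were appended in extra_obs)
    for t2 in range(upper_record.steps_executed):
        start, stop = upper_record.step_window(t2)
        schedule.upper_iters.append(stop - start)

    return HierarchicalTrialResult(
        upper_record=upper_record,
        lower_records=lower_records,
        schedule=schedule,
        events=dict(events or {}),
    )
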