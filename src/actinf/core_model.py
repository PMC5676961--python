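"""Categorical generative-model containers for one MDP level and for hierarchies.

An agent's generative model is specified by the classical four arrays of a
discrete (PO)MDP:

* ``A`` — likelihood: one array per outcome modality ``g``,
  ``A[g][o, s_1, ..., s_F] = P(o_t = o | s_t = (s_1, ..., s_F))``;
* ``B`` — transitions: one array per hidden-state factor ``f``,
  ``B[f][s', s, u] = P(s_{t+1} = s' | s_t = s, u_t = u)``;
* ``C`` — log-preferences over outcomes per modality (need not normalise:
  they only ever enter through expected log-probabilities);
* ``D`` — priors over initial states per factor.

Hidden states factorise mean-field style: posteriors are held per factor and
combined multiplicatively inside ``A`` lookups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: probabilities are floored at this value before taking logs, keeping
#: messages finite in the presence of deterministic (0/1) arrays.
LOG_FLOOR = 1e-16

NORM_TOL = 1e-8


def ln(x):
    """Elementwise natural log with the package-wide probability floor."""
    return np.log(np.maximum(x, LOG_FLOOR))


def softmax(x, axis=-1):
    x = np.asarray(x, dtype=float)
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def normalise(p, axis=0):
    """Normalise a non-negative array to sum to one along ``axis``."""
    p = np.asarray(p, dtype=float)
    s = p.sum(axis=axis, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return p / s


def is_distribution(p, tol=NORM_TOL):
    p = np.asarray(p, dtype=float)
    return bool(np.all(p >= -tol) and abs(p.sum() - 1.0) <= tol)


@dataclass
class Policy:
    """A sequence of composite actions, one tuple of per-factor action
    indices for every future transition."""

    actions: tuple  # tuple of tuples: actions[step][factor] -> action index

    def action_at(self, step):
        """Action tuple applied at transition ``step`` -> ``step + 1``.

        Depth-one policies are padded by repeating their last action, which
        makes "constant action" policy sets behave as the obvious plans.
        """
        idx = min(step, len(self.actions) - 1)
        return self.actions[idx]


@dataclass
class GenerativeLevel:
    """One MDP level: arrays, policy set, horizon and label tables."""

    A: list  # per modality g: ndarray [n_out_g, *state_dims]
    B: list  # per factor f: ndarray [n_next, n_cur, n_act_f]
    C: list  # per modality g: ndarray [n_out_g] (log units)
    D: list  # per factor f: ndarray [n_states_f]
    policies: list  # list of Policy
    T: int  # number of time steps in a trial at this level
    state_labels: list = field(default_factory=list)  # per factor: list of str
    outcome_labels: list = field(default_factory=list)  # per modality
    action_labels: list = field(default_factory=list)  # per factor
    name: str = "level"

    # --- derived geometry -------------------------------------------------
    @property
    def n_factors(self):
        return len(self.B)

    @property
    def n_modalities(self):
        return len(self.A)

    @property
    def state_dims(self):
        return tuple(b.shape[0] for b in self.B)

    @property
    def outcome_dims(self):
        return tuple(a.shape[0] for a in self.A)

    @property
    def n_joint(self):
        return int(np.prod(self.state_dims))

    def A_flat(self, g):
        """Likelihood of modality ``g`` over the flattened joint state."""
        return self.A[g].reshape(self.A[g].shape[0], -1)

    def joint_transition(self, action):
        """Joint transition matrix over the flattened state space for one
        composite action (Kronecker product of per-factor B slices)."""
        key = tuple(action)
        cache = self.__dict__.setdefault("_trans_cache", {})
        if key not in cache:
            M = np.ones((1, 1))
            for f, b in enumerate(self.B):
                M = np.kron(M, b[:, :, action[f]])
            cache[key] = M
        return cache[key]

    def joint_initial(self):
        p = np.ones(1)
        for d in self.D:
            p = np.kron(p, d)
        return p

    def marginals_from_joint(self, q_joint):
        """Per-factor marginals of a distribution over the joint state."""
        q = q_joint.reshape(self.state_dims)
        out = []
        for f in range(self.n_factors):
            axes = tuple(i for i in range(self.n_factors) if i != f)
            out.append(q.sum(axis=axes) if axes else q.copy())
        return out


@dataclass
class HierarchicalModel:
    """Ordered levels (index 0 = lowest) plus the conditional link arrays
    that couple adjacent levels.

    ``link_init[i]`` maps the joint state at level ``i+1`` onto the prior over
    the linked factor's initial state at level ``i``:
    ``link_init[i][s_low, s_high_joint] = P(s_1^{(i)} | s^{(i+1)})``.
    ``link_policy[i]`` does the same for the lower level's policy prior.
    """

    levels: list
    link_init: list  # per adjacent pair: ndarray [n_lower_states, n_upper_joint]
    link_policy: list  # per adjacent pair: ndarray [n_lower_policies, n_upper_joint]
    steps_per_epoch: int = 4
    linked_factor: int = 0  # which lower-level factor the init link feeds


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_columns(name, arr, viols):
    """Every slice along axis 0 (fixed conditioning indices) must be a
    categorical distribution."""
    flat = arr.reshape(arr.shape[0], -1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        if np.any(col < 0):
            viols.append(f"{name}: column {j} has a negative entry")
        elif abs(col.sum() - 1.0) > NORM_TOL:
            viols.append(f"{name}: column {j} sums to {col.sum():.6g}, not 1")


def validate_level(level: GenerativeLevel):
    """Return a list of human-readable invariant violations (empty iff valid)."""
    v = []
    dims = level.state_dims
    for g, a in enumerate(level.A):
        if a.shape[1:] != dims:
            v.append(f"A[{g}]: state dimensions {a.shape[1:]} != {dims}")
        else:
            _check_columns(f"A[{g}]", a, v)
    for f, b in enumerate(level.B):
        if b.ndim != 3 or b.shape[0] != b.shape[1]:
            v.append(f"B[{f}]: expected square [next, current, action] array")
        else:
            _check_columns(f"B[{f}]", b, v)
    for f, d in enumerate(level.D):
        if d.shape[0] != dims[f]:
            v.append(f"D[{f}]: length {d.shape[0]} != factor cardinality {dims[f]}")
        elif not is_distribution(d):
            v.append(f"D[{f}]: not a normalised non-negative distribution")
    for g, c in enumerate(level.C):
        if not np.all(np.isfinite(c)):
            v.append(f"C[{g}]: non-finite log-preference")
        if c.shape[0] != level.outcome_dims[g]:
            v.append(f"C[{g}]: length {c.shape[0]} != modality cardinality")
    if not level.policies:
        v.append("policies: at least one policy required")
    for p_i, pol in enumerate(level.policies):
        if len(pol.actions) > level.T:
            v.append(f"policy {p_i}: longer than horizon {level.T}")
        for step, act in enumerate(pol.actions):
            for f, u in enumerate(act):
                if not (0 <= u < level.B[f].shape[2]):
                    v.append(
                        f"policy {p_i}: action {u} at step {step} outside "
                        f"factor {f} cardinality {level.B[f].shape[2]}"
                    )
    if level.state_labels:
        for f, labels in enumerate(level.state_labels):
            if len(labels) != dims[f]:
                v.append(f"state_labels[{f}]: {len(labels)} labels for {dims[f]} states")
    return v


def validate_hierarchy(model: HierarchicalModel):
    v = []
    for i, (link, lower, upper) in enumerate(
        zip(model.link_init, model.levels[:-1], model.levels[1:])
    ):
        if link.shape != (lower.state_dims[model.linked_factor], upper.n_joint):
            v.append(f"link_init[{i}]: shape {link.shape} inconsistent with levels")
        else:
            _check_columns(f"link_init[{i}]", link, v)
    for i, (link, lower, upper) in enumerate(
        zip(model.link_policy, model.levels[:-1], model.levels[1:])
    ):
        if link.shape != (len(lower.policies), upper.n_joint):
            v.append(f"link_policy[{i}]: shape {link.shape} inconsistent with levels")
        else:
            _check_columns(f"link_policy[{i}]", link, v)
    if model.steps_per_epoch < 1:
        v.append("steps_per_epoch must be >= 1")
    return v


# ---------------------------------------------------------------------------
# entropies and precision kernels
# ---------------------------------------------------------------------------

def _entropy(p):
    p = np.asarray(p, dtype=float)
    if not is_distribution(p):
        raise ValueError("entropy requires a normalised non-negative distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def transition_entropy(b_column):
    """Volatility of one B column, H = -sum p ln p (nats); 0 for a
    deterministic transition, ln n for a maximally volatile one."""
    return _entropy(b_column)


def likelihood_entropy(a_column):
    """Imprecision of one A column (nats): 0 when an outcome uniquely
    identifies the hidden state, ln m when it carries no information."""
    return _entropy(a_column)


def make_banded_kernel(n, precision, circular=False):
    """Column-stochastic kernel exp(-precision * d^2) banded about the
    diagonal; ``d`` is index distance, wrapped modulo ``n`` when circular.

    Column entropy decreases monotonically in ``precision``: the identity in
    the precision -> inf limit (zero volatility), uniform columns as
    precision -> 0. ``precision=np.inf`` returns the identity exactly.
    """
    if n < 2:
        raise ValueError("kernel needs n >= 2")
    if not precision > 0:
        raise ValueError("precision must be positive")
    if np.isinf(precision):
        return np.eye(n)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    if circular:
        d = np.minimum(d, n - d)
    K = np.exp(-precision * d.astype(float) ** 2)
    return normalise(K, axis=0)


# ---------------------------------------------------------------------------
# constructors used by config files
# ---------------------------------------------------------------------------

#: named matrix constructors usable in declarative model specifications
def _ctor_identity(n, **_):
    return np.eye(n)


def _ctor_uniform(n, m=None, **_):
    m = n if m is None else m
    return np.full((m, n), 1.0 / m)


def _ctor_banded(n, precision, circular=False, **_):
    return make_banded_kernel(n, precision, circular=circular)


MATRIX_CONSTRUCTORS = {
    "identity": _ctor_identity,
    "uniform": _ctor_uniform,
    "banded_kernel": _ctor_banded,
}


def matrix_from_spec(spec, n=None):
    """Dense matrix from a declarative entry: either a nested list of
    numbers, or ``{"constructor": name, ...kwargs}`` using the named
    constructors (identity, uniform, banded_kernel)."""
    if isinstance(spec, dict):
        kind = spec.get("constructor")
        if kind not in MATRIX_CONSTRUCTORS:
            raise ValueError(f"unknown matrix constructor {kind!r}")
        kw = {k: v for k, v in spec.items() if k != "constructor"}
        if n is not None:
            kw.setdefault("n", n)
        return MATRIX_CONSTRUCTORS[kind](**kw)
    return np.asarray(spec, dtype=float)


def level_from_dict(data):
    """Build a GenerativeLevel from a declarative mapping (the parsed form
    of a JSON/YAML model file): label tables plus A/B/C/D given as dense
    arrays or named constructors; B entries may be 2-d (single action).

    The result is validated; violations raise ValueError.
    """
    states = data["state_labels"]
    outcomes = data["outcome_labels"]
    B = []
    for f, spec in enumerate(data["B"]):
        b = matrix_from_spec(spec, n=len(states[f]))
        if b.ndim == 2:
            b = b[:, :, None]
        B.append(b)
    A = [matrix_from_spec(spec) for spec in data["A"]]
    C = [np.asarray(c, dtype=float) if c is not None else np.zeros(len(o))
         for c, o in zip(data.get("C", [None] * len(A)), outcomes)]
    D = [normalise(matrix_from_spec(d, n=len(s)).reshape(-1), axis=0)
         if not isinstance(d, dict) else matrix_from_spec(d, n=len(s))[:, 0]
         for d, s in zip(data["D"], states)]
    policies = [Policy(actions=tuple(tuple(a) for a in p))
                for p in data["policies"]]
    level = GenerativeLevel(
        A=A, B=B, C=C, D=D, policies=policies, T=int(data["T"]),
        state_labels=states, outcome_labels=outcomes,
        name=data.get("name", "level"))
    bad = validate_level(level)
    if bad:
        raise ValueError("; ".join(bad))
    return level


def constant_policies(n_actions, controllable_factor, n_factors, depth=1):
    """Policy set of one constant-action policy per action of one factor."""
    pols = []
    for u in range(n_actions):
        act = tuple(u if f == controllable_factor else 0 for f in range(n_factors))
        pols.append(Policy(actions=tuple([act] * depth)))
    return pols


def enumerate_joint_states(dims):
    return list(itertools.product(*[range(d) for d in dims]))
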