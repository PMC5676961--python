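"""Shared fixtures and independent oracles for the test suite.

The enumeration oracle below computes posteriors and evidence by summing
over every hidden-state sequence with itertools — a code path deliberately
disjoint from the package's forward-backward implementation.
"""

import itertools

import numpy as np
import pytest

from actinf.core_model import GenerativeLevel, Policy, normalise
from actinf.inference import InferenceConfig


def make_single_factor_level(A, B, D, T, C=None, policies=None, name="toy"):
    """One-factor, one-modality level from plain matrices.

    A: [n_out, n_states]; B: [n, n] or [n, n, n_act]; D: [n]."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 2:
        B = B[:, :, None]
    D = np.asarray(D, dtype=float)
    n_out = A.shape[0]
    if policies is None:
        policies = [Policy(actions=((0,),))]
    return GenerativeLevel(
        A=[A], B=[B], C=[np.zeros(n_out) if C is None else np.asarray(C, float)],
        D=[D], policies=policies, T=T, name=name)


def enumerate_posterior(A, B, D, obs, actions=None):
    """Brute-force posterior marginals and evidence for a single-factor HMM.

    obs: list of outcome indices (None = unobserved step).
    Returns (marginals [T, n], log_evidence over the observed steps).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if B.ndim == 3:
        B = B[:, :, 0] if actions is None else B
    D = np.asarray(D, float)
    n = D.shape[0]
    T = len(obs)
    post = np.zeros((T, n))
    Z = 0.0
    for seq in itertools.product(range(n), repeat=T):
        p = D[seq[0]]
        if obs[0] is not None:
            p *= A[obs[0], seq[0]]
        for t in range(1, T):
            Bt = B if B.ndim == 2 else B[:, :, actions[t - 1]]
            p *= Bt[seq[t], seq[t - 1]]
            if obs[t] is not None:
                p *= A[obs[t], seq[t]]
        Z += p
        for t in range(T):
            post[t, seq[t]] += p
    return post / Z, float(np.log(Z))


def random_level(rng, n_states=None, T=None, n_out=None):
    """Random fully supported single-factor model."""
    n = int(rng.integers(2, 5)) if n_states is None else n_states
    T = int(rng.integers(2, 4)) if T is None else T
    m = n if n_out is None else n_out
    A = normalise(rng.random((m, n)) + 0.1, axis=0)
    B = normalise(rng.random((n, n)) + 0.1, axis=0)
    D = normalise(rng.random(n) + 0.1, axis=0)
    return make_single_factor_level(A, B, D, T), A, B, D


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def quick_config():
    return InferenceConfig(n_iter=64, update_precision=False)
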