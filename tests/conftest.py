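"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's recursions: likelihoods and
posteriors are computed by exhaustive enumeration over all N^T state paths,
and hourly activity fractions by a 1-second grid count.  They stay
independent of the code paths they check.
"""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest

from socialhmm.hmm import HMMParameters, ObservationSequence


def enum_path_probs(params: HMMParameters, seq: ObservationSequence):
    """(paths, probabilities) by brute force over all N^T paths."""
    A = params.transition_matrices()
    N, T = params.n_states, seq.T
    hidx = (
        seq.hour_of_day
        if params.covariate == "hour_onehot24"
        else np.zeros(seq.T, dtype=int)
    )

    def emit(t, n):
        pr = 1.0
        for c in range(seq.C):
            v = seq.x[t, c]
            if np.isnan(v):
                continue
            pr *= params.phi[n, c] if v == 1.0 else 1.0 - params.phi[n, c]
        return pr

    paths = list(itertools.product(range(N), repeat=T))
    probs = []
    for path in paths:
        pr = params.pi[path[0]] * emit(0, path[0])
        for t in range(1, T):
            pr *= A[hidx[t], path[t - 1], path[t]] * emit(t, path[t])
        probs.append(pr)
    return paths, np.array(probs)


def enum_loglik(params, seq) -> float:
    return float(np.log(enum_path_probs(params, seq)[1].sum()))


def enum_gamma(params, seq) -> np.ndarray:
    """(T, N) posterior state marginals by enumeration."""
    paths, probs = enum_path_probs(params, seq)
    probs = probs / probs.sum()
    gamma = np.zeros((seq.T, params.n_states))
    for path, pr in zip(paths, probs):
        for t, n in enumerate(path):
            gamma[t, n] += pr
    return gamma


def enum_best_path(params, seq):
    """(best path tuple, its joint probability) by enumeration."""
    paths, probs = enum_path_probs(params, seq)
    i = int(np.argmax(probs))
    return paths[i], float(probs[i])


def random_instance(rng, N=None, C=3, T=None, p_missing=0.2, hour_covariate=True):
    """A random (params, sequence) pair small enough for enumeration."""
    N = N or int(rng.integers(2, 4))
    T = T or int(rng.integers(2, 9))
    P = 24 if hour_covariate else 1
    pi = rng.dirichlet(np.ones(N))
    phi = rng.uniform(0.05, 0.95, (N, C))
    beta = rng.normal(0.0, 1.0, (N, N, P))
    beta[:, 0, :] = 0.0
    params = HMMParameters(
        pi=pi, phi=phi, beta=beta,
        covariate="hour_onehot24" if hour_covariate else "none",
    )
    x = rng.integers(0, 2, (T, C)).astype(float)
    if p_missing:
        x[rng.random((T, C)) < p_missing] = np.nan
    seq = ObservationSequence("r", x, rng.integers(0, 24, T))
    return params, seq


def grid_fraction_seconds(intervals, hour_start: datetime) -> float:
    """Union length (seconds) of intervals within [hour_start, +1h) counted
    on a 1-second grid — the independent oracle for hourly fractions."""
    grid = np.zeros(3600, dtype=bool)
    for s, e in intervals:
        lo = max(0, int((s - hour_start).total_seconds()))
        hi = min(3600, int(np.ceil((e - hour_start).total_seconds())))
        # mark whole seconds covered; inputs in tests use whole-second events
        if hi > lo:
            grid[lo:hi] = True
    return float(grid.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def two_state_params():
    from socialhmm.simulate import default_hmm_parameters

    return default_hmm_parameters()
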