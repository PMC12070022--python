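"""Binary-emission hidden Markov model with hour-of-day transition covariates.

The model: a latent behavioural state z_t in {1..N} evolves as a Markov chain
whose transition matrix depends on the hour of day through a multinomial
logistic link,

    A_mn(c_t) = softmax_n( beta[m, n, :] . c_t ),

with c_t the one-hot encoding of the hour (24 columns, no intercept) and
destination state 1 the zero-fixed reference.  Given z_t = n, the C binary
channels are independent Bernoulli draws with success probabilities phi[n, c].
Missing observations (NaN) are marginalised out of the likelihood — a fully
missing timepoint contributes only its transition term — which is what makes
the model usable on passive-sensing data with block missingness.

Fitting is by EM: the E-step is a scaled forward–backward pass (batched over
sequences padded to a common length; padding is transparent because a missing
emission contributes probability 1 and row-stochastic transitions preserve
the scaling); the M-step has closed forms for the starting distribution, the
emission matrix and — because the one-hot hour design separates the
multinomial-logistic objective by hour — for the transition coefficients.
Decoding is by the Viterbi algorithm with ties broken toward the lowest state
index.  States are reported 1-based at the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

N_HOURS = 24
_PHI_FLOOR = 1e-6
_COUNT_SMOOTH = 1e-8


class ModelError(ValueError):
    """Raised on dimensionally or probabilistically invalid model inputs."""


@dataclass
class ObservationSequence:
    """One participant's hourly binary observations with missingness as NaN.

    ``x`` is (T, C) with entries 0.0, 1.0 or NaN; ``hour_of_day`` is (T,) in
    0..23.  The preprocessing pipeline produces all-or-nothing missingness per
    timepoint, but the likelihood supports partial missingness too.
    """

    participant_id: str
    x: np.ndarray
    hour_of_day: np.ndarray
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.hour_of_day = np.asarray(self.hour_of_day, dtype=int)
        if self.x.ndim != 2 or self.x.shape[0] != self.hour_of_day.shape[0]:
            raise ModelError("x must be (T, C) aligned with hour_of_day")
        vals = self.x[~np.isnan(self.x)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ModelError("observations must be 0, 1 or NaN")
        if ((self.hour_of_day < 0) | (self.hour_of_day >= N_HOURS)).any():
            raise ModelError("hour_of_day entries must be in 0..23")

    @property
    def T(self) -> int:
        return self.x.shape[0]

    @property
    def C(self) -> int:
        return self.x.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """True at timepoints where no channel is observed."""
        return np.isnan(self.x).all(axis=1)


def hour_onehot(hour: int) -> np.ndarray:
    v = np.zeros(N_HOURS)
    v[hour] = 1.0
    return v


@dataclass
class HMMParameters:
    """pi (N,), phi (N, C), beta (N, N, P) with beta[:, 0, :] = 0.

    ``covariate`` is ``"hour_onehot24"`` (P = 24) or ``"none"`` (P = 1, a
    single constant column — the homogeneous HMM).
    """

    pi: np.ndarray
    phi: np.ndarray
    beta: np.ndarray
    covariate: str = "hour_onehot24"
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        N = self.pi.shape[0]
        if self.phi.shape[0] != N or self.beta.shape[:2] != (N, N):
            raise ModelError("pi, phi, beta dimensions disagree")
        if self.covariate not in ("hour_onehot24", "none"):
            raise ModelError(f"unknown covariate scheme {self.covariate!r}")
        if self.covariate == "hour_onehot24" and self.beta.shape[2] != N_HOURS:
            raise ModelError("hour covariate requires beta with 24 columns")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi < 0).any():
            raise ModelError("pi must be a probability distribution")
        if ((self.phi < 0) | (self.phi > 1)).any():
            raise ModelError("phi entries must lie in [0, 1]")
        if not np.allclose(self.beta[:, 0, :], 0.0):
            raise ModelError("beta[:, 0, :] must be exactly zero (reference state)")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phi.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[2]

    def transition_matrices(self) -> np.ndarray:
        """(P, N, N) stack of row-stochastic matrices, one per covariate column."""
        scores = np.moveaxis(self.beta, 2, 0)  # (P, N, N)
        scores = scores - scores.max(axis=2, keepdims=True)
        exps = np.exp(scores)
        return exps / exps.sum(axis=2, keepdims=True)


def transition_probs(params: HMMParameters, covariate_row: np.ndarray) -> np.ndarray:
    """Row-stochastic N x N transition matrix for one covariate vector.

    The covariate row must be a valid one-hot vector of length P.
    """
    c = np.asarray(covariate_row, dtype=float)
    if c.shape != (params.n_covariates,) or not (
        np.isin(c, (0.0, 1.0)).all() and c.sum() == 1.0
    ):
        raise ModelError("covariate_row must be one-hot of length P")
    return params.transition_matrices()[int(np.argmax(c))]


def emission_logprob(params: HMMParameters, x_row: np.ndarray) -> np.ndarray:
    """log p(x_t | z_t = n) for each state n; NaN channels contribute 0.

    A phi of exactly 0 or 1 contradicted by the observation yields -inf
    (impossible observation), never an exception.
    """
    x = np.asarray(x_row, dtype=float)
    obs = ~np.isnan(x)
    if not obs.any():
        return np.zeros(params.n_states)
    xo = x[obs]
    with np.errstate(divide="ignore"):
        lp = np.where(
            xo == 1.0, np.log(params.phi[:, obs]), np.log1p(-params.phi[:, obs])
        )
    return lp.sum(axis=1)


def _log_emissions(params: HMMParameters, X: np.ndarray) -> np.ndarray:
    """(..., T, N) log emission probabilities for a (..., T, C) array with NaN."""
    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)
    with np.errstate(divide="ignore"):
        # degenerate phi (exactly 0/1) is mapped to a huge finite penalty so
        # that 0 * log for unobserved channels stays an exact zero
        lp1 = np.maximum(np.log(params.phi), -1e300)  # (N, C)
        lp0 = np.maximum(np.log1p(-params.phi), -1e300)
    # contribution per channel: x*lp1 + (1-x)*lp0, masked to observed entries
    return np.einsum("...tc,nc->...tn", Xf * obs, lp1) + np.einsum(
        "...tc,nc->...tn", (1.0 - Xf) * obs, lp0
    )


def _hour_index(params: HMMParameters, hours: np.ndarray) -> np.ndarray:
    """Map hour-of-day to the covariate column index (0 when homogeneous)."""
    if params.covariate == "hour_onehot24":
        return hours
    return np.zeros_like(hours)


def _batch(sequences: list[ObservationSequence]):
    """Pad sequences to a common length; padding is all-missing observations."""
    S = len(sequences)
    Tmax = max(s.T for s in sequences)
    C = sequences[0].C
    X = np.full((S, Tmax, C), np.nan)
    hours = np.zeros((S, Tmax), dtype=int)
    lengths = np.zeros(S, dtype=int)
    for i, s in enumerate(sequences):
        if s.C != C:
            raise ModelError("sequences have inconsistent channel counts")
        X[i, : s.T] = s.x
        hours[i, : s.T] = s.hour_of_day
        lengths[i] = s.T
    return X, hours, lengths


def _forward(params, X, hours, lengths):
    """Scaled forward pass.  Returns alphas (S,T,N), log-scales (S,T), logliks (S,)."""
    S, T, _ = X.shape
    N = params.n_states
    A = params.transition_matrices()  # (P, N, N)
    h = _hour_index(params, hours)
    logB = _log_emissions(params, X)  # (S, T, N)
    alphas = np.zeros((S, T, N))
    logc = np.zeros((S, T))
    shift = logB[:, 0, :].max(axis=1, initial=-np.inf)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    a = params.pi[None, :] * np.exp(logB[:, 0, :] - shift[:, None])
    c = a.sum(axis=1)
    if (c <= 0).any():
        raise ModelError("zero-probability observation at t=0")
    alphas[:, 0] = a / c[:, None]
    logc[:, 0] = np.log(c) + shift
    for t in range(1, T):
        At = A[h[:, t]]  # (S, N, N)
        pred = np.einsum("sm,smn->sn", alphas[:, t - 1], At)
        shift = logB[:, t, :].max(axis=1)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        a = pred * np.exp(logB[:, t, :] - shift[:, None])
        c = a.sum(axis=1)
        if (c <= 0).any():
            raise ModelError(f"zero-probability observation at t={t}")
        alphas[:, t] = a / c[:, None]
        logc[:, t] = np.log(c) + shift
    # padded steps contribute log 1 = 0 by construction; mask anyway for safety
    tidx = np.arange(T)[None, :]
    logliks = np.where(tidx < lengths[:, None], logc, 0.0).sum(axis=1)
    return alphas, logc, logliks, logB, A, h


def forward_loglik(params: HMMParameters, seq: ObservationSequence) -> float:
    """Marginal log-likelihood log p(x_{1..T}) by the scaled forward recursion."""
    _check_dims(params, seq)
    X, hours, lengths = _batch([seq])
    return float(_forward(params, X, hours, lengths)[2][0])


def _check_dims(params: HMMParameters, seq: ObservationSequence) -> None:
    if seq.C != params.n_channels:
        raise ModelError(
            f"sequence has {seq.C} channels but model expects {params.n_channels}"
        )


def forward_backward(params: HMMParameters, seq: ObservationSequence):
    """Posterior state marginals gamma (T, N) and transition posteriors
    xi (T-1, N, N), with xi[t] = p(z_t = m, z_{t+1} = n | x)."""
    _check_dims(params, seq)
    X, hours, lengths = _batch([seq])
    gamma, xi_by_step = _forward_backward_full(params, X, hours, lengths)
    return gamma[0], xi_by_step[0]


def _forward_backward_full(params, X, hours, lengths):
    """Batched forward-backward returning per-step gamma and xi (for tests /
    single sequences).  EM uses the accumulating variant below instead."""
    alphas, logc, _, logB, A, h = _forward(params, X, hours, lengths)
    S, T, _ = X.shape
    N = params.n_states
    gamma = np.zeros((S, T, N))
    xi = np.zeros((S, max(T - 1, 0), N, N))
    b = np.ones((S, N))
    gamma[:, T - 1] = alphas[:, T - 1] * b
    for t in range(T - 2, -1, -1):
        At = A[h[:, t + 1]]
        shift = logB[:, t + 1, :].max(axis=1)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        Bb = np.exp(logB[:, t + 1, :] - shift[:, None]) * b  # (S, N)
        joint = alphas[:, t, :, None] * At * Bb[:, None, :]
        denom = joint.sum(axis=(1, 2), keepdims=True)
        xi[:, t] = joint / denom
        b = np.einsum("smn,sn->sm", At, Bb)
        b = b / b.sum(axis=1, keepdims=True) * N  # rescale, keep relative sizes
        g = alphas[:, t] * b
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    return gamma, xi


@dataclass
class FitResult:
    """EM fitting output: parameters plus diagnostics."""

    params: HMMParameters
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_obs_used: int
    seed: int | None = None

    @property
    def bic(self) -> float:
        return bic(self)


def n_free_parameters(params: HMMParameters) -> int:
    """(N-1) starting + N*C emission + N*(N-1)*P transition coefficients."""
    N, C, P = params.n_states, params.n_channels, params.n_covariates
    return (N - 1) + N * C + N * (N - 1) * P


def bic(fit: FitResult) -> float:
    """-2 logL + k log(n), with n the number of non-missing timepoints used."""
    k = n_free_parameters(fit.params)
    return -2.0 * fit.loglik + k * np.log(fit.n_obs_used)


def _m_step(params, X, hours, lengths, alphas, logc, logB, A, h):
    """One EM M-step; returns updated parameters.

    gamma/xi are accumulated on the fly during the backward pass to avoid
    storing (S, T, N, N) arrays.
    """
    S, T, C = X.shape
    N = params.n_states
    P = params.n_covariates
    tvalid = np.arange(T)[None, :] < lengths[:, None]  # (S, T)

    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)
    phi_num = np.zeros((N, C))
    phi_den = np.zeros((N, C))
    xi_counts = np.zeros((P, N, N))
    pi_acc = np.zeros(N)

    b = np.ones((S, N))
    g_last = alphas[:, T - 1] * b
    g_last /= g_last.sum(axis=1, keepdims=True)
    w = g_last * tvalid[:, T - 1 : T]
    phi_num += np.einsum("sn,sc->nc", w, Xf[:, T - 1] * obs[:, T - 1])
    phi_den += np.einsum("sn,sc->nc", w, obs[:, T - 1].astype(float))
    if T == 1:
        pi_acc += g_last.sum(axis=0)
    for t in range(T - 2, -1, -1):
        At = A[h[:, t + 1]]
        shift = logB[:, t + 1, :].max(axis=1)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        Bb = np.exp(logB[:, t + 1, :] - shift[:, None]) * b
        joint = alphas[:, t, :, None] * At * Bb[:, None, :]
        denom = joint.sum(axis=(1, 2))
        joint /= denom[:, None, None]
        # transitions into t+1 only count where t+1 is inside the sequence
        valid = tvalid[:, t + 1]
        if params.covariate == "hour_onehot24":
            np.add.at(xi_counts, h[:, t + 1][valid], joint[valid])
        else:
            xi_counts[0] += joint[valid].sum(axis=0)
        b = np.einsum("smn,sn->sm", At, Bb)
        b = b / b.sum(axis=1, keepdims=True) * N
        g = alphas[:, t] * b
        g /= g.sum(axis=1, keepdims=True)
        w = g * tvalid[:, t : t + 1]
        phi_num += np.einsum("sn,sc->nc", w, Xf[:, t] * obs[:, t])
        phi_den += np.einsum("sn,sc->nc", w, obs[:, t].astype(float))
        if t == 0:
            pi_acc += g.sum(axis=0)

    pi = pi_acc / pi_acc.sum()
    phi = np.where(phi_den > 0, phi_num / np.maximum(phi_den, 1e-300), params.phi)
    phi = np.clip(phi, _PHI_FLOOR, 1.0 - _PHI_FLOOR)
    # closed-form multinomial-logistic M-step: the one-hot design separates by
    # covariate column, so beta[m, n, p] = log(W[p,m,n] / W[p,m,0])
    W = xi_counts + _COUNT_SMOOTH
    beta = np.log(W) - np.log(W[:, :, 0:1])
    beta = np.moveaxis(beta, 0, 2)  # (N, N, P)
    return HMMParameters(
        pi=pi, phi=phi, beta=beta, covariate=params.covariate, channels=params.channels
    )


def _init_params(rng, n_states, C, covariate, channels, X):
    """Starting point: uniform-plus-jitter pi, channel means with state
    offsets for phi, zero beta."""
    N = n_states
    pi = np.full(N, 1.0 / N) + 0.1 * (rng.dirichlet(np.ones(N)) - 1.0 / N)
    pi = pi / pi.sum()
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=(0, 1))
    means = np.where(np.isnan(means), 0.5, means)
    offsets = np.linspace(-0.2, 0.2, N)[:, None] + rng.normal(0, 0.05, size=(N, len(means)))
    phi = np.clip(means[None, :] + offsets, 0.05, 0.95)
    P = N_HOURS if covariate == "hour_onehot24" else 1
    beta = np.zeros((N, N, P))
    return HMMParameters(pi=pi, phi=phi, beta=beta, covariate=covariate, channels=channels)


def _canonical_order(params: HMMParameters, order_channel: int) -> HMMParameters:
    """Relabel states by ascending emission probability of one channel (by
    default the last, overall phone usage) so state 1 is the inactive state."""
    order = np.argsort(params.phi[:, order_channel], kind="stable")
    if (order == np.arange(params.n_states)).all():
        return params
    scores = params.beta[np.ix_(order, order)]
    scores = scores - scores[:, 0:1, :]  # re-zero the new reference destination
    return HMMParameters(
        pi=params.pi[order],
        phi=params.phi[order],
        beta=scores,
        covariate=params.covariate,
        channels=params.channels,
    )


def em_fit(
    sequences: list[ObservationSequence],
    n_states: int,
    use_hour_covariate: bool = True,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_params: HMMParameters | None = None,
    order_channel: int | None = -1,
) -> FitResult:
    """Fit by EM with random restarts; the best final log-likelihood wins.

    ``init_params`` bypasses random initialisation (then a single start is
    run).  ``order_channel`` selects the emission column used to put states in
    canonical ascending order after fitting (None disables relabelling).
    """
    if n_states < 1:
        raise ModelError("n_states must be >= 1")
    if not sequences:
        raise ModelError("at least one sequence is required")
    X, hours, lengths = _batch(sequences)
    tvalid = np.arange(X.shape[1])[None, :] < lengths[:, None]
    n_obs = int((~np.isnan(X).all(axis=2) & tvalid).sum())
    if n_obs == 0:
        raise ModelError("all timepoints are missing in all sequences")
    covariate = "hour_onehot24" if use_hour_covariate else "none"
    channels = sequences[0].channels
    C = sequences[0].C
    rng = np.random.default_rng(seed)

    best: FitResult | None = None
    starts = 1 if init_params is not None else max(1, n_restarts)
    for _ in range(starts):
        params = (
            init_params
            if init_params is not None
            else _init_params(rng, n_states, C, covariate, channels, X)
        )
        trace = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            alphas, logc, logliks, logB, A, h = _forward(params, X, hours, lengths)
            ll = float(logliks.sum())
            trace.append(ll)
            if np.isfinite(prev) and ll - prev < tol * abs(prev):
                converged = True
                break
            prev = ll
            if n_states == 1:
                # closed form: single state, independent Bernoulli channels
                obs = ~np.isnan(X) & tvalid[:, :, None]
                phi = np.where(
                    obs.sum(axis=(0, 1)) > 0,
                    np.nansum(np.where(obs, X, 0.0), axis=(0, 1))
                    / np.maximum(obs.sum(axis=(0, 1)), 1),
                    0.5,
                )
                params = HMMParameters(
                    pi=np.ones(1),
                    phi=np.clip(phi[None, :], _PHI_FLOOR, 1 - _PHI_FLOOR),
                    beta=np.zeros((1, 1, params.n_covariates)),
                    covariate=covariate,
                    channels=channels,
                )
                continue
            params = _m_step(params, X, hours, lengths, alphas, logc, logB, A, h)
        result = FitResult(
            params=params,
            loglik=trace[-1],
            loglik_trace=np.array(trace),
            converged=converged,
            n_iter=len(trace),
            n_obs_used=n_obs,
            seed=seed,
        )
        if best is None or result.loglik > best.loglik:
            best = result
    assert best is not None
    if order_channel is not None and best.params.n_states > 1:
        best.params = _canonical_order(best.params, order_channel)
    return best


def viterbi(params: HMMParameters, seq: ObservationSequence):
    """Most probable state path (StatePath, 1-based states).

    At fully missing timepoints the emission term is absent, so decoding is
    driven by the transition structure alone.  Ties break toward the lowest
    state index.
    """
    from .phenotype import StatePath

    _check_dims(params, seq)
    T, N = seq.T, params.n_states
    logB = _log_emissions(params, seq.x[None])[0]  # (T, N)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrices())  # (P, N, N)
        logpi = np.log(params.pi)
    h = _hour_index(params, seq.hour_of_day)
    delta = logpi + logB[0]
    psi = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA[h[t]]  # (m, n)
        psi[t] = scores.argmax(axis=0)  # first max -> lowest origin index
        delta = scores[psi[t], np.arange(N)] + logB[t]
    states = np.zeros(T, dtype=int)
    states[T - 1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    return StatePath(
        participant_id=seq.participant_id,
        states=states + 1,
        missing_mask=seq.missing_mask,
    )


def select_n_states(
    sequences, candidates=(2, 3, 4), use_hour_covariate=True, seed=None, **kwargs
):
    """Fit each candidate state count and return (fits, best_n) by BIC."""
    fits = {}
    rng = np.random.default_rng(seed)
    for n in candidates:
        fits[n] = em_fit(
            sequences,
            n_states=n,
            use_hour_covariate=use_hour_covariate,
            seed=int(rng.integers(2**31 - 1)),
            **kwargs,
        )
    best = min(fits, key=lambda n: fits[n].bic)
    return fits, best
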