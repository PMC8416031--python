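"""Linear-chain conditional random field over the five sleep stages.

A night of T epochs gets an emission score matrix E (T x 5) from the encoder.
The CRF adds a learned transition score A[i, j] for staging epoch t as j when
epoch t-1 was i, plus start/end scores, and scores a whole-night labelling y as

    score(y) = start[y_0] + sum_t w[y_t] * E[t, y_t]
             + sum_t A[y_{t-1}, y_t] + end[y_{T-1}]

Class weights w (one positive real per stage, default all ones) counteract
stage imbalance. The training loss used by the estimator weights the gold
path's emission term only:

    L_w = logZ(E) - [start[y_0] + sum_t w[y_t] E[t, y_t]
                     + sum_t A[y_{t-1}, y_t] + end[y_{T-1}]]

so its emission gradient is P(y_t = k) - w[y_t] 1{k = y_t}: epochs of an
upweighted rare stage push their stage's score up w times harder, raising
that stage's recall at (unweighted) Viterbi decoding. Unit weights reduce
exactly to the standard CRF negative log-likelihood. The alternative
"reweighted emission table" formulation (every path scored with its own
labels' weighted emissions, functions below accepting ``weights``) is also
provided; it shares the unit-weight reduction but, trained and then decoded
without weights, it suppresses rather than boosts the rare stage, so the
estimator does not use it.

All sums over the 5^T candidate paths are computed with the forward recursion
in log space; the brute-force enumeration equivalent is kept in the test suite
as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .stages import N_STAGES

__all__ = [
    "CrfParams",
    "path_score",
    "log_partition",
    "nll_loss",
    "forward_backward",
    "viterbi",
    "crf_gradients",
    "class_weighted_nll",
    "class_weighted_gradients",
]


@dataclass
class CrfParams:
    """Transition structure of the chain.

    Attributes
    ----------
    transitions : (5, 5) array
        ``transitions[i, j]`` is the score of moving from stage i to stage j.
    start, end : (5,) arrays
        Scores for the first and last stage of a night.
    """

    transitions: np.ndarray = field(
        default_factory=lambda: np.zeros((N_STAGES, N_STAGES))
    )
    start: np.ndarray = field(default_factory=lambda: np.zeros(N_STAGES))
    end: np.ndarray = field(default_factory=lambda: np.zeros(N_STAGES))

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.transitions.shape != (N_STAGES, N_STAGES):
            raise ValueError(
                f"transition matrix must be {N_STAGES}x{N_STAGES}, "
                f"got {self.transitions.shape}"
            )
        if self.start.shape != (N_STAGES,) or self.end.shape != (N_STAGES,):
            raise ValueError("start/end score vectors must have length 5")
        for arr in (self.transitions, self.start, self.end):
            if not np.all(np.isfinite(arr)):
                raise ValueError("CRF parameters must be finite")


def _check_emissions(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] != N_STAGES:
        raise ValueError(f"emission matrix must be (T, {N_STAGES}), got {E.shape}")
    if E.shape[0] < 1:
        raise ValueError("emission matrix needs at least one epoch")
    return E


def _check_weights(weights) -> np.ndarray:
    if weights is None:
        return np.ones(N_STAGES)
    w = np.asarray(weights, dtype=float)
    if w.shape != (N_STAGES,):
        raise ValueError(f"class weights must have length {N_STAGES}")
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return w


def path_score(E, y, params: CrfParams, weights=None) -> float:
    """Score of one complete labelling y (length T) of a night."""
    E = _check_emissions(E)
    w = _check_weights(weights)
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (E.shape[0],):
        raise ValueError("label sequence length must match number of epochs")
    if y.min() < 0 or y.max() >= N_STAGES:
        raise ValueError("stage indices must lie in 0-4")
    score = params.start[y[0]] + params.end[y[-1]]
    score += float(np.sum(w[y] * E[np.arange(len(y)), y]))
    if len(y) > 1:
        score += float(np.sum(params.transitions[y[:-1], y[1:]]))
    return float(score)


def _weighted(E: np.ndarray, w: np.ndarray) -> np.ndarray:
    return E * w[None, :]


def log_partition(E, params: CrfParams, weights=None) -> float:
    """log sum over all 5^T paths of exp(path score), by the forward recursion."""
    E = _check_emissions(E)
    w = _check_weights(weights)
    Ew = _weighted(E, w)
    alpha = params.start + Ew[0]
    for t in range(1, E.shape[0]):
        # alpha[j] = logsumexp_i(alpha[i] + A[i, j]) + Ew[t, j]
        alpha = logsumexp(alpha[:, None] + params.transitions, axis=0) + Ew[t]
    return float(logsumexp(alpha + params.end))


def nll_loss(E, y, params: CrfParams, weights=None) -> float:
    """Negative log-likelihood of the gold labelling under the (weighted) CRF."""
    return log_partition(E, params, weights) - path_score(E, y, params, weights)


def forward_backward(E, params: CrfParams, weights=None):
    """Posterior stage marginals and pairwise transition marginals.

    Returns
    -------
    gamma : (T, 5) array
        ``gamma[t, k] = P(y_t = k)``; rows sum to 1.
    xi : (5, 5) array
        Expected transition counts summed over t: ``xi[i, j] =
        sum_t P(y_{t-1} = i, y_t = j)``. Zero matrix when T == 1.
    logZ : float
    """
    E = _check_emissions(E)
    w = _check_weights(weights)
    Ew = _weighted(E, w)
    T = E.shape[0]
    A = params.transitions

    log_alpha = np.empty((T, N_STAGES))
    log_alpha[0] = params.start + Ew[0]
    for t in range(1, T):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + A, axis=0) + Ew[t]

    log_beta = np.empty((T, N_STAGES))
    log_beta[-1] = params.end
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(A + (Ew[t + 1] + log_beta[t + 1])[None, :], axis=1)

    logZ = float(logsumexp(log_alpha[-1] + params.end))
    gamma = np.exp(log_alpha + log_beta - logZ)
    gamma /= gamma.sum(axis=1, keepdims=True)  # wash out residual round-off

    xi = np.zeros((N_STAGES, N_STAGES))
    for t in range(1, T):
        log_xi_t = (
            log_alpha[t - 1][:, None]
            + A
            + (Ew[t] + log_beta[t])[None, :]
            - logZ
        )
        xi += np.exp(log_xi_t)
    return gamma, xi, logZ


def viterbi(E, params: CrfParams):
    """Best-scoring stage sequence and its score (unweighted emissions).

    Ties are broken toward the lower stage index (W before N1, ...).
    """
    E = _check_emissions(E)
    T = E.shape[0]
    A = params.transitions

    delta = params.start + E[0]
    backptr = np.empty((T, N_STAGES), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + A  # cand[i, j]
        backptr[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[backptr[t], np.arange(N_STAGES)] + E[t]
    delta = delta + params.end

    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return path, float(delta[path[-1]])


def crf_gradients(E, y, params: CrfParams, weights=None):
    """Gradients of :func:`nll_loss` w.r.t. emissions and CRF parameters.

    Returns ``(dE, dA, dstart, dend, loss)``. The emission gradient is
    ``w[k] * (P'(y_t = k) - 1{y_t = k})`` where P' is the posterior under the
    reweighted emission table; transition/start/end gradients are expected
    minus empirical counts.
    """
    E = _check_emissions(E)
    w = _check_weights(weights)
    y = np.asarray(y, dtype=np.int64)
    T = E.shape[0]

    gamma, xi, logZ = forward_backward(E, params, weights)
    loss = logZ - path_score(E, y, params, weights)

    dE = gamma.copy()
    dE[np.arange(T), y] -= 1.0
    dE *= w[None, :]

    dA = xi
    if T > 1:
        np.subtract.at(dA, (y[:-1], y[1:]), 1.0)

    dstart = gamma[0].copy()
    dstart[y[0]] -= 1.0
    dend = gamma[-1].copy()
    dend[y[-1]] -= 1.0
    return dE, dA, dstart, dend, float(loss)


def class_weighted_nll(E, y, params: CrfParams, weights=None) -> float:
    """Training loss: unweighted log-partition minus the w-weighted gold score."""
    return log_partition(E, params) - path_score(E, y, params, weights)


def class_weighted_gradients(E, y, params: CrfParams, weights=None):
    """Gradients of :func:`class_weighted_nll`.

    Returns ``(dE, dA, dstart, dend, loss)`` with
    ``dE[t, k] = P(y_t = k) - w[y_t] * 1{y_t = k}`` under the unweighted
    posterior; transition/start/end gradients are expected minus empirical
    counts as in the standard CRF.
    """
    E = _check_emissions(E)
    w = _check_weights(weights)
    y = np.asarray(y, dtype=np.int64)
    T = E.shape[0]

    gamma, xi, logZ = forward_backward(E, params)
    loss = logZ - path_score(E, y, params, w)

    dE = gamma.copy()
    dE[np.arange(T), y] -= w[y]

    dA = xi
    if T > 1:
        np.subtract.at(dA, (y[:-1], y[1:]), 1.0)

    dstart = gamma[0].copy()
    dstart[y[0]] -= 1.0
    dend = gamma[-1].copy()
    dend[y[-1]] -= 1.0
    return dE, dA, dstart, dend, float(loss)
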