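"""Two-state Gaussian hidden Markov model: forward likelihood and Baum-Welch.

The baseline week's valid (breathing rate, inspiratory amplitude) series is
modeled as a 2-state HMM with diagonal-covariance Gaussian emissions: the
patient alternates between two latent respiratory regimes (e.g. restful vs.
active breathing) according to per-slot transition probabilities.  Sequences
are split at every missing 5-minute slot; segments are treated as independent
realisations, each restarting from the initial state distribution.

Numerics: the forward and backward recursions use per-step normalisation
(scaling constants accumulate the log-likelihood), emission densities are
evaluated in log space, and variances are floored.  Training is standard
multi-sequence Baum-Welch (EM), initialised from a seeded 2-means partition of
the pooled samples; the total log-likelihood is non-decreasing across
iterations up to floor effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TINY = 1e-300


@dataclass
class HmmParams:
    """Parameters of a K-state diagonal-Gaussian HMM over d variables."""

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K), row-stochastic
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d), diagonal covariances

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    def permuted(self, order) -> "HmmParams":
        """Same model with hidden states relabeled."""
        order = list(order)
        return HmmParams(
            startprob=self.startprob[order],
            transmat=self.transmat[np.ix_(order, order)],
            means=self.means[order],
            variances=self.variances[order],
        )


def _log_emission(params: HmmParams, obs: np.ndarray) -> np.ndarray:
    """(T, K) log N(obs_t; mean_k, diag var_k)."""
    obs = np.atleast_2d(obs)
    diff = obs[:, None, :] - params.means[None, :, :]
    return -0.5 * (
        np.sum(diff * diff / params.variances[None], axis=2)
        + np.sum(np.log(2 * np.pi * params.variances), axis=1)[None, :]
    )


def _forward(params: HmmParams, log_b: np.ndarray):
    """Scaled forward pass. Returns (alpha_hat, log c_t) with alpha rows summing to 1."""
    T, K = log_b.shape
    b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
    log_shift = log_b.max(axis=1)
    alpha = np.empty((T, K))
    logc = np.empty(T)
    a = params.startprob * b[0]
    s = a.sum()
    alpha[0] = a / max(s, _TINY)
    logc[0] = np.log(max(s, _TINY)) + log_shift[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.transmat) * b[t]
        s = a.sum()
        alpha[t] = a / max(s, _TINY)
        logc[t] = np.log(max(s, _TINY)) + log_shift[t]
    return alpha, logc


def _backward(params: HmmParams, log_b: np.ndarray) -> np.ndarray:
    """Scaled backward pass (each row normalised to sum 1)."""
    T, K = log_b.shape
    b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
    beta = np.empty((T, K))
    beta[-1] = 1.0 / K
    for t in range(T - 2, -1, -1):
        v = params.transmat @ (b[t + 1] * beta[t + 1])
        beta[t] = v / max(v.sum(), _TINY)
    return beta


def forward_loglik(params: HmmParams, segments: list[np.ndarray]) -> float:
    """Total log-likelihood of independent observation segments.

    Each segment restarts from the initial state distribution; independent
    segments contribute additively.
    """
    segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    segments = [s for s in segments if s.shape[0] > 0]
    if not segments:
        raise ValueError("need at least one non-empty segment")
    total = 0.0
    for seg in segments:
        _, logc = _forward(params, _log_emission(params, seg))
        total += float(logc.sum())
    return total


def kmeans_init(
    samples: np.ndarray,
    n_states: int,
    rng: np.random.Generator,
    var_floor: float,
) -> HmmParams:
    """Seeded k-means initialisation for Baum-Welch."""
    from sklearn.cluster import KMeans

    samples = np.atleast_2d(samples)
    km = KMeans(
        n_clusters=n_states,
        n_init=5,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(samples)
    means = km.cluster_centers_
    variances = np.empty_like(means)
    for k in range(n_states):
        pts = samples[km.labels_ == k]
        variances[k] = pts.var(axis=0) if len(pts) > 1 else samples.var(axis=0)
    variances = np.maximum(variances, var_floor)
    transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.9)
    return HmmParams(
        startprob=np.full(n_states, 1.0 / n_states),
        transmat=transmat,
        means=means,
        variances=variances,
    )


def baum_welch(
    segments: list[np.ndarray],
    init: HmmParams,
    max_iter: int = 200,
    tol: float = 1e-6,
    var_floor: float = 1e-4,
) -> tuple[HmmParams, list[float]]:
    """Multi-sequence EM for a diagonal-Gaussian HMM.

    Stops when the total log-likelihood improves by less than ``tol`` (or
    after ``max_iter`` iterations).  Returns the fitted parameters and the
    per-iteration log-likelihood history (non-decreasing up to variance-floor
    projections).
    """
    segs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    segs = [s for s in segs if s.shape[0] > 0]
    if not segs:
        raise ValueError("need at least one non-empty segment")
    params = init
    history: list[float] = []
    for _ in range(max_iter):
        K = params.n_states
        d = segs[0].shape[1]
        loglik = 0.0
        start_acc = np.zeros(K)
        trans_num = np.zeros((K, K))
        gamma_sum = np.zeros(K)
        mean_num = np.zeros((K, d))
        sq_num = np.zeros((K, d))
        for seg in segs:
            log_b = _log_emission(params, seg)
            alpha, logc = _forward(params, log_b)
            beta = _backward(params, log_b)
            loglik += float(logc.sum())
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), _TINY)
            start_acc += gamma[0]
            b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
            if seg.shape[0] > 1:
                # xi_t(i,j) ∝ alpha_t(i) A(i,j) b_{t+1}(j) beta_{t+1}(j);
                # per-t scaling constants cancel in the normalisation
                xi = (
                    alpha[:-1, :, None]
                    * params.transmat[None]
                    * (b[1:] * beta[1:])[:, None, :]
                )
                xi /= np.maximum(xi.sum(axis=(1, 2), keepdims=True), _TINY)
                trans_num += xi.sum(axis=0)
            gamma_sum += gamma.sum(axis=0)
            mean_num += gamma.T @ seg
            sq_num += gamma.T @ (seg * seg)
        history.append(loglik)

        denom = np.maximum(gamma_sum, _TINY)[:, None]
        new_means = mean_num / denom
        new_vars = np.maximum(sq_num / denom - new_means**2, var_floor)
        row = np.maximum(trans_num.sum(axis=1, keepdims=True), _TINY)
        params = HmmParams(
            startprob=start_acc / start_acc.sum(),
            transmat=trans_num / row,
            means=new_means,
            variances=new_vars,
        )
        if len(history) >= 2 and history[-1] - history[-2] < tol:
            break
    return params, history
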