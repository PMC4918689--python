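"""Product hidden Markov model over a Cartesian +/-1 state space.

A product HMM couples K two-state channels -- here, the "correlated" (+1)
and "anti-correlated" (-1) regimes of K windowed-correlation series -- into
a single HMM whose hidden state space is the Cartesian product
S = {-1, +1}^K, of cardinality M = 2^K.  The full M x M transition matrix A
captures the joint dynamics of the channels; emissions factorize across
channels as univariate Gaussians conditioned on each channel's sub-state,

    b_j(Y_t) = prod_k N(Y_t^k ; mu_{j^k}, sigma_{j^k}),

so the joint emission of state j is a diagonal-covariance Gaussian whose
mean vector is read off j's sub-states.

Conventions fixed here (so transition matrices are comparable across runs):
channel 0 is the most significant bit of the joint state index, and
sub-state +1 maps to bit 1.  State labels follow the field's case
convention -- channel name upper-case when correlated, lower-case when
anti-correlated, e.g. ``OPFN-rfpn-lfpn-OPN-DMN-bg``.

Numerics: per-step scaled forward/backward recursions; log-space Viterbi
with ties broken toward the lower state index; variance floor 1e-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "VARIANCE_FLOOR",
    "EmissionParams",
    "ProductHMMModel",
    "StateSequence",
    "FitResult",
    "state_bits",
    "index_to_substates",
    "substates_to_index",
    "state_label",
    "label_to_substates",
    "init_parameters",
    "log_likelihood",
    "log_likelihood_backward",
    "baum_welch_fit",
    "viterbi_decode",
    "generate_observations",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-3  # lower bound on emission sigma


# ---------------------------------------------------------------------------
# Joint-state indexing


def state_bits(k: int) -> np.ndarray:
    """(2^K, K) matrix of bits; channel 0 is the most significant bit."""
    idx = np.arange(2 ** k)
    return (idx[:, None] >> (k - 1 - np.arange(k))) & 1


def index_to_substates(index: int, k: int) -> np.ndarray:
    """Joint state index -> length-K vector over {-1, +1}."""
    if not 0 <= index < 2 ** k:
        raise ValueError(f"state index {index} out of range for K={k}")
    bits = (index >> (k - 1 - np.arange(k))) & 1
    return 2 * bits - 1


def substates_to_index(substates: np.ndarray) -> int:
    """Length-K vector over {-1, +1} -> joint state index."""
    s = np.asarray(substates)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("substates must be -1 or +1")
    bits = (s + 1) // 2
    k = len(s)
    return int((bits << (k - 1 - np.arange(k))).sum())


def state_label(index: int, channel_names: list[str] | None = None,
                k: int | None = None, sep: str = "-") -> str:
    """Render a joint state in the case convention (upper = correlated)."""
    if channel_names is None:
        if k is None:
            raise ValueError("need channel_names or k")
        channel_names = [f"ch{i + 1}" for i in range(k)]
    sub = index_to_substates(index, len(channel_names))
    return sep.join(name.upper() if s == 1 else name.lower()
                    for name, s in zip(channel_names, sub))


def label_to_substates(label: str, sep: str = "-") -> np.ndarray:
    """Inverse of :func:`state_label` (case -> sub-state; names discarded)."""
    parts = label.split(sep)
    out = np.empty(len(parts), dtype=int)
    for i, p in enumerate(parts):
        if p.isupper():
            out[i] = 1
        elif p.islower():
            out[i] = -1
        else:
            raise ValueError(f"mixed-case channel name {p!r} in state label")
    return out


# ---------------------------------------------------------------------------
# Model containers


@dataclass
class EmissionParams:
    """Per-channel two-component Gaussian emission table.

    ``means``/``stds`` have shape (K, 2): column 0 is the anti-correlated
    sub-state (-1), column 1 the correlated sub-state (+1).  Invariants:
    sigma >= VARIANCE_FLOOR and mu_{+1} >= mu_{-1} on every channel.
    """

    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if self.means.shape != self.stds.shape or self.means.ndim != 2 \
                or self.means.shape[1] != 2:
            raise ValueError("means/stds must both have shape (K, 2)")
        if np.any(self.stds < VARIANCE_FLOOR):
            raise ValueError(f"emission stds must be >= {VARIANCE_FLOOR}")
        if np.any(self.means[:, 1] < self.means[:, 0]):
            raise ValueError("mu_{+1} must be >= mu_{-1} on every channel")

    @property
    def k(self) -> int:
        return self.means.shape[0]


@dataclass
class ProductHMMModel:
    """lambda = (Pi, A, B): a product HMM over 2^K joint states."""

    k: int
    startprob: np.ndarray
    transmat: np.ndarray
    emissions: EmissionParams
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = 2 ** self.k
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if self.startprob.shape != (m,):
            raise ValueError(f"startprob must have length {m}")
        if self.transmat.shape != (m, m):
            raise ValueError(f"transmat must be {m}x{m}")
        if self.emissions.k != self.k:
            raise ValueError("emission table does not match K")
        if np.any(self.startprob < 0) or np.any(self.transmat < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.startprob.sum() - 1.0) > 1e-10:
            raise ValueError("startprob must sum to 1")
        if np.max(np.abs(self.transmat.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("every transmat row must sum to 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.k)]
        elif len(self.channel_names) != self.k:
            raise ValueError("channel_names must have length K")

    @property
    def n_states(self) -> int:
        return 2 ** self.k

    def state_label(self, index: int) -> str:
        return state_label(index, self.channel_names)

    # joint-Gaussian view of the factored emissions: state-wise mean vectors
    # and diagonal variances on the 2^K space
    def joint_means(self) -> np.ndarray:
        bits = state_bits(self.k)
        return np.where(bits == 1, self.emissions.means[:, 1],
                        self.emissions.means[:, 0])

    def joint_stds(self) -> np.ndarray:
        bits = state_bits(self.k)
        return np.where(bits == 1, self.emissions.stds[:, 1],
                        self.emissions.stds[:, 0])

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "bit_order": "channel 0 = most significant bit; +1 -> bit 1",
            "channel_names": list(self.channel_names),
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emission_means": self.emissions.means.tolist(),
            "emission_stds": self.emissions.stds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProductHMMModel":
        return cls(
            k=int(d["k"]),
            startprob=np.array(d["startprob"], dtype=float),
            transmat=np.array(d["transmat"], dtype=float),
            emissions=EmissionParams(np.array(d["emission_means"], dtype=float),
                                     np.array(d["emission_stds"], dtype=float)),
            channel_names=list(d["channel_names"]),
        )


@dataclass
class StateSequence:
    """A joint-state path with its per-channel expansion and log-probability."""

    joint: np.ndarray
    per_channel: np.ndarray
    log_prob: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=int)
        self.per_channel = np.asarray(self.per_channel, dtype=int)
        k, t = self.per_channel.shape
        if self.joint.shape != (t,):
            raise ValueError("joint and per_channel lengths disagree")
        expected = np.stack([index_to_substates(i, k) for i in self.joint], axis=1)
        if not np.array_equal(expected, self.per_channel):
            raise ValueError("per_channel is not the sub-state expansion of joint")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(k)]

    @classmethod
    def from_joint(cls, joint: np.ndarray, k: int, log_prob: float,
                   channel_names: list[str] | None = None) -> "StateSequence":
        joint = np.asarray(joint, dtype=int)
        per_channel = np.stack([index_to_substates(i, k) for i in joint], axis=1)
        return cls(joint=joint, per_channel=per_channel, log_prob=float(log_prob),
                   channel_names=channel_names or [])

    def labels(self) -> list[str]:
        return [state_label(i, self.channel_names) for i in self.joint]

    def __len__(self) -> int:
        return len(self.joint)


@dataclass
class FitResult:
    model: ProductHMMModel
    log_likelihoods: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# Likelihood machinery


def _as_obs(values: np.ndarray, k: int | None = None) -> np.ndarray:
    obs = np.asarray(values, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observations must be a (K, T) matrix")
    if k is not None and obs.shape[0] != k:
        raise ValueError(f"observation channel count {obs.shape[0]} != model K {k}")
    if not np.isfinite(obs).all():
        raise ValueError("observations contain non-finite values")
    return obs


def _joint_log_emissions(model: ProductHMMModel, obs: np.ndarray) -> np.ndarray:
    """(2^K, T) matrix of log b_j(Y_t) = sum_k log N(Y_t^k; mu_{j^k}, sigma_{j^k})."""
    mu = model.emissions.means  # (K, 2)
    sd = model.emissions.stds
    # lp[k, s, t]: channel-k log density under sub-state s (0 -> -1, 1 -> +1)
    lp = norm.logpdf(obs[:, None, :], loc=mu[:, :, None], scale=sd[:, :, None])
    bits = state_bits(model.k).astype(float)
    return bits @ lp[:, 1, :] + (1.0 - bits) @ lp[:, 0, :]


def _forward(model: ProductHMMModel, log_b: np.ndarray):
    """Scaled forward pass.

    Emissions are rescaled per time-step by their column max before the
    recursion, so the scaling constants stay in range for any K.  Returns
    (alpha_hat, c, m, log_lik) with alpha_hat the normalized forward
    variables, c the per-step normalizers of the rescaled recursion and m
    the per-step emission log offsets: log P(Y|lambda) = sum log c + sum m.
    """
    m = log_b.max(axis=0)
    b = np.exp(log_b - m)
    n_states, t_len = b.shape
    alpha = np.empty((n_states, t_len))
    c = np.empty(t_len)
    a = model.startprob * b[:, 0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise FloatingPointError("forward recursion underflowed at t=0")
    alpha[:, 0] = a / c[0]
    at = model.transmat.T
    for t in range(1, t_len):
        a = (at @ alpha[:, t - 1]) * b[:, t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise FloatingPointError(f"forward recursion underflowed at t={t}")
        alpha[:, t] = a / c[t]
    return alpha, c, m, float(np.log(c).sum() + m.sum())


def _backward(model: ProductHMMModel, log_b: np.ndarray, c: np.ndarray,
              m: np.ndarray) -> np.ndarray:
    """Backward variables scaled with the forward pass's constants."""
    b = np.exp(log_b - m)
    n_states, t_len = b.shape
    beta = np.empty((n_states, t_len))
    beta[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[:, t] = (model.transmat @ (b[:, t + 1] * beta[:, t + 1])) / c[t + 1]
    return beta


def log_likelihood(model: ProductHMMModel, obs: np.ndarray) -> float:
    """log P(Y | lambda) via the scaled forward recursion."""
    obs = _as_obs(obs, model.k)
    log_b = _joint_log_emissions(model, obs)
    return _forward(model, log_b)[3]


def log_likelihood_backward(model: ProductHMMModel, obs: np.ndarray) -> float:
    """log P(Y | lambda) via an independently scaled backward recursion.

    Exists as a numerical cross-check of the forward pass; the two must
    agree to tight tolerance.
    """
    obs = _as_obs(obs, model.k)
    log_b = _joint_log_emissions(model, obs)
    m = log_b.max(axis=0)
    b = np.exp(log_b - m)
    n_states, t_len = b.shape
    beta = np.ones(n_states)
    log_scale = 0.0
    for t in range(t_len - 2, -1, -1):
        beta = model.transmat @ (b[:, t + 1] * beta)
        s = beta.max()
        beta /= s
        log_scale += np.log(s)
    total = float(np.sum(model.startprob * b[:, 0] * beta))
    return float(np.log(total) + log_scale + m.sum())


# ---------------------------------------------------------------------------
# Initialization


def init_parameters(obs: np.ndarray, channel_names: list[str] | None = None
                    ) -> ProductHMMModel:
    """Data-driven initialization of a product HMM from one observation matrix.

    Pi is uniform (1/2^K).  A starts diagonal-favoring: off-diagonal entries
    1/(2^K + 1) and diagonal entries 2/(2^K + 1), so each row sums to one
    exactly.  Per channel, (mu_{+1}, sigma_{+1}) are the sample moments of
    the positive observations and (mu_{-1}, sigma_{-1}) those of the
    negative ones; zeros count as neither.  A channel with no positive (or
    no negative) samples falls back to the grand mean +/- one grand std for
    the missing component (warning logged).  Sample stds use ddof=1; a
    single-sample split falls back to the grand std; all stds are floored
    at VARIANCE_FLOOR.
    """
    obs = _as_obs(obs)
    k, _ = obs.shape
    m = 2 ** k
    startprob = np.full(m, 1.0 / m)
    transmat = np.full((m, m), 1.0 / (m + 1))
    np.fill_diagonal(transmat, 2.0 / (m + 1))
    means = np.empty((k, 2))
    stds = np.empty((k, 2))
    for ch in range(k):
        row = obs[ch]
        grand_mu = float(row.mean())
        grand_sd = max(float(row.std(ddof=1)) if len(row) > 1 else VARIANCE_FLOOR,
                       VARIANCE_FLOOR)
        for col, sel in ((0, row[row < 0]), (1, row[row > 0])):
            if sel.size == 0:
                sign = -1.0 if col == 0 else 1.0
                means[ch, col] = grand_mu + sign * grand_sd
                stds[ch, col] = grand_sd
                logger.warning(
                    "channel %d has no %s samples; emission component "
                    "initialized from grand moments", ch,
                    "negative" if col == 0 else "positive")
            else:
                means[ch, col] = sel.mean()
                sd = sel.std(ddof=1) if sel.size > 1 else grand_sd
                stds[ch, col] = max(float(sd), VARIANCE_FLOOR)
    return ProductHMMModel(k=k, startprob=startprob, transmat=transmat,
                           emissions=EmissionParams(means, stds),
                           channel_names=channel_names or [])


# ---------------------------------------------------------------------------
# Learning


def baum_welch_fit(model: ProductHMMModel, obs: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-4,
                   update_startprob: bool = True) -> FitResult:
    """EM re-estimation of the transition matrix (and Pi) with emissions fixed.

    Holding the Gaussian emission table at its data-driven initialization
    keeps the parameter count manageable on short sequences; only the joint
    dynamics (A, and optionally Pi) are learned.  Stops when the
    log-likelihood improvement drops below ``tol`` or after ``max_iter``
    iterations; non-convergence returns the best model with
    ``converged=False`` rather than raising.

    Returns
    -------
    FitResult
        Fitted model, per-iteration log-likelihood trace (evaluated at the
        parameters entering each iteration, plus a final evaluation), and a
        convergence flag.
    """
    obs = _as_obs(obs, model.k)
    log_b = _joint_log_emissions(model, obs)
    t_len = obs.shape[1]
    pi = model.startprob.copy()
    a = model.transmat.copy()
    trace = []
    converged = False
    for it in range(max_iter):
        current = replace(model, startprob=pi, transmat=a)
        alpha, c, m_off, ll = _forward(current, log_b)
        trace.append(ll)
        if it > 0 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        beta = _backward(current, log_b, c, m_off)
        gamma = alpha * beta
        b = np.exp(log_b - m_off)
        # expected transition counts: sum_t alpha_t(i) a_ij b_j(t+1) beta_{t+1}(j) / c_{t+1}
        xi_sum = np.zeros_like(a)
        for t in range(t_len - 1):
            xi_sum += np.outer(alpha[:, t], b[:, t + 1] * beta[:, t + 1] / c[t + 1])
        xi_sum *= a
        row_sums = xi_sum.sum(axis=1, keepdims=True)
        stuck = row_sums[:, 0] <= 0
        new_a = np.where(stuck[:, None], a, xi_sum / np.where(row_sums > 0, row_sums, 1.0))
        new_a /= new_a.sum(axis=1, keepdims=True)
        a = new_a
        if update_startprob:
            pi = gamma[:, 0] / gamma[:, 0].sum()
    fitted = replace(model, startprob=pi, transmat=a)
    if not converged:
        trace.append(log_likelihood(fitted, obs))
        logger.warning("Baum-Welch did not converge within %d iterations", max_iter)
    return FitResult(model=fitted, log_likelihoods=np.array(trace),
                     converged=converged, n_iter=len(trace) - 1)


# ---------------------------------------------------------------------------
# Decoding and generation


def viterbi_decode(model: ProductHMMModel, obs: np.ndarray) -> StateSequence:
    """Maximum-a-posteriori joint state path (log-space Viterbi).

    Ties in the argmax are broken toward the lower state index, so decoding
    is deterministic.  ``log_prob`` is the joint log-probability
    log P(X*, Y | lambda) of the returned path.
    """
    obs = _as_obs(obs, model.k)
    log_b = _joint_log_emissions(model, obs)
    n_states, t_len = log_b.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.startprob)
        log_a = np.log(model.transmat)
    delta = log_pi + log_b[:, 0]
    psi = np.empty((t_len, n_states), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # (from, to)
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[psi[t], np.arange(n_states)] + log_b[:, t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    log_prob = float(delta[path[-1]])
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = psi[t][path[t]]
    return StateSequence.from_joint(path, model.k, log_prob, model.channel_names)


def generate_observations(model: ProductHMMModel, t_gen: int,
                          seed: int | np.random.SeedSequence,
                          ) -> tuple[np.ndarray, StateSequence]:
    """Sample a hidden path and Gaussian observations from the model.

    Deterministic given ``seed``.  Returns the (K, t_gen) observation
    matrix together with the hidden path (its ``log_prob`` is the full
    joint log-probability of path and observations under the model).
    """
    if t_gen < 1:
        raise ValueError("t_gen must be >= 1")
    rng = np.random.default_rng(seed)
    n_states = model.n_states
    # inverse-CDF sampling of the chain (cheaper than per-step choice calls)
    u = rng.random(t_gen)
    cdf_pi = np.cumsum(model.startprob)
    cdf_a = np.cumsum(model.transmat, axis=1)
    path = np.empty(t_gen, dtype=int)
    path[0] = min(int(np.searchsorted(cdf_pi, u[0], side="right")), n_states - 1)
    for t in range(1, t_gen):
        path[t] = min(int(np.searchsorted(cdf_a[path[t - 1]], u[t], side="right")),
                      n_states - 1)
    mu = model.joint_means()  # (M, K)
    sd = model.joint_stds()
    obs = (mu[path] + rng.standard_normal((t_gen, model.k)) * sd[path]).T
    with np.errstate(divide="ignore"):
        log_prob = float(np.log(model.startprob[path[0]])
                         + np.log(model.transmat[path[:-1], path[1:]]).sum()
                         + norm.logpdf(obs, loc=mu[path].T, scale=sd[path].T).sum())
    seq = StateSequence.from_joint(path, model.k, log_prob, model.channel_names)
    return obs, seq
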