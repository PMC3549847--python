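"""Copy-number assignment with a Gaussian-emission hidden Markov model.

Hidden states are integer copy numbers 0..K-1 (default K=6: homozygous
deletion, hemizygous deletion, neutral, one-copy gain, two- and three-copy
amplification).  The observation at each exon is the smoothed,
median-normalized DOC ratio; state k emits N(mu_k, sigma^2) with one sigma
shared across states.  The state means come from the admixture model

    mu_k = (alpha * 2 + (1 - alpha) * c_k) / (alpha * 2 + (1 - alpha) * P_T)

where alpha is the normal-cell contamination fraction, c_k the tumour copy
number of state k, 2 the normal ploidy and P_T the most abundant tumour
ploidy (the median-normalization reference).

The initial distribution and transition matrix are fixed heuristics: mass
concentrated on the neutral state, strong self-transition, and return to
neutral favoured over switching between CNV states.  The single free
parameter sigma is fitted by bounded minimization of the negative
log-likelihood (scaled forward algorithm); decoding is Viterbi with ties
broken toward the lower copy number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

from .preprocess import RatioTrack
from .targets_io import InputError, TargetRegion

__all__ = [
    "HMMModel",
    "StatePath",
    "Segment",
    "emission_means",
    "default_model",
    "negative_log_likelihood",
    "fit_sigma",
    "viterbi",
    "decode_track",
    "call_segments",
]

NORMAL_COPY = 2
DEFAULT_SIGMA_BOUNDS = (0.01, 1.0)

# pi / A heuristics: the ordinal constraints (neutral favoured; stay >
# return-to-neutral > CNV-to-CNV switch) made numeric
PI_NORMAL = 0.95
A_STAY = 0.95
A_TO_NORMAL = 0.03


def emission_means(
    alpha: float,
    tumour_ploidy: float,
    copies: np.ndarray | list[int],
    normal_ploidy: float = 2.0,
) -> np.ndarray:
    """Expected median-normalized DOC ratio for each copy-number state."""
    if not 0.0 <= alpha <= 1.0:
        raise InputError(f"alpha must be in [0, 1], got {alpha}")
    if tumour_ploidy < 1:
        raise InputError(f"tumour ploidy must be >= 1, got {tumour_ploidy}")
    copies = np.asarray(copies, dtype=float)
    denom = alpha * normal_ploidy + (1.0 - alpha) * tumour_ploidy
    return (alpha * normal_ploidy + (1.0 - alpha) * copies) / denom


@dataclass
class HMMModel:
    """lambda = (A, B, pi) with admixture-derived means and one shared sigma."""

    K: int
    copies: np.ndarray
    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray
    sigma: float
    alpha: float = 0.0
    tumour_ploidy: float = 2.0
    normal_ploidy: float = 2.0

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=int)
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if not (len(self.pi) == len(self.mu) == len(self.copies) == self.K):
            raise InputError("pi, mu, copies must all have length K")
        if self.A.shape != (self.K, self.K):
            raise InputError("A must be K x K")
        if self.sigma <= 0:
            raise InputError(f"sigma must be > 0, got {self.sigma}")
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise InputError("pi and A must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise InputError("pi must sum to 1")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-12:
            raise InputError("rows of A must sum to 1")

    def with_sigma(self, sigma: float) -> "HMMModel":
        return replace(self, sigma=float(sigma))


@dataclass
class StatePath:
    """Viterbi-decoded copy number per exon plus the path log-probability."""

    states: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class Segment:
    """Maximal run of consecutive exons sharing one decoded copy number."""

    chrom: str
    start: int
    end: int
    copy_number: int
    n_exons: int
    mean_ratio: float

    @property
    def is_cnv(self) -> bool:
        return self.copy_number != NORMAL_COPY


def default_model(
    K: int = 6,
    alpha: float = 0.0,
    tumour_ploidy: float = 2.0,
    sigma0: float = 0.1,
) -> HMMModel:
    """Build the heuristic K-state model (copies 0..K-1, neutral = copy 2)."""
    if K < 2:
        raise InputError(f"need at least 2 states, got K={K}")
    copies = np.arange(K)
    if NORMAL_COPY >= K:
        raise InputError("the copy-2 (neutral) state must exist")
    normal = NORMAL_COPY  # index of the neutral state in 0..K-1 copy ordering

    pi = np.full(K, (1.0 - PI_NORMAL) / (K - 1))
    pi[normal] = PI_NORMAL

    A = np.zeros((K, K))
    for m in range(K):
        A[m, m] = A_STAY
        if m == normal:
            A[m, np.arange(K) != m] = (1.0 - A_STAY) / (K - 1)
        else:
            A[m, normal] = A_TO_NORMAL
            others = [p for p in range(K) if p not in (m, normal)]
            if others:
                A[m, others] = (1.0 - A_STAY - A_TO_NORMAL) / len(others)
            else:
                A[m, normal] = 1.0 - A_STAY

    mu = emission_means(alpha, tumour_ploidy, copies)
    return HMMModel(
        K=K, copies=copies, pi=pi, A=A, mu=mu, sigma=float(sigma0),
        alpha=alpha, tumour_ploidy=tumour_ploidy,
    )


@njit(cache=True)
def _forward_nll(obs, pi, A, mu, sigma):  # pragma: no cover - jitted
    L = obs.shape[0]
    K = mu.shape[0]
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    alpha_t = np.empty(K)
    nll = 0.0
    for k in range(K):
        d = obs[0] - mu[k]
        alpha_t[k] = pi[k] * norm * np.exp(-d * d * inv2s2)
    s = alpha_t.sum()
    if s <= 0.0:
        return np.inf
    nll -= np.log(s)
    alpha_t /= s
    nxt = np.empty(K)
    for t in range(1, L):
        for p in range(K):
            acc = 0.0
            for m in range(K):
                acc += alpha_t[m] * A[m, p]
            d = obs[t] - mu[p]
            nxt[p] = acc * norm * np.exp(-d * d * inv2s2)
        s = nxt.sum()
        if s <= 0.0:
            return np.inf
        nll -= np.log(s)
        for k in range(K):
            alpha_t[k] = nxt[k] / s
    return nll


@njit(cache=True)
def _viterbi_path(obs, log_pi, log_A, mu, sigma):  # pragma: no cover - jitted
    L = obs.shape[0]
    K = mu.shape[0]
    log_norm = -np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    delta = np.empty(K)
    for k in range(K):
        d = obs[0] - mu[k]
        delta[k] = log_pi[k] + log_norm - d * d * inv2s2
    back = np.empty((L, K), dtype=np.int64)
    nxt = np.empty(K)
    for t in range(1, L):
        for p in range(K):
            best = -np.inf
            arg = 0
            for m in range(K):
                v = delta[m] + log_A[m, p]
                if v > best:  # strict: first (lowest-copy) maximizer wins
                    best = v
                    arg = m
            d = obs[t] - mu[p]
            nxt[p] = best + log_norm - d * d * inv2s2
            back[t, p] = arg
        delta[:] = nxt
    best = -np.inf
    last = 0
    for k in range(K):
        if delta[k] > best:
            best = delta[k]
            last = k
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = last
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


def negative_log_likelihood(model: HMMModel, observations: np.ndarray) -> float:
    """-log P(O | lambda) by the scaled forward algorithm."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise InputError("empty observation sequence")
    if model.sigma <= 0:
        raise InputError("sigma must be > 0")
    return float(_forward_nll(obs, model.pi, model.A, model.mu, model.sigma))


def initial_sigma(values: np.ndarray, bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS) -> float:
    """MAD-based starting sigma: MAD(values - 1)/0.6745 clipped to bounds."""
    mad = float(np.median(np.abs(np.asarray(values) - 1.0)))
    return float(np.clip(mad / 0.6745, bounds[0], bounds[1]))


def fit_sigma(
    model: HMMModel,
    observations: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
) -> HMMModel:
    """Fit the shared emission sigma by bounded NLL minimization.

    pi, A and mu stay fixed; sigma is the model's one free parameter.
    Guaranteed not to return a model worse than the input.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise InputError(f"invalid sigma bounds {bounds}")
    obs = np.asarray(observations, dtype=float)
    nll0 = negative_log_likelihood(model, obs)
    res = minimize_scalar(
        lambda s: _forward_nll(obs, model.pi, model.A, model.mu, s),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success or not np.isfinite(res.fun):
        warnings.warn("sigma optimization did not converge; keeping initial sigma")
        return model
    if res.fun > nll0:
        # initial sigma (e.g. pinned at a bound) already beats the interior
        return model
    return model.with_sigma(float(res.x))


def viterbi(model: HMMModel, observations: np.ndarray) -> StatePath:
    """Most probable copy-number path; exact ties go to the lower copy number."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise InputError("empty observation sequence")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_A = np.log(model.A)
    path, logp = _viterbi_path(obs, log_pi, log_A, model.mu, model.sigma)
    return StatePath(states=model.copies[path], log_likelihood=float(logp))


def decode_track(model: HMMModel, track: RatioTrack) -> StatePath:
    """Viterbi-decode each chromosome independently (fresh pi per chromosome)."""
    states = np.empty(len(track), dtype=int)
    total = 0.0
    for sl in track.chrom_index.values():
        sub = viterbi(model, track.values[sl])
        states[sl] = sub.states
        total += sub.log_likelihood
    return StatePath(states=states, log_likelihood=total)


def call_segments(path: StatePath, track: RatioTrack) -> list[Segment]:
    """Run-length encode the decoded states into per-chromosome segments."""
    if len(path) != len(track):
        raise InputError("state path and ratio track have different lengths")
    segments: list[Segment] = []
    for chrom, sl in track.chrom_index.items():
        states = path.states[sl]
        values = track.values[sl]
        regions = track.regions[sl]
        run_start = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[run_start]:
                segments.append(
                    Segment(
                        chrom=chrom,
                        start=regions[run_start].start,
                        end=regions[i - 1].end,
                        copy_number=int(states[run_start]),
                        n_exons=i - run_start,
                        mean_ratio=float(values[run_start:i].mean()),
                    )
                )
                run_start = i
    return segments
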