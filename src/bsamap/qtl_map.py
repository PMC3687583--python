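"""Linkage-region detection on pooled variant-frequency tracks.

Two complementary views of the same data:

* a coverage-weighted tricube kernel smoother with a 95 % confidence band,
  for visualising systematic deviations of the variant frequency from the
  neutral 0.5; and
* a three-state hidden Markov model with binomial read-count emissions that
  segments each chromosome into neutral stretches and stretches linked to
  the superior or inferior parent.  The linked states emit reads with
  success probability ``p_link`` (respectively ``1 - p_link``); the neutral
  state emits at 0.5.  Transitions decay with physical distance d between
  adjacent markers: with probability ``exp(-d / lambda)`` the state
  persists, otherwise the next state is drawn from the stationary prior.
  That family is multiplicative in d, so markers with zero coverage can be
  carried in the chain with unit emission likelihood — equivalent to
  skipping them and measuring distances between covered markers.

The HMM stands in for the unpublished segmentation model used in the
original pooled-segregant analyses; every parameter is explicit and
configurable.  Forward–backward runs in log space (read depths of 100x
over thousands of markers underflow linear-space arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .poolseq import PoolCounts, VariantFrequencyTrack

__all__ = [
    "STATE_NEUTRAL",
    "STATE_SUPERIOR",
    "STATE_INFERIOR",
    "HmmParams",
    "SmoothedTrack",
    "QtlRegion",
    "smooth_track",
    "hmm_posteriors",
    "call_regions",
]

STATE_NEUTRAL = 0
STATE_SUPERIOR = 1
STATE_INFERIOR = 2
_DIRECTIONS = {STATE_SUPERIOR: "superior", STATE_INFERIOR: "inferior"}


@dataclass(frozen=True)
class HmmParams:
    """Parameters of the three-state binomial-emission linkage HMM.

    p_link
        Emission probability of a superior-allele read inside a
        superior-linked segment (the inferior-linked state emits at
        ``1 - p_link``); must exceed 0.5.
    persistence_bp
        Distance scale lambda (bp) of state persistence; comparable to the
        physical extent of linked regions.
    priors
        Stationary probabilities of (neutral, linked-superior,
        linked-inferior); also the initial distribution of each chromosome.
    posterior_threshold, min_markers
        A region is called from a run of >= ``min_markers`` consecutive
        markers whose winning linked-state posterior reaches the threshold.
    """

    p_link: float = 0.9
    persistence_bp: float = 20_000.0
    priors: tuple[float, float, float] = (0.98, 0.01, 0.01)
    posterior_threshold: float = 0.95
    min_markers: int = 3

    def __post_init__(self):
        if not 0.5 < self.p_link <= 1.0:
            raise ValueError("p_link must lie in (0.5, 1]")
        if self.persistence_bp <= 0:
            raise ValueError("persistence length must be positive")
        pr = np.asarray(self.priors, dtype=float)
        if pr.shape != (3,) or np.any(pr < 0) or abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be three non-negative numbers summing to 1")
        if not 0 < self.posterior_threshold <= 1:
            raise ValueError("posterior threshold must lie in (0, 1]")
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")

    @property
    def emission_probs(self) -> np.ndarray:
        return np.array([0.5, self.p_link, 1.0 - self.p_link])


@dataclass
class SmoothedTrack:
    """Kernel-smoothed variant frequency with a 95 % confidence band."""

    chrom: np.ndarray
    pos: np.ndarray
    smoothed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class QtlRegion:
    """Candidate linked region: 1-based inclusive interval with direction."""

    chrom: int
    start: int
    end: int
    direction: str
    mean_posterior: float
    n_markers: int
    pool_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
        if self.direction not in ("superior", "inferior"):
            raise ValueError("direction must be 'superior' or 'inferior'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _chromosome_slices(chrom: np.ndarray) -> list[tuple[int, slice]]:
    out = []
    values, starts = np.unique(chrom, return_index=True)
    order = np.argsort(starts)
    starts = np.append(starts[order], len(chrom))
    for i, c in enumerate(values[order]):
        out.append((int(c), slice(int(starts[i]), int(starts[i + 1]))))
    return out


def smooth_track(track: VariantFrequencyTrack, bandwidth: float = 30_000.0) -> SmoothedTrack:
    """Coverage-weighted tricube kernel smoothing of a variant-frequency
    track, per chromosome.

    At marker i the smoothed value is the weighted mean of raw frequencies
    of covered markers within +-bandwidth, with weights
    ``tricube(d / bandwidth) * coverage``.  The 95 % band uses the
    effective binomial sample size of the window under a normal
    approximation and is clipped to [0, 1].  Markers whose window contains
    no covered marker stay NaN.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    m = track.n_markers
    smoothed = np.full(m, np.nan)
    lower = np.full(m, np.nan)
    upper = np.full(m, np.nan)
    for _, sl in _chromosome_slices(track.chrom):
        pos = track.pos[sl].astype(float)
        freq = track.freq[sl]
        cov = track.coverage[sl].astype(float)
        covered = cov > 0
        cpos, cfreq, ccov = pos[covered], freq[covered], cov[covered]
        if len(cpos) == 0:
            continue
        lo = np.searchsorted(cpos, pos - bandwidth, side="left")
        hi = np.searchsorted(cpos, pos + bandwidth, side="right")
        s = np.full(len(pos), np.nan)
        lb = np.full(len(pos), np.nan)
        ub = np.full(len(pos), np.nan)
        for i in range(len(pos)):
            j = slice(lo[i], hi[i])
            if j.start >= j.stop:
                continue
            t = (1.0 - (np.abs(cpos[j] - pos[i]) / bandwidth) ** 3) ** 3
            w = t * ccov[j]
            wsum = w.sum()
            if wsum <= 0:
                continue
            shat = float(np.dot(w, cfreq[j]) / wsum)
            n_eff = wsum ** 2 / float(np.dot(t ** 2, ccov[j]))
            se = np.sqrt(max(shat * (1.0 - shat), 0.0) / n_eff)
            s[i] = shat
            lb[i] = max(shat - 1.96 * se, 0.0)
            ub[i] = min(shat + 1.96 * se, 1.0)
        smoothed[sl], lower[sl], upper[sl] = s, lb, ub
    return SmoothedTrack(chrom=track.chrom.copy(), pos=track.pos.copy(),
                         smoothed=smoothed, lower=lower, upper=upper, bandwidth=bandwidth)


def hmm_posteriors(counts: PoolCounts, params: HmmParams | None = None) -> np.ndarray:
    """Per-marker posterior probabilities of (neutral, linked-superior,
    linked-inferior), from forward–backward in log space, chromosome by
    chromosome.  Rows sum to 1; a lone marker with zero coverage gets the
    stationary prior.
    """
    params = params or HmmParams()
    m = counts.n_markers
    post = np.empty((m, 3))
    log_pi = np.log(np.asarray(params.priors))
    p_states = params.emission_probs
    for _, sl in _chromosome_slices(counts.chrom):
        k = counts.k[sl]
        n = counts.n[sl]
        pos = counts.pos[sl]
        L = len(k)
        # binomial log-likelihood per marker and state; identically 1 at n=0
        loge = stats.binom.logpmf(k[:, None], n[:, None], p_states[None, :])
        # T(d) = stay(d) I + (1 - stay(d)) 1 pi is rank-one off the diagonal,
        # so each forward/backward step is a closed-form logaddexp update
        # rather than a full 3x3 log-matrix product.
        with np.errstate(divide="ignore"):
            log_stay = -np.diff(pos).astype(float) / params.persistence_bp
            log_move = np.log(-np.expm1(log_stay))
        alpha = np.empty((L, 3))
        alpha[0] = log_pi + loge[0]
        for i in range(1, L):
            a = alpha[i - 1]
            hi = a.max()
            total = hi + np.log(np.exp(a - hi).sum())
            alpha[i] = np.logaddexp(a + log_stay[i - 1],
                                    total + log_move[i - 1] + log_pi) + loge[i]
        beta = np.zeros((L, 3))
        for i in range(L - 2, -1, -1):
            b = loge[i + 1] + beta[i + 1]
            bp = b + log_pi
            hi = bp.max()
            mixed = hi + np.log(np.exp(bp - hi).sum())
            beta[i] = np.logaddexp(log_stay[i] + b, log_move[i] + mixed)
        gamma = alpha + beta
        gamma -= logsumexp(gamma, axis=1, keepdims=True)
        post[sl] = np.exp(gamma)
    return post


def call_regions(posteriors: np.ndarray, counts: PoolCounts,
                 params: HmmParams | None = None) -> list[QtlRegion]:
    """Maximal runs of consecutive markers whose winning linked-state
    posterior reaches the threshold, with at least ``min_markers`` markers
    and a consistent direction.  The interval spans the first to the last
    marker of the run (1-based inclusive).
    """
    params = params or HmmParams()
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.shape != (counts.n_markers, 3):
        raise ValueError("posteriors must be (n_markers, 3) aligned with the counts")
    regions: list[QtlRegion] = []
    for c, sl in _chromosome_slices(counts.chrom):
        post = posteriors[sl]
        pos = counts.pos[sl]
        linked = np.where(post[:, STATE_SUPERIOR] >= post[:, STATE_INFERIOR],
                          STATE_SUPERIOR, STATE_INFERIOR)
        score = post[np.arange(len(pos)), linked]
        hot = score >= params.posterior_threshold
        i = 0
        while i < len(pos):
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pos) and hot[j + 1] and linked[j + 1] == linked[i]:
                j += 1
            if j - i + 1 >= params.min_markers:
                regions.append(QtlRegion(
                    chrom=c, start=int(pos[i]), end=int(pos[j]),
                    direction=_DIRECTIONS[int(linked[i])],
                    mean_posterior=float(score[i:j + 1].mean()),
                    n_markers=j - i + 1, pool_id=counts.pool_id))
            i = j + 1
    return regions
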