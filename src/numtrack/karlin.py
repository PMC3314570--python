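"""Karlin-Altschul statistics for ungapped local alignment scores.

The significance filter of the hybridization step keeps an HSP when its
expectation E = K * m * n * exp(-lambda * S) falls below the configured
threshold.  lambda is the unique positive root of the moment equation

    sum_ij p_i p_j exp(lambda * s_ij) = 1

for the substitution scores s_ij, and K is obtained by the standard lattice
series approximation (convolutions of the score distribution).  Gapped
alignments reuse the ungapped lambda and K solved from the substitution
scores — a documented approximation; both constants can be overridden to
match an external BLAST run bit-exactly.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy.optimize import brentq

from .model import EValueParams, ScoringScheme

__all__ = [
    "score_distribution",
    "solve_lambda",
    "karlin_k",
    "solve_karlin_altschul",
    "evalue",
    "min_score_for_evalue",
]

UNIFORM_FREQS = (0.25, 0.25, 0.25, 0.25)


def score_distribution(
    scheme: ScoringScheme, base_frequencies=UNIFORM_FREQS
) -> dict[int, float]:
    """Probability of each substitution score for one aligned column.

    With a match/mismatch matrix this collapses to two support points:
    P(match) = sum_i p_i^2, P(mismatch) = 1 - P(match).
    """
    p = np.asarray(base_frequencies, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not math.isclose(p.sum(), 1.0):
        raise ValueError("base_frequencies must be 4 non-negative values summing to 1")
    p_match = float(np.sum(p * p))
    dist: dict[int, float] = defaultdict(float)
    dist[int(scheme.match_reward)] += p_match
    dist[int(scheme.mismatch_penalty)] += 1.0 - p_match
    return dict(dist)


def solve_lambda(dist: dict[int, float]) -> float:
    """Unique positive root of sum_s P(s) * exp(lambda * s) = 1.

    Exists iff the expected score is negative and a positive score occurs.
    """
    scores = np.array(sorted(dist), dtype=float)
    probs = np.array([dist[int(s)] for s in scores])
    if float(np.dot(scores, probs)) >= 0:
        raise ValueError(
            "expected score must be negative for the E-value statistic"
        )
    if scores.max() <= 0:
        raise ValueError("a positive score must be possible")

    def moment(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * scores))) - 1.0

    hi = 1.0
    while moment(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - malformed distribution
            raise ValueError("failed to bracket lambda")
    return float(brentq(moment, 1e-12, hi, xtol=1e-12, rtol=1e-14))


def _entropy_h(dist: dict[int, float], lam: float) -> float:
    """Relative entropy H = lambda * sum_s s P(s) exp(lambda s) (nats/column)."""
    return lam * sum(s * p * math.exp(lam * s) for s, p in dist.items())


def karlin_k(dist: dict[int, float], lam: float, iterations: int = 120) -> float:
    """Karlin-Altschul K by the lattice-case series approximation.

    Accumulates sigma = sum_{k>=1} (1/k) [ E(exp(lambda S_k); S_k < 0)
    + P(S_k >= 0) ] over k-fold convolutions of the per-column score
    distribution, then applies

        K = delta * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda delta)))

    where delta is the lattice span (gcd of the score values) and H the
    relative entropy.
    """
    scores = sorted(dist)
    delta = 0
    for s in scores:
        delta = math.gcd(delta, abs(int(s)))
    if delta == 0:
        raise ValueError("degenerate score distribution")
    H = _entropy_h(dist, lam)

    lo, hi = min(scores), max(scores)
    # dense probability vector on the score lattice
    base = np.zeros(hi - lo + 1)
    for s, p in dist.items():
        base[s - lo] = p
    conv = np.array([1.0])  # distribution of S_0 = 0
    offset = 0  # value of the first cell of `conv`
    sigma = 0.0
    for k in range(1, iterations + 1):
        conv = np.convolve(conv, base)
        offset += lo
        values = offset + np.arange(conv.size)
        neg = values < 0
        term = float(np.sum(conv[neg] * np.exp(lam * values[neg])))
        term += float(np.sum(conv[~neg]))
        sigma += term / k
        if term / k < 1e-12:
            break
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    if not (K > 0 and math.isfinite(K)):  # pragma: no cover - defensive
        raise ValueError("K computation did not converge")
    return K


def solve_karlin_altschul(
    scheme: ScoringScheme,
    base_frequencies=UNIFORM_FREQS,
    m: int = 1,
    n: int = 1,
) -> EValueParams:
    """Solve lambda and K for a scoring scheme and background composition."""
    dist = score_distribution(scheme, base_frequencies)
    lam = solve_lambda(dist)
    K = karlin_k(dist, lam)
    return EValueParams(lambda_=lam, K=K, m=m, n=n)


def evalue(raw_score: float, params: EValueParams) -> float:
    """Expected number of chance HSPs scoring >= raw_score in an m x n search."""
    return params.K * params.m * params.n * math.exp(-params.lambda_ * raw_score)


def min_score_for_evalue(threshold: float, params: EValueParams) -> int:
    """Smallest integer score whose E-value is <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    s = math.log(params.K * params.m * params.n / threshold) / params.lambda_
    return max(1, math.ceil(s - 1e-9))
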