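"""Brute-force reference implementations used only to cross-check the package.

Everything here is written in plain Python loops, directly from the defining
formulas, and shares no code with sleepops.
"""

import itertools
import math


def brute_patterns(D):
    """All rank tuples of length D, lexicographically sorted."""
    return sorted(itertools.permutations(range(D)))


def brute_encode(segment):
    """Rank tuple of a segment; ties broken by temporal order."""
    order = sorted(range(len(segment)), key=lambda i: (segment[i], i))
    ranks = [0] * len(segment)
    for r, i in enumerate(order):
        ranks[i] = r
    return tuple(ranks)


def brute_variance(segment):
    m = sum(segment) / len(segment)
    return sum((x - m) ** 2 for x in segment) / len(segment)


def brute_segments(series, D, tau):
    T = len(series)
    return [
        [series[t + j * tau] for j in range(D)] for t in range(T - (D - 1) * tau)
    ]


def brute_gwpe_distribution(series, D, tau, q):
    """Generalized weighted pattern probabilities via exhaustive enumeration.

    Returns a dict rank-tuple -> probability.  Zero-variance segments get
    weight 1 at q = 0, weight 0 at q > 0, and are skipped at q < 0.
    """
    sums = {}
    total = 0.0
    for seg in brute_segments(series, D, tau):
        pat = brute_encode(seg)
        w = brute_variance(seg)
        if q == 0:
            wq = 1.0
        elif w == 0:
            if q < 0:
                continue
            wq = 0.0
        else:
            wq = w ** (q / 2.0)
        sums[pat] = sums.get(pat, 0.0) + wq
        total += wq
    return {pat: s / total for pat, s in sums.items()}


def brute_prob_vector(series, D, tau, q):
    """Probability list in canonical (lexicographic) pattern order."""
    dist = brute_gwpe_distribution(series, D, tau, q)
    return [dist.get(pat, 0.0) for pat in brute_patterns(D)]


def brute_shannon(probs):
    return -sum(p * math.log(p) for p in probs if p > 0)


def brute_jsd(p, u):
    mid = [(a + b) / 2 for a, b in zip(p, u)]
    return brute_shannon(mid) - (brute_shannon(p) + brute_shannon(u)) / 2


def brute_complexity(probs):
    """(S, H, Q, C) evaluated term by term from the defining formulas."""
    M = len(probs)
    uniform = [1.0 / M] * M
    S = brute_shannon(probs)
    H = S / math.log(M)
    delta = [1.0] + [0.0] * (M - 1)
    Q = brute_jsd(probs, uniform) / brute_jsd(delta, uniform)
    return S, H, Q, Q * H
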