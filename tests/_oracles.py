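"""Independent brute-force transcriptions of the published estimator formulas.

Deliberately written in a direct, loop-based style, separate from the package
implementation, so the two code paths share nothing but the published maths.
"""

import math
from collections import Counter

import numpy as np


def profile(values):
    """Counter j -> number of species with frequency/abundance exactly j."""
    return Counter(int(v) for v in values if v > 0)


def chao1_oracle(abundances):
    f = profile(abundances)
    sobs = sum(f.values())
    f1, f2 = f.get(1, 0), f.get(2, 0)
    if f2 > 0:
        return sobs + f1 * f1 / (2.0 * f2)
    return sobs + f1 * (f1 - 1) / 2.0


def chao2_oracle(incidence_rows):
    m = len(incidence_rows)
    freq = [sum(col) for col in zip(*incidence_rows)]
    q = profile(freq)
    sobs = sum(q.values())
    q1, q2 = q.get(1, 0), q.get(2, 0)
    a = (m - 1) / m
    if q2 > 0:
        return sobs + a * q1 * q1 / (2.0 * q2)
    return sobs + a * q1 * (q1 - 1) / 2.0


def jack1_oracle(incidence_rows):
    m = len(incidence_rows)
    freq = [sum(col) for col in zip(*incidence_rows)]
    q = profile(freq)
    return sum(q.values()) + q.get(1, 0) * (m - 1) / m


def jack2_oracle(incidence_rows):
    m = len(incidence_rows)
    freq = [sum(col) for col in zip(*incidence_rows)]
    q = profile(freq)
    sobs = sum(q.values())
    q1, q2 = q.get(1, 0), q.get(2, 0)
    return sobs + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))


def ace_oracle(abundances, threshold=10):
    ns = [int(v) for v in abundances if v > 0]
    rare = [v for v in ns if v <= threshold]
    s_abund = len(ns) - len(rare)
    s_rare = len(rare)
    if s_rare == 0:
        return float(len(ns))
    n_rare = sum(rare)
    f1 = sum(1 for v in rare if v == 1)
    c = 1.0 - f1 / n_rare
    if c <= 0:
        return chao1_oracle(ns)
    total = sum(k * (k - 1) * sum(1 for v in rare if v == k) for k in range(1, threshold + 1))
    gamma2 = max((s_rare / c) * total / (n_rare * (n_rare - 1)) - 1.0, 0.0) if n_rare > 1 else 0.0
    return s_abund + s_rare / c + f1 / c * gamma2


def ice_oracle(incidence_rows, threshold=10):
    freq = [sum(col) for col in zip(*incidence_rows)]
    present = [i for i, v in enumerate(freq) if v > 0]
    infreq = [i for i in present if freq[i] <= threshold]
    s_freq = len(present) - len(infreq)
    s_infreq = len(infreq)
    if s_infreq == 0:
        return float(len(present))
    m_infreq = sum(1 for row in incidence_rows if any(row[i] for i in infreq))
    n_infreq = sum(freq[i] for i in infreq)
    q1 = sum(1 for i in infreq if freq[i] == 1)
    c = 1.0 - q1 / n_infreq
    if c <= 0 or m_infreq <= 1:
        return chao2_oracle(incidence_rows)
    total = sum(
        j * (j - 1) * sum(1 for i in infreq if freq[i] == j) for j in range(1, threshold + 1)
    )
    gamma2 = max(
        (s_infreq / c) * (m_infreq / (m_infreq - 1)) * total / n_infreq**2 - 1.0, 0.0
    )
    return s_freq + s_infreq / c + q1 / c * gamma2


def brillouin_oracle(counts):
    ns = [int(v) for v in counts if v > 0]
    N = sum(ns)
    return (math.lgamma(N + 1) - sum(math.lgamma(v + 1) for v in ns)) / N


def fisher_alpha_bisect(S, N, lo=1e-6, hi=1e6, tol=1e-9):
    """Bisection root of S = alpha ln(1 + N/alpha)."""
    f = lambda a: a * math.log(1 + N / a) - S
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_incidence(rng, max_m=10, max_s=20):
    """A random small incidence matrix with at least one occupied sample."""
    while True:
        m = rng.integers(2, max_m + 1)
        s = rng.integers(2, max_s + 1)
        X = (rng.random((m, s)) < rng.uniform(0.1, 0.6)).astype(int)
        if X.sum() > 0:
            return X


def random_abundance(rng, max_s=25):
    while True:
        s = rng.integers(2, max_s + 1)
        n = rng.poisson(rng.uniform(0.5, 6.0), size=s)
        if (n > 0).sum() >= 2:
            return n
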