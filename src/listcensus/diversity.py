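"""Diversity and evenness indices with leave-one-sample-out jackknife SEs.

Indices operate on integer count vectors (n_i individuals per species,
N = sum n_i, S species present):

* Fisher's alpha — the log-series parameter, the unique alpha > 0 solving
  ``S = alpha * ln(1 + N / alpha)``.
* Brillouin diversity — ``HB = (ln N! - sum ln n_i!) / N``, the exact
  diversity of a fully censused collection (well defined only for integer
  counts, hence pooled list counts / summed MaxN as inputs).
* Brillouin evenness — HB divided by the Brillouin diversity of the maximally
  even partition of N individuals into S species.
* Pielou's J — Shannon entropy over ln S.

Natural logs throughout.  ``jackknife_se`` pools per-sample count vectors,
recomputes the index leaving each sample out, and reports the first-order
jackknife standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln


def _counts(x) -> np.ndarray:
    n = np.asarray(x, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("count vector has no positive entries")
    return n


def fisher_alpha(counts) -> float:
    """Fisher's log-series alpha, solved to 1e-9 by bracketed root finding.

    Requires S >= 2 and N > S: when every individual is its own species the
    defining equation has no finite root.
    """
    n = _counts(counts)
    S = float(n.size)
    N = float(n.sum())
    if S < 2:
        raise ValueError(f"fisher_alpha requires S >= 2 (got S = {S:g})")
    if S >= N:
        raise ValueError(f"fisher_alpha requires N > S (got S = {S:g}, N = {N:g})")

    def f(alpha: float) -> float:
        return alpha * np.log1p(N / alpha) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError("fisher_alpha bracket expansion failed")
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16))


def brillouin(counts) -> float:
    """Brillouin diversity HB = (ln N! - sum ln n_i!) / N via log-gamma."""
    n = _counts(counts)
    if not np.allclose(n, np.rint(n)):
        raise ValueError("brillouin requires integer counts")
    N = n.sum()
    return float((gammaln(N + 1) - gammaln(n + 1).sum()) / N)


def brillouin_evenness(counts) -> float:
    """HB / HBmax with HBmax from the maximally even partition of N into S parts.

    The even partition has S - r parts of floor(N/S) and r = N mod S parts of
    ceil(N/S).  Undefined (raises) for S = 1, where HBmax = 0.
    """
    n = _counts(counts)
    S = n.size
    if S < 2:
        raise ValueError("brillouin_evenness undefined for a single species")
    N = int(round(n.sum()))
    q, r = divmod(N, S)
    even = np.array([q + 1] * r + [q] * (S - r), dtype=float)
    hb_max = brillouin(even)
    if hb_max == 0:
        raise ValueError("brillouin_evenness: HBmax = 0")
    return brillouin(n) / hb_max


def pielou_j(counts) -> float:
    """Pielou's evenness J = H' / ln S (Shannon entropy, natural log)."""
    n = _counts(counts)
    S = n.size
    if S < 2:
        raise ValueError("pielou_j requires S >= 2")
    p = n / n.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(S))


INDEX_FUNCS: dict[str, Callable] = {
    "fisher_alpha": fisher_alpha,
    "brillouin": brillouin,
    "brillouin_evenness": brillouin_evenness,
    "pielou_j": pielou_j,
}


@dataclass
class DiversityResult:
    index: str
    value: float
    jackknife_se: float
    m: int
    n_failed_replicates: int = 0


def jackknife_se(index, sample_counts: pd.DataFrame) -> DiversityResult:
    """First-order leave-one-sample-out jackknife SE of a pooled-count index.

    ``sample_counts`` has one row per sample (video or list) and one column
    per species.  Each replicate pools the counts omitting one sample;
    ``SE = sqrt(((m - 1)/m) * sum_i (theta_(i) - theta_bar)^2)``.  Replicates
    where the index is undefined are dropped with a warning.
    """
    fn = INDEX_FUNCS[index] if isinstance(index, str) else index
    name = index if isinstance(index, str) else getattr(index, "__name__", "index")
    m = len(sample_counts)
    if m < 2:
        raise ValueError("jackknife_se needs at least 2 samples")
    pooled = sample_counts.sum(axis=0)
    value = float(fn(pooled))
    thetas = []
    failed = 0
    for i in range(m):
        loo = pooled - sample_counts.iloc[i]
        try:
            thetas.append(float(fn(loo)))
        except ValueError:
            failed += 1
    if failed:
        warnings.warn(
            f"{name}: index undefined on {failed}/{m} leave-one-out replicates; "
            "SE computed over the defined ones",
            stacklevel=2,
        )
    thetas = np.asarray(thetas)
    m_eff = thetas.size
    if m_eff < 2:
        raise ValueError("jackknife_se: fewer than 2 defined leave-one-out replicates")
    se = float(np.sqrt((m_eff - 1) / m_eff * np.sum((thetas - thetas.mean()) ** 2)))
    return DiversityResult(name, value, se, m=m, n_failed_replicates=failed)


def diversity_table(sample_counts_by_habitat: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Habitat x index table of values and jackknife SEs.

    ``sample_counts_by_habitat`` maps a habitat label to its per-sample
    species count matrix (lists x species list-incidence counts for MLT;
    videos x species MaxN for the MaxN method).
    """
    rows = []
    for habitat, counts in sample_counts_by_habitat.items():
        for name in INDEX_FUNCS:
            try:
                res = jackknife_se(name, counts)
                rows.append((habitat, name, res.value, res.jackknife_se))
            except ValueError:
                rows.append((habitat, name, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["habitat", "index", "value", "jackknife_se"]
    ).set_index(["habitat", "index"])
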