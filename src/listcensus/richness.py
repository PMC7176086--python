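"""Species accumulation curves and nonparametric richness estimators.

Implements the classic sample-based battery used for survey-completeness
assessment: Sobs accumulation over randomised sample orders, Chao1, Chao2
(with log-normal confidence intervals), ACE, ICE, first- and second-order
jackknife, and Michaelis-Menten asymptotes (per-run and on the mean curve),
plus estimate trajectories with the final-rate-of-change stability
diagnostic.

Formula dialect
---------------
The classic "EstimateS-style" forms are used throughout:

* Chao2 carries the small-sample factor ``A = (m - 1)/m`` and switches to the
  bias-corrected branch when there are no duplicates; Chao1 likewise when
  there are no doubletons.
* ACE/ICE use a rare/infrequent threshold of 10 individuals/samples and floor
  the squared coefficient of variation at zero; a zero sample-coverage
  estimate falls back to the corresponding Chao estimator (with a warning on
  the result).
* Chao confidence intervals use the log-normal method on ``T = value - Sobs``
  with the published Chao variance formulas; when ``T = 0`` the interval
  collapses to ``[Sobs, Sobs]``.

All matrices are pandas DataFrames with samples as rows and species as
columns.  Incidence-based estimators binarise the matrix; abundance-based
estimators (Chao1, ACE) work on integer column totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .events import habitat_of
from .maxn import maxn_matrix
from .mlt import incidence_matrix, lists_for_survey

Z95 = 1.959963984540054  # two-sided 95% normal quantile

INCIDENCE_ESTIMATORS = ("Sobs", "Chao2", "ICE", "Jack1", "Jack2")
ABUNDANCE_ESTIMATORS = ("Chao1", "ACE")
ALL_ESTIMATORS = ("Sobs", "ACE", "ICE", "Chao1", "Chao2", "Jack1", "Jack2", "MMruns", "MMMeans")


@dataclass
class RichnessEstimate:
    estimator: str
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    m_used: int | None = None
    warning: str | None = None


@dataclass
class AccumulationCurve:
    """Mean observed richness after t randomly ordered samples (t = 1..m)."""

    t: np.ndarray
    s_mean: np.ndarray
    runs: np.ndarray  # (n_runs, m) per-run cumulative richness
    n_runs: int
    seed: int | None


def _as_incidence(matrix: pd.DataFrame) -> np.ndarray:
    return (matrix.to_numpy() > 0).astype(int)


def _abundance_totals(matrix: pd.DataFrame) -> np.ndarray:
    totals = np.asarray(matrix.sum(axis=0), dtype=float)
    return np.rint(totals).astype(int)


def _chao_ci(sobs: float, value: float, var: float) -> tuple[float, float]:
    """Log-normal 95% CI on T = value - Sobs (collapses to Sobs when T = 0)."""
    T = value - sobs
    if T <= 0 or var <= 0:
        return sobs, sobs
    K = np.exp(Z95 * np.sqrt(np.log(1.0 + var / T**2)))
    return sobs + T / K, sobs + T * K


def chao1(abundances) -> RichnessEstimate:
    """Chao1 abundance-based minimum richness with log-normal 95% CI.

    ``Sobs + F1^2 / (2 F2)``; when F2 = 0, the bias-corrected
    ``Sobs + F1 (F1 - 1) / 2``.  F1/F2 are singleton/doubleton counts.
    """
    n = np.asarray(abundances, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("chao1: no species with positive abundance")
    sobs = float(n.size)
    f1 = float(np.sum(n == 1))
    f2 = float(np.sum(n == 2))
    if f2 > 0:
        value = sobs + f1**2 / (2 * f2)
        r = f1 / f2
        var = f2 * (r**2 / 2 + r**3 + r**4 / 4)
    else:
        value = sobs + f1 * (f1 - 1) / 2
        var = f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4
        if value > 0:
            var -= f1**4 / (4 * value)
    lo, hi = _chao_ci(sobs, value, var)
    return RichnessEstimate("Chao1", value, lo, hi)


def chao2(matrix: pd.DataFrame) -> RichnessEstimate:
    """Chao2 incidence-based minimum richness with log-normal 95% CI.

    With m samples, Q1 uniques and Q2 duplicates, and ``A = (m - 1)/m``:
    ``Sobs + A Q1^2 / (2 Q2)``; when Q2 = 0 the bias-corrected
    ``Sobs + A Q1 (Q1 - 1) / 2``.
    """
    X = _as_incidence(matrix)
    m = X.shape[0]
    if m < 1 or X.size == 0:
        raise ValueError("chao2: empty matrix")
    freq = X.sum(axis=0)
    freq = freq[freq > 0]
    sobs = float(freq.size)
    q1 = float(np.sum(freq == 1))
    q2 = float(np.sum(freq == 2))
    A = (m - 1) / m if m > 0 else 0.0
    if q2 > 0:
        value = sobs + A * q1**2 / (2 * q2)
        r = q1 / q2
        var = q2 * (A * r**2 / 2 + A**2 * r**3 + A**2 * r**4 / 4)
    else:
        value = sobs + A * q1 * (q1 - 1) / 2
        var = A * q1 * (q1 - 1) / 2 + A**2 * q1 * (2 * q1 - 1) ** 2 / 4
        if value > 0:
            var -= A**2 * q1**4 / (4 * value)
    lo, hi = _chao_ci(sobs, value, var)
    return RichnessEstimate("Chao2", value, lo, hi, m_used=m)


def ace(abundances, rare_threshold: int = 10) -> RichnessEstimate:
    """Abundance-based coverage estimator (Chao & Lee) on species with n_i <= 10.

    ``S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2`` with sample coverage
    ``C_ace = 1 - F1 / N_rare`` and the squared coefficient of variation
    floored at zero.  If every rare individual is a singleton (C_ace = 0) the
    estimate falls back to Chao1 with a warning.
    """
    n = np.asarray(abundances, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("ace: no species with positive abundance")
    rare = n[n <= rare_threshold]
    s_abund = float(np.sum(n > rare_threshold))
    s_rare = float(rare.size)
    if s_rare == 0:
        return RichnessEstimate("ACE", float(n.size))
    n_rare = float(rare.sum())
    f1 = float(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        fb = chao1(n)
        return RichnessEstimate("ACE", fb.value, warning="C_ace = 0; fell back to Chao1")
    fk = np.array([np.sum(rare == k) for k in range(1, rare_threshold + 1)], dtype=float)
    ksum = float(np.sum(np.arange(1, rare_threshold + 1) * (np.arange(1, rare_threshold + 1) - 1) * fk))
    gamma2 = (s_rare / c_ace) * ksum / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    value = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return RichnessEstimate("ACE", value)


def ice(matrix: pd.DataFrame, infrequent_threshold: int = 10) -> RichnessEstimate:
    """Incidence-based coverage estimator on species found in <= 10 samples.

    ``S_freq + S_infreq / C_ice + (Q1 / C_ice) * gamma^2`` with
    ``C_ice = 1 - Q1 / N_infreq``; m_infreq counts samples containing at
    least one infrequent species.  C_ice = 0 falls back to Chao2.
    """
    X = _as_incidence(matrix)
    m = X.shape[0]
    if m < 1 or X.size == 0:
        raise ValueError("ice: empty matrix")
    freq = X.sum(axis=0)
    present = freq > 0
    freq = freq[present]
    infreq_mask = freq <= infrequent_threshold
    s_freq = float(np.sum(~infreq_mask))
    s_infreq = float(np.sum(infreq_mask))
    if s_infreq == 0:
        return RichnessEstimate("ICE", float(freq.size), m_used=m)
    X_infreq = X[:, np.where(present)[0][infreq_mask]]
    m_infreq = int(np.sum(X_infreq.sum(axis=1) > 0))
    n_infreq = float(X_infreq.sum())
    q1 = float(np.sum(freq[infreq_mask] == 1))
    c_ice = 1.0 - q1 / n_infreq
    if c_ice <= 0 or m_infreq <= 1:
        fb = chao2(matrix)
        return RichnessEstimate(
            "ICE", fb.value, m_used=m, warning="C_ice = 0 or single sample; fell back to Chao2"
        )
    js = np.arange(1, infrequent_threshold + 1)
    qj = np.array([np.sum(freq[infreq_mask] == j) for j in js], dtype=float)
    jsum = float(np.sum(js * (js - 1) * qj))
    gamma2 = (s_infreq / c_ice) * (m_infreq / (m_infreq - 1.0)) * jsum / n_infreq**2 - 1.0
    gamma2 = max(gamma2, 0.0)
    value = s_freq + s_infreq / c_ice + (q1 / c_ice) * gamma2
    return RichnessEstimate("ICE", value, m_used=m)


def jackknife(matrix: pd.DataFrame, order: int = 1) -> RichnessEstimate:
    """First-/second-order jackknife richness.

    ``Jack1 = Sobs + Q1 (m-1)/m``;
    ``Jack2 = Sobs + Q1 (2m-3)/m - Q2 (m-2)^2 / (m (m-1))``.
    """
    if order not in (1, 2):
        raise ValueError(f"jackknife order must be 1 or 2, got {order}")
    X = _as_incidence(matrix)
    m = X.shape[0]
    if m < order + 1:
        raise ValueError(f"jackknife order {order} needs m >= {order + 1}, got m = {m}")
    freq = X.sum(axis=0)
    freq = freq[freq > 0]
    sobs = float(freq.size)
    q1 = float(np.sum(freq == 1))
    q2 = float(np.sum(freq == 2))
    if order == 1:
        value = sobs + q1 * (m - 1) / m
    else:
        value = sobs + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))
    return RichnessEstimate(f"Jack{order}", value, m_used=m)


def sobs(matrix: pd.DataFrame) -> RichnessEstimate:
    X = _as_incidence(matrix)
    return RichnessEstimate("Sobs", float(np.sum(X.sum(axis=0) > 0)), m_used=X.shape[0])


def accumulation_curve(
    matrix: pd.DataFrame, n_runs: int = 50, seed: int | None = None
) -> AccumulationCurve:
    """Sobs accumulation over randomised sample orders.

    Each run permutes sample order uniformly at random (without replacement)
    and records cumulative distinct-species counts; the curve is the
    across-run mean — the standard sample-order randomisation used to remove
    order effects before fitting asymptotes.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    X = _as_incidence(matrix)
    m = X.shape[0]
    if m < 1:
        raise ValueError("accumulation_curve: empty matrix")
    rng = np.random.default_rng(seed)
    runs = np.empty((n_runs, m), dtype=float)
    for r in range(n_runs):
        perm = rng.permutation(m)
        seen = np.maximum.accumulate(X[perm], axis=0)
        runs[r] = seen.sum(axis=1)
    return AccumulationCurve(
        t=np.arange(1, m + 1), s_mean=runs.mean(axis=0), runs=runs, n_runs=n_runs, seed=seed
    )


def _mm_fit(t: np.ndarray, s: np.ndarray) -> float:
    """Least-squares Michaelis-Menten asymptote S(t) = Smax t / (B + t)."""
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 2:
        raise ValueError("Michaelis-Menten fit needs at least 2 points")
    if np.allclose(s, 0):
        raise ValueError("Michaelis-Menten fit undefined on a flat-zero curve")
    # analytic two-point initialisation from the first and last points
    t1, s1, t2, s2 = t[0], s[0], t[-1], s[-1]
    denom = s2 * t1 - s1 * t2
    if denom != 0 and s1 > 0 and s2 > 0:
        smax0 = s1 * s2 * (t1 - t2) / denom
        b0 = t1 * (smax0 - s1) / s1 if s1 > 0 else 1.0
        if not (np.isfinite(smax0) and smax0 > 0 and np.isfinite(b0) and b0 > 0):
            smax0, b0 = float(s.max()) * 1.5, float(t.mean())
    else:
        smax0, b0 = float(s.max()) * 1.5, float(t.mean())
    if t.size == 2:
        if denom == 0:
            raise ValueError("two-point Michaelis-Menten solve is degenerate")
        smax = s1 * s2 * (t1 - t2) / denom
        return float(smax)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            lambda tt, smax, b: smax * tt / (b + tt),
            t,
            s,
            p0=(smax0, b0),
            maxfev=20000,
        )
    return float(popt[0])


def michaelis_menten(curve: AccumulationCurve, mode: str = "means") -> RichnessEstimate:
    """Michaelis-Menten asymptotic richness.

    ``mode="means"`` fits the across-run mean curve once; ``mode="runs"``
    fits each randomised run and averages the asymptotes.
    """
    if mode == "means":
        value = _mm_fit(curve.t, curve.s_mean)
        return RichnessEstimate("MMMeans", value, m_used=int(curve.t[-1]))
    if mode == "runs":
        vals = [_mm_fit(curve.t, run) for run in curve.runs]
        return RichnessEstimate("MMRuns", float(np.mean(vals)), m_used=int(curve.t[-1]))
    raise ValueError(f"unknown Michaelis-Menten mode {mode!r}")


_INCIDENCE_FUNCS = {
    "Sobs": sobs,
    "Chao2": chao2,
    "ICE": ice,
    "Jack1": lambda m: jackknife(m, 1),
    "Jack2": lambda m: jackknife(m, 2),
}


def estimate(matrix: pd.DataFrame, estimator: str) -> RichnessEstimate:
    """Dispatch a sample x species count matrix to one named estimator.

    Incidence estimators binarise the matrix; abundance estimators (Chao1,
    ACE) use rounded integer column totals.
    """
    if estimator in _INCIDENCE_FUNCS:
        return _INCIDENCE_FUNCS[estimator](matrix)
    if estimator == "Chao1":
        return chao1(_abundance_totals(matrix))
    if estimator == "ACE":
        return ace(_abundance_totals(matrix))
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class EstimateTrajectory:
    """Estimator value after 1..m samples under a fixed sample order."""

    estimator: str
    t: np.ndarray
    values: np.ndarray  # NaN where the estimator is undefined at small t

    @property
    def final_rate(self) -> float:
        """|value(m) - value(m-1)| — the stability diagnostic."""
        if self.t.size < 2:
            raise ValueError("final_rate needs m >= 2")
        return float(abs(self.values[-1] - self.values[-2]))


def estimate_trajectory(
    matrix: pd.DataFrame, estimator: str = "Chao2", order: np.ndarray | None = None
) -> EstimateTrajectory:
    """Recompute an estimator on the first t samples for t = 1..m.

    ``order`` fixes the sample order (default: input row order).  Values
    where the estimator is undefined at small t are recorded as NaN.
    """
    m = len(matrix)
    if m < 2:
        raise ValueError("estimate_trajectory needs m >= 2")
    ordered = matrix if order is None else matrix.iloc[np.asarray(order)]
    values = np.full(m, np.nan)
    for t in range(1, m + 1):
        try:
            values[t - 1] = estimate(ordered.iloc[:t], estimator).value
        except ValueError:
            pass
    return EstimateTrajectory(estimator=estimator, t=np.arange(1, m + 1), values=values)


def final_rate_of_change(final: float, penultimate: float) -> float:
    """Stability diagnostic on a printed or computed estimate pair."""
    return float(abs(final - penultimate))


def richness_table(
    events: pd.DataFrame,
    videos: pd.DataFrame,
    method: str = "mlt",
    k: int = 5,
    gap_s: float = 180.0,
    n_runs: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Habitat x estimator richness table for one method.

    ``method="mlt"`` runs on the incidence matrix of list samples (pooled
    included); ``method="maxn"`` on the video x species MaxN matrix, with
    abundance-based estimators fed summed MaxN totals.
    """
    habitats = habitat_of(videos)
    labels = pd.Series([h.label for h in habitats], index=videos["video_id"].values)
    if method == "mlt":
        samples = lists_for_survey(events, videos, k=k, gap_s=gap_s)
        mats = {}
        for label in sorted(labels.unique()):
            hab_samples = [s for s in samples if s.habitat.label == label]
            if not hab_samples:
                raise ValueError(f"habitat {label!r} has no list samples")
            mats[label] = incidence_matrix(hab_samples, include_pooled=True)
    elif method == "maxn":
        full = maxn_matrix(events, videos)
        mats = {}
        for label in sorted(labels.unique()):
            vids = labels.index[labels == label]
            if len(vids) == 0:
                raise ValueError(f"habitat {label!r} has no videos")
            block = full.loc[vids]
            mats[label] = block.loc[:, block.sum(axis=0) > 0]
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = {}
    for label, mat in mats.items():
        row = {}
        for name in ("Sobs", "ACE", "ICE", "Chao1", "Chao2", "Jack1", "Jack2"):
            try:
                row[name] = estimate(mat, name).value
            except ValueError:
                row[name] = np.nan
        try:
            curve = accumulation_curve(mat, n_runs=n_runs, seed=seed)
            row["MMruns"] = michaelis_menten(curve, mode="runs").value
            row["MMMeans"] = michaelis_menten(curve, mode="means").value
        except ValueError:
            row["MMruns"] = np.nan
            row["MMMeans"] = np.nan
        rows[label] = row
    table = pd.DataFrame(rows).T.loc[:, list(ALL_ESTIMATORS)]
    table.index.name = "habitat"
    return table
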