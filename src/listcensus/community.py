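"""Multivariate community analysis and method-comparison statistics.

The battery here mirrors the standard distance-based workflow for abundance
tables from ecological surveys:

* square-root transform plus a constant *dummy species*, then Bray-Curtis
  dissimilarity (the zero-adjusted variant: two empty samples get distance 0
  instead of 0/0);
* PERMANOVA for mixed factorial designs with nested random factors
  (e.g. Status and Depth fixed, Site nested in Status random, and Video as an
  additional random factor when list samples are the units), with
  expected-mean-squares denominator selection, restricted permutations and a
  Monte-Carlo p-value from the asymptotic permutation distribution;
* balanced effort-reduction subsampling of videos per habitat;
* the headline method-comparison statistics: paired t-tests across habitats,
  top-k most-abundant-species overlap, and mean rank differences.

Sums of squares are partitioned from the Gower-centred distance matrix
``G = -1/2 J D^2 J``: for any grouping of samples, ``tr(H G)`` with ``H`` the
block-averaging hat matrix gives the among-group SS, and nested/factorial
terms are obtained by subtracting the SS of all marginal terms.  This is the
classical balanced decomposition; it tolerates mild imbalance.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats


# ---------------------------------------------------------------------------
# transform + distance
# ---------------------------------------------------------------------------

DUMMY_SPECIES = "__dummy__"


def transform_and_distance(
    abundance: pd.DataFrame,
    sqrt_transform: bool = True,
    dummy: bool = True,
) -> pd.DataFrame:
    """Square-root transform, append a dummy species, Bray-Curtis distances.

    The dummy species takes the constant value 1 in every sample (sqrt(1) = 1
    either way), bounding the distance between depauperate samples and making
    the distance between two all-zero samples 0 rather than undefined.
    """
    if len(abundance) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    X = abundance.to_numpy(dtype=float)
    if sqrt_transform:
        X = np.sqrt(X)
    if dummy:
        X = np.column_stack([X, np.ones(len(X))])
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=abundance.index, columns=abundance.index)


def gower_center(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J (J = I - 11'/n)."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Factor:
    """One design factor: fixed or random, optionally nested in parents."""

    name: str
    kind: str  # "fixed" | "random"
    nested_in: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("fixed", "random"):
            raise ValueError(f"factor {self.name!r}: kind must be fixed|random")


@dataclass
class DesignSpec:
    """Factors and ordered model terms for a (possibly nested) mixed design.

    Each term is a tuple of raw factor names; nesting parents are implied by
    the factor declarations, so ``("site",)`` with site nested in status means
    the term Site(Status), and ``("site", "depth")`` means Depth x Site(Status).
    """

    factors: dict[str, Factor]
    terms: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self):
        for t in self.terms:
            for f in t:
                if f not in self.factors:
                    raise ValueError(f"term {t} uses undeclared factor {f!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(name: str, trail: tuple[str, ...]) -> None:
            if state.get(name) == 1:
                return
            if state.get(name) == 0:
                raise ValueError(f"nesting is cyclic: {' -> '.join(trail + (name,))}")
            state[name] = 0
            for parent in self.factors[name].nested_in:
                if parent not in self.factors:
                    raise ValueError(
                        f"factor {name!r} nested in undeclared factor {parent!r}"
                    )
                visit(parent, trail + (name,))
            state[name] = 1

        for name in self.factors:
            visit(name, ())

    def closure(self, term: Sequence[str]) -> frozenset[str]:
        """Factors of the term plus all transitive nesting parents."""
        out = set(term)
        frontier = list(term)
        depth = 0
        while frontier:
            depth += 1
            if depth > 100:
                raise ValueError("nesting is cyclic")
            nxt = []
            for f in frontier:
                for p in self.factors[f].nested_in:
                    if p not in out:
                        out.add(p)
                        nxt.append(p)
            frontier = nxt
        return frozenset(out)

    def is_random(self, term: Sequence[str]) -> bool:
        """A term is random if any of its own factors is random."""
        return any(self.factors[f].kind == "random" for f in term)

    def descendants(self, term: Sequence[str]) -> frozenset[str]:
        """Factors nested (transitively) within any factor of the term."""
        own = set(term)
        return frozenset(
            g
            for g in self.factors
            if g not in own and (self.closure((g,)) - {g}) & own
        )

    def label(self, term: Sequence[str]) -> str:
        parts = []
        for f in term:
            parents = self.factors[f].nested_in
            parts.append(f"{f}({','.join(parents)})" if parents else f)
        return " x ".join(parts)

    @classmethod
    def three_factor(cls) -> "DesignSpec":
        """Status + Depth fixed, Site(Status) random — video-level units."""
        return cls(
            factors={
                "status": Factor("status", "fixed"),
                "depth": Factor("depth", "fixed"),
                "site": Factor("site", "random", nested_in=("status",)),
            },
            terms=[
                ("status",),
                ("depth",),
                ("status", "depth"),
                ("site",),
                ("site", "depth"),
            ],
        )

    @classmethod
    def four_factor(cls) -> "DesignSpec":
        """As three_factor plus Video(Site x Depth) random — list-level units."""
        design = cls.three_factor()
        design.factors["video"] = Factor("video", "random", nested_in=("site", "depth"))
        design.terms = design.terms + [("video",)]
        return design

    @classmethod
    def one_way(cls, factor: str = "group", kind: str = "fixed") -> "DesignSpec":
        return cls(factors={factor: Factor(factor, kind)}, terms=[(factor,)])


def _cells(meta: pd.DataFrame, factors: frozenset[str] | Sequence[str]) -> np.ndarray:
    """Integer cell codes for the partition by a set of factors."""
    cols = sorted(factors)
    if not cols:
        return np.zeros(len(meta), dtype=int)
    key = meta[cols].astype(str).agg("|".join, axis=1)
    return pd.factorize(key)[0]


def _hat(codes: np.ndarray) -> np.ndarray:
    """Block-averaging projection matrix for a partition."""
    n = len(codes)
    H = np.zeros((n, n))
    for c in np.unique(codes):
        idx = np.where(codes == c)[0]
        H[np.ix_(idx, idx)] = 1.0 / len(idx)
    return H


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms + Residual + Total; df, SS, MS, pseudo_F, denom, p_perm, p_mc
    design: DesignSpec
    n_perm: int
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n={int(self.table.loc['Total', 'df']) + 1})\n{self.table}"


def _partition_ss(
    raw_traces: dict[tuple[str, ...], np.ndarray],
    design: DesignSpec,
    total: np.ndarray,
) -> dict[str, np.ndarray]:
    """Term SS by subtracting marginal (strictly coarser) terms' SS."""
    closures = {t: design.closure(t) for t in design.terms}
    order = sorted(design.terms, key=lambda t: len(closures[t]))
    ss: dict[tuple[str, ...], np.ndarray] = {}
    for t in order:
        val = np.array(raw_traces[t], dtype=float, copy=True)
        for s in order:
            if s != t and closures[s] < closures[t]:
                val = val - ss[s]
        ss[t] = val
    out = {design.label(t): ss[t] for t in design.terms}
    out["Residual"] = total - sum(ss.values())
    return out


def _term_df(design: DesignSpec, meta: pd.DataFrame) -> dict[str, int]:
    closures = {t: design.closure(t) for t in design.terms}
    order = sorted(design.terms, key=lambda t: len(closures[t]))
    df: dict[tuple[str, ...], int] = {}
    for t in order:
        ncells = len(np.unique(_cells(meta, closures[t])))
        d = ncells - 1
        for s in order:
            if s != t and closures[s] < closures[t]:
                d -= df[s]
        df[t] = d
    out = {design.label(t): d for t, d in df.items()}
    out["Residual"] = len(meta) - 1 - sum(df.values())
    return out


def _denominator(design: DesignSpec, term: tuple[str, ...]) -> str:
    """Expected-mean-squares denominator: the lowest-order random term whose
    closure strictly contains this term's closure; otherwise the residual."""
    tc = design.closure(term)
    candidates = [
        s
        for s in design.terms
        if s != term and design.is_random(s) and tc < design.closure(s)
    ]
    if not candidates:
        return "Residual"
    candidates.sort(key=lambda s: (len(design.closure(s)), design.label(s)))
    return design.label(candidates[0])


def _perm_indices(
    design: DesignSpec,
    meta: pd.DataFrame,
    term: tuple[str, ...],
    denom_label: str,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_perm, n) permutation index arrays for testing one term.

    Residual denominator: permute samples freely within the strata defined by
    the term's nesting parents.  Random-term denominator: permute whole cells
    of the denominator term (the exchangeable units) within the strata given
    by the denominator's extra factors that are neither in the tested term
    nor nested under it; unequal cell sizes fall back to within-strata sample
    permutation.
    """
    n = len(meta)
    tc = design.closure(term)
    if denom_label == "Residual":
        strata_factors = tc - set(term)
        strata = _cells(meta, strata_factors)
        return _permute_within(strata, n_perm, rng)
    denom_term = next(t for t in design.terms if design.label(t) == denom_label)
    unit_factors = design.closure(denom_term)
    strata_factors = unit_factors - tc - design.descendants(term)
    units = _cells(meta, unit_factors)
    strata = _cells(meta, strata_factors)
    # unit sizes must be equal within each stratum for whole-unit exchange
    balanced = True
    for s in np.unique(strata):
        sizes = {np.sum(units == u) for u in np.unique(units[strata == s])}
        if len(sizes) > 1:
            balanced = False
            break
    if not balanced:
        return _permute_within(strata, n_perm, rng)
    return _permute_units(units, strata, n_perm, rng)


def _permute_within(strata: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permute sample indices independently within each stratum (vectorised)."""
    n = len(strata)
    keys = strata[None, :] + rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1, kind="stable")
    pos_sorted = np.argsort(strata, kind="stable")
    out = np.empty((n_perm, n), dtype=int)
    out[:, pos_sorted] = idx
    return out


def _permute_units(
    units: np.ndarray, strata: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permute whole equal-sized units within strata, samples riding along."""
    n = len(units)
    out = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(strata):
        in_s = np.where(strata == s)[0]
        unit_ids = np.unique(units[in_s])
        if len(unit_ids) < 2:
            continue
        unit_pos = np.array(
            [np.sort(in_s[units[in_s] == u]) for u in unit_ids]
        )  # (n_units, unit_size)
        order = np.argsort(rng.random((n_perm, len(unit_ids))), axis=1)
        new_pos = unit_pos[order]  # (n_perm, n_units, unit_size)
        out[:, unit_pos.ravel()] = new_pos.reshape(n_perm, -1)
    return out


def _traces_under_perms(
    G: np.ndarray, hats: dict, perms: np.ndarray, chunk: int = 256
) -> dict:
    """tr(H G_pi) for every hat matrix and every permutation, chunked."""
    n_perm = perms.shape[0]
    out = {t: np.empty(n_perm) for t in hats}
    for start in range(0, n_perm, chunk):
        idx = perms[start : start + chunk]
        Gp = G[idx[:, :, None], idx[:, None, :]]  # (chunk, n, n)
        for t, H in hats.items():
            out[t][start : start + len(idx)] = np.einsum("ij,pij->p", H, Gp)
    return out


def permanova(
    dist: pd.DataFrame,
    design: DesignSpec,
    meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    mc_draws: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA for a declared mixed/nested design.

    ``meta`` maps each sample (rows aligned with ``dist``) to its factor
    levels.  Pseudo-F uses expected-mean-squares denominators; ``p_perm``
    comes from ``n_perm`` restricted permutations per term, reported as
    ``(b + 1) / (n_perm + 1)``; ``p_mc > 0`` draws additionally sample the
    asymptotic permutation distribution (chi-square mixtures over the
    eigenvalues of G).
    """
    ids = list(dist.index)
    meta = meta.loc[ids]
    n = len(ids)
    G = gower_center(dist)
    total_ss = float(np.trace(G))

    # terms that lose all their df under the realised (possibly reduced)
    # design are confounded with coarser terms: drop them, coarsest first,
    # until every remaining term is estimable
    full_terms = list(design.terms)
    dropped: list[str] = []
    work = design
    for _ in range(len(full_terms)):
        dfs = _term_df(work, meta)
        bad = [t for t in work.terms if dfs[work.label(t)] <= 0]
        if not bad:
            break
        for t in bad:
            dropped.append(work.label(t))
        work = DesignSpec(
            factors=work.factors, terms=[t for t in work.terms if t not in bad]
        )
    if dropped:
        warnings.warn(
            f"dropped inestimable term(s) under this design: {dropped}", stacklevel=2
        )
    design = work
    dfs = _term_df(design, meta)

    hats = {t: _hat(_cells(meta, design.closure(t))) for t in design.terms}
    raw = {t: float(np.einsum("ij,ij->", hats[t], G)) for t in design.terms}
    ss = {k: float(v[0]) for k, v in _partition_ss(
        {t: np.array([raw[t]]) for t in design.terms}, design, np.array([total_ss])
    ).items()}

    ms = {lbl: (ss[lbl] / dfs[lbl] if dfs[lbl] > 0 else np.nan) for lbl in ss}
    denom = {design.label(t): _denominator(design, t) for t in design.terms}

    rng = np.random.default_rng(seed)
    eigvals = None
    if mc_draws:
        eigvals = np.linalg.eigvalsh(G)
        eigvals = eigvals[np.abs(eigvals) > 1e-10 * max(np.abs(eigvals).max(), 1e-300)]

    rows = []
    for t in design.terms:
        lbl = design.label(t)
        d_lbl = denom[lbl]
        if dfs[d_lbl] <= 0 or not np.isfinite(ms[d_lbl]):
            rows.append((lbl, dfs[lbl], ss[lbl], ms[lbl], np.nan, d_lbl, np.nan, np.nan))
            continue
        f_obs = ms[lbl] / ms[d_lbl]
        p_perm = np.nan
        if n_perm > 0:
            perms = _perm_indices(design, meta, t, d_lbl, n_perm, rng)
            raw_p = _traces_under_perms(G, hats, perms)
            ss_p = _partition_ss(raw_p, design, np.full(n_perm, total_ss))
            num = ss_p[lbl] / dfs[lbl]
            den = ss_p[d_lbl] / dfs[d_lbl]
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm = num / den
            b = int(np.sum(f_perm >= f_obs - 1e-12))
            p_perm = (b + 1) / (n_perm + 1)
        p_mc = (
            monte_carlo_p(eigvals, dfs[lbl], dfs[d_lbl], f_obs, n_draws=mc_draws, rng=rng)
            if mc_draws
            else np.nan
        )
        rows.append((lbl, dfs[lbl], ss[lbl], ms[lbl], f_obs, d_lbl, p_perm, p_mc))

    for lbl in dropped:
        rows.append((lbl, 0, 0.0, np.nan, np.nan, "(dropped)", np.nan, np.nan))
    rows.append(("Residual", dfs["Residual"], ss["Residual"], ms["Residual"],
                 np.nan, "", np.nan, np.nan))
    rows.append(("Total", n - 1, total_ss, np.nan, np.nan, "", np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "pseudo_F", "denom", "p_perm", "p_mc"]
    ).set_index("term")
    return PermanovaResult(table=table, design=design, n_perm=n_perm, seed=seed)


def monte_carlo_p(
    eigvals: np.ndarray,
    df_num: int,
    df_den: int,
    f_obs: float,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo p-value from the asymptotic permutation distribution.

    Under the null the numerator and denominator sums of squares behave
    asymptotically as mixtures of independent chi-squares weighted by the
    eigenvalues of the Gower-centred matrix; with a single eigenvalue
    (univariate Euclidean data) the simulated ratio is exactly F-distributed.
    """
    if eigvals is None or len(eigvals) == 0:
        raise ValueError("monte_carlo_p: degenerate (rank-0) distance matrix")
    if rng is None:
        rng = np.random.default_rng()
    lam = np.asarray(eigvals, dtype=float)
    k = lam.size
    num = (rng.chisquare(df_num, size=(n_draws, k)) @ lam) / df_num
    den = (rng.chisquare(df_den, size=(n_draws, k)) @ lam) / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f_sim = num / den
    f_sim = f_sim[np.isfinite(f_sim)]
    b = int(np.sum(f_sim >= f_obs - 1e-12))
    return (b + 1) / (len(f_sim) + 1)


# ---------------------------------------------------------------------------
# effort reduction and method comparison
# ---------------------------------------------------------------------------


def reduce_effort(
    videos: pd.DataFrame, n_per_habitat: int, seed: int | None = None
) -> pd.DataFrame:
    """Uniform random balanced subset of videos: n per habitat.

    The returned subset is meant to be used identically for the MLT and MaxN
    pipelines, so reduced-effort comparisons share deployments.
    """
    from .events import ALL_HABITATS, habitat_of

    rng = np.random.default_rng(seed)
    labels = pd.Series([h.label for h in habitat_of(videos)], index=videos.index)
    keep: list[int] = []
    for habitat in ALL_HABITATS:
        idx = labels.index[labels == habitat.label].to_numpy()
        if len(idx) < n_per_habitat:
            raise ValueError(
                f"habitat {habitat.label!r} has only {len(idx)} videos (< {n_per_habitat})"
            )
        keep.extend(rng.choice(idx, size=n_per_habitat, replace=False))
    return videos.loc[sorted(keep)].reset_index(drop=True)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired two-sided t-test on per-habitat method values.

    Returns (t, df, p) with ``t = mean(d) / (sd(d)/sqrt(n))`` on the
    differences d = x - y (sample sd, ddof 1), df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired_t: zero-variance differences, t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def _top_k(counts: Mapping[str, float], k: int) -> list[str]:
    """k largest positive values; ties broken by descending value then name."""
    positive = [(sp, v) for sp, v in counts.items() if v > 0]
    positive.sort(key=lambda item: (-item[1], item[0]))
    return [sp for sp, _ in positive[: min(k, len(positive))]]


def top_k_overlap(
    counts_a: Mapping[str, float], counts_b: Mapping[str, float], k: int = 10
) -> int:
    """Size of the intersection of the two methods' top-k species sets."""
    return len(set(_top_k(counts_a, k)) & set(_top_k(counts_b, k)))


def mean_rank_difference(
    counts_a: Mapping[str, float], counts_b: Mapping[str, float], k: int = 10
) -> float:
    """Mean |rank_A - rank_B| over species in both methods' top-k sets.

    Ranks are 1-based positions in each method's own descending-value order
    (same tie policy as :func:`top_k_overlap`).
    """
    top_a = _top_k(counts_a, k)
    top_b = _top_k(counts_b, k)
    shared = set(top_a) & set(top_b)
    if not shared:
        raise ValueError("mean_rank_difference: top-k sets do not intersect")
    rank_a = {sp: i + 1 for i, sp in enumerate(top_a)}
    rank_b = {sp: i + 1 for i, sp in enumerate(top_b)}
    return float(np.mean([abs(rank_a[sp] - rank_b[sp]) for sp in sorted(shared)]))
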