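import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from listcensus.community import (
    DesignSpec,
    Factor,
    gower_center,
    mean_rank_difference,
    monte_carlo_p,
    paired_t,
    permanova,
    reduce_effort,
    top_k_overlap,
    transform_and_distance,
)

from conftest import make_videos


def euclid_dist(y):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    return pd.DataFrame(squareform(pdist(y)))


class TestTransformAndDistance:
    def test_identical_samples_distance_zero(self):
        ab = pd.DataFrame([[3, 1, 0], [3, 1, 0]])
        d = transform_and_distance(ab)
        assert d.iloc[0, 1] == 0.0

    def test_plain_bray_curtis_kernel_hand_value(self):
        ab = pd.DataFrame([[1, 2], [2, 1]])
        d = transform_and_distance(ab, sqrt_transform=False, dummy=False)
        assert d.iloc[0, 1] == pytest.approx(2 / 6)

    def test_dummy_gives_zero_distance_between_empty_samples(self):
        ab = pd.DataFrame([[0, 0], [0, 0], [1, 4]])
        d = transform_and_distance(ab)
        assert d.iloc[0, 1] == 0.0
        assert np.isfinite(d.values).all()

    def test_matrix_properties(self, rng):
        ab = pd.DataFrame(rng.poisson(2.0, size=(10, 6)))
        d = transform_and_distance(ab)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()


class TestPermanova:
    def test_one_way_pseudo_f_equals_classical_anova(self, rng):
        y = rng.normal(size=15)
        groups = np.repeat(list("abc"), 5)
        res = permanova(
            euclid_dist(y),
            DesignSpec.one_way(),
            pd.DataFrame({"group": groups}),
            n_perm=99,
            seed=0,
        )
        f_classic = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res.table.loc["group", "pseudo_F"] == pytest.approx(f_classic, abs=1e-9)

    def test_agrees_with_skbio_permanova(self, rng):
        skbio = pytest.importorskip("skbio")
        y = rng.poisson(3.0, size=(12, 5)).astype(float)
        d = transform_and_distance(pd.DataFrame(y))
        groups = np.repeat(["x", "y", "z"], 4)
        res = permanova(
            d, DesignSpec.one_way(), pd.DataFrame({"group": groups}), n_perm=0, seed=0
        )
        dm = skbio.DistanceMatrix(d.values)
        ref = skbio.stats.distance.permanova(dm, grouping=list(groups), permutations=0)
        assert res.table.loc["group", "pseudo_F"] == pytest.approx(
            ref["test statistic"], abs=1e-9
        )

    def test_total_ss_obeys_gower_identity(self, rng):
        ab = pd.DataFrame(rng.poisson(2.0, size=(9, 7)))
        d = transform_and_distance(ab)
        G = gower_center(d)
        n = len(d)
        assert np.trace(G) == pytest.approx(
            (squareform(d.values) ** 2).sum() / n, abs=1e-10
        )

    def test_df_ledger_sums_to_n_minus_one(self, small_survey):
        import listcensus as lc
        from listcensus.cli import _permanova_inputs

        events, videos, _ = small_survey
        for method in ("maxn", "mlt"):
            dist, design, meta = _permanova_inputs(events, videos, method, 5, 180.0)
            res = lc.permanova(dist, design, meta, n_perm=19, seed=0)
            tbl = res.table
            n = len(dist)
            assert tbl.drop("Total")["df"].sum() == n - 1 == tbl.loc["Total", "df"]
            assert tbl.drop("Total")["SS"].sum() == pytest.approx(
                tbl.loc["Total", "SS"], abs=1e-8
            )

    def test_permutation_p_is_seeded_and_in_unit_interval(self, rng):
        y = rng.normal(size=12)
        meta = pd.DataFrame({"group": np.repeat(["a", "b"], 6)})
        r1 = permanova(euclid_dist(y), DesignSpec.one_way(), meta, n_perm=199, seed=5)
        r2 = permanova(euclid_dist(y), DesignSpec.one_way(), meta, n_perm=199, seed=5)
        p = r1.table.loc["group", "p_perm"]
        assert 0 < p <= 1
        assert p == r2.table.loc["group", "p_perm"]

    def test_relabelling_invariance(self, rng):
        y = rng.normal(size=12)
        meta = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 4)})
        d = euclid_dist(y)
        perm = rng.permutation(12)
        d2 = pd.DataFrame(d.values[np.ix_(perm, perm)])
        meta2 = meta.iloc[perm].reset_index(drop=True)
        r1 = permanova(d, DesignSpec.one_way(), meta, n_perm=0, seed=0)
        r2 = permanova(d2, DesignSpec.one_way(), meta2, n_perm=0, seed=0)
        assert r1.table.loc["group", "pseudo_F"] == pytest.approx(
            r2.table.loc["group", "pseudo_F"], abs=1e-9
        )


class TestMonteCarloP:
    def test_univariate_limit_matches_classical_f(self, rng):
        y = rng.normal(size=18)
        groups = np.repeat(list("abc"), 6)
        d = euclid_dist(y)
        res = permanova(
            d,
            DesignSpec.one_way(),
            pd.DataFrame({"group": groups}),
            n_perm=0,
            seed=1,
            mc_draws=20000,
        )
        f = res.table.loc["group", "pseudo_F"]
        p_classic = stats.f.sf(f, 2, 15)
        assert res.table.loc["group", "p_mc"] == pytest.approx(p_classic, abs=0.01)

    def test_mc_and_permutation_p_agree_on_well_permuted_design(self, rng):
        y = rng.poisson(2.0, size=(16, 6)).astype(float)
        y[:8] += rng.poisson(1.0, size=(8, 6))
        d = transform_and_distance(pd.DataFrame(y))
        meta = pd.DataFrame({"group": np.repeat(["a", "b"], 8)})
        res = permanova(d, DesignSpec.one_way(), meta, n_perm=999, seed=2, mc_draws=5000)
        assert abs(
            res.table.loc["group", "p_perm"] - res.table.loc["group", "p_mc"]
        ) < 0.05

    def test_seeded_repeat_identical(self, rng):
        lam = np.array([2.0, 1.0, 0.5])
        r1 = monte_carlo_p(lam, 2, 9, 1.7, n_draws=500, rng=np.random.default_rng(9))
        r2 = monte_carlo_p(lam, 2, 9, 1.7, n_draws=500, rng=np.random.default_rng(9))
        assert r1 == r2

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_p(np.array([]), 1, 2, 1.0)


class TestNestedDesign:
    def test_ems_denominators_follow_declared_structure(self):
        design = DesignSpec.four_factor()
        from listcensus.community import _denominator

        assert _denominator(design, ("status",)) == "site(status)"
        assert _denominator(design, ("depth",)) == "site(status) x depth"
        assert _denominator(design, ("status", "depth")) == "site(status) x depth"
        assert _denominator(design, ("site", "depth")) == "video(site,depth)"
        assert _denominator(design, ("video",)) == "Residual"

    def test_cyclic_nesting_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            DesignSpec(
                factors={
                    "a": Factor("a", "random", nested_in=("b",)),
                    "b": Factor("b", "random", nested_in=("a",)),
                },
                terms=[("a",)],
            )


class TestEffortReduction:
    def videos(self):
        rows = []
        for status in ("fished", "roa"):
            for depth in ("deep", "shallow"):
                for i in range(4):
                    rows.append(
                        (f"v_{status[0]}{depth[0]}{i}", f"s_{status[0]}", status, depth, 3600)
                    )
        return make_videos(rows)

    def test_balanced_subset_of_requested_size(self):
        sub = reduce_effort(self.videos(), 2, seed=0)
        assert len(sub) == 8
        counts = sub.groupby(["status", "depth_class"]).size()
        assert (counts == 2).all()
        assert set(sub["video_id"]) <= set(self.videos()["video_id"])

    def test_same_seed_same_subset(self):
        s1 = reduce_effort(self.videos(), 3, seed=7)
        s2 = reduce_effort(self.videos(), 3, seed=7)
        pd.testing.assert_frame_equal(s1, s2)

    def test_insufficient_videos_names_the_habitat(self):
        vids = self.videos()
        vids = vids[~((vids.status == "roa") & (vids.depth_class == "deep"))]
        with pytest.raises(ValueError, match="Deep ROA"):
            reduce_effort(vids, 2, seed=0)


class TestPairedT:
    def test_against_scipy(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        t, df, p = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert df == 5

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])


class TestTopK:
    def test_identical_tables_full_overlap_zero_rank_difference(self):
        counts = {f"sp{i}": 20 - i for i in range(15)}
        assert top_k_overlap(counts, dict(counts), k=10) == 10
        assert mean_rank_difference(counts, dict(counts), k=10) == 0.0

    def test_single_adjacent_swap_gives_point_two(self):
        a = {f"sp{i}": 20 - i for i in range(10)}
        b = dict(a)
        b["sp3"], b["sp4"] = a["sp4"], a["sp3"]
        assert mean_rank_difference(a, b, k=10) == pytest.approx(0.2)

    def test_k_truncates_to_available_positive_species(self):
        a = {"x": 3.0, "y": 1.0, "z": 0.0}
        b = {"x": 2.0, "y": 5.0, "w": 0.0}
        assert top_k_overlap(a, b, k=10) == 2

    def test_disjoint_top_sets_rejected_for_rank_difference(self):
        with pytest.raises(ValueError):
            mean_rank_difference({"a": 2.0}, {"b": 3.0}, k=5)
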