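import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from listcensus.richness import (
    accumulation_curve,
    ace,
    chao1,
    chao2,
    estimate,
    estimate_trajectory,
    final_rate_of_change,
    ice,
    jackknife,
    michaelis_menten,
    richness_table,
)

import _oracles as oracle


def inc(rows):
    return pd.DataFrame(rows)


class TestChao:
    def test_chao2_hand_value_with_duplicates(self):
        # Sobs=10, m=10, Q1=4, Q2=2 -> 10 + 0.9 * 16 / 4 = 13.6
        X = np.zeros((10, 10), dtype=int)
        for j in range(10):  # all species present somewhere
            X[j % 10, j] = 1
        # species 0..3 unique; 4,5 in two samples; 6..9 in three
        X[:, :] = 0
        for j in range(4):
            X[j, j] = 1
        for j in (4, 5):
            X[[j, (j + 1) % 10], j] = 1
        for j in range(6, 10):
            X[[j % 10, (j + 1) % 10, (j + 2) % 10], j] = 1
        est = chao2(inc(X))
        assert est.value == pytest.approx(13.6)
        assert est.ci_low <= est.value <= est.ci_high

    def test_chao2_bias_corrected_branch_when_no_duplicates(self):
        # Sobs=8, m=5, Q1=3, Q2=0 -> 8 + 0.8 * 3 * 2 / 2 = 10.4
        X = np.zeros((5, 8), dtype=int)
        for j in range(3):
            X[j, j] = 1
        for j in range(3, 8):
            X[:3, j] = 1
        est = chao2(inc(X))
        assert est.value == pytest.approx(10.4)

    def test_chao2_no_uniques_collapses_to_sobs_with_point_ci(self):
        X = np.ones((4, 6), dtype=int)
        est = chao2(inc(X))
        assert est.value == 6 == est.ci_low == est.ci_high

    def test_chao1_hand_values_both_branches(self):
        # Sobs=12, F1=5, F2=2 -> 12 + 25/4 = 18.25
        counts = [1] * 5 + [2] * 2 + [5] * 5
        assert chao1(counts).value == pytest.approx(18.25)
        # Sobs=7, F1=2, F2=0 -> 7 + 1 = 8
        assert chao1([1, 1, 3, 4, 5, 6, 7]).value == pytest.approx(8.0)

    def test_chao1_no_singletons_equals_sobs(self):
        assert chao1([3, 4, 5]).value == 3

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            chao1([0, 0])
        with pytest.raises(ValueError):
            chao2(inc(np.zeros((0, 3), dtype=int)))


class TestCoverageEstimators:
    def test_ace_all_abundant_equals_sobs(self):
        assert ace([11, 12, 50]).value == 3

    def test_ace_matches_published_formula_on_worked_vector(self):
        counts = [1, 1, 2, 3, 15]
        assert ace(counts).value == pytest.approx(oracle.ace_oracle(counts), abs=1e-12)

    def test_ace_all_singletons_falls_back_to_chao1(self):
        est = ace([1, 1, 1])
        assert est.warning is not None
        assert est.value == chao1([1, 1, 1]).value

    def test_ice_all_frequent_equals_sobs(self):
        X = np.ones((12, 4), dtype=int)
        assert ice(inc(X)).value == 4

    def test_ice_matches_published_formula_on_small_matrix(self):
        # 6 samples, Q-profile Q1=3, Q2=2, Q3=1
        X = np.zeros((6, 6), dtype=int)
        for j in range(3):
            X[j, j] = 1
        X[[0, 1], 3] = 1
        X[[2, 3], 4] = 1
        X[[0, 2, 4], 5] = 1
        assert ice(inc(X)).value == pytest.approx(oracle.ice_oracle(X.tolist()), abs=1e-12)

    def test_ice_single_sample_takes_fallback(self):
        X = np.ones((1, 5), dtype=int)
        est = ice(inc(X))
        assert est.warning is not None


class TestJackknife:
    def test_hand_values(self):
        rng = np.random.default_rng(0)
        # Build m=10 incidence with Sobs=10, Q1=4, Q2=2 exactly (rest Q3)
        X = np.zeros((10, 10), dtype=int)
        for j in range(4):
            X[j, j] = 1
        for j in (4, 5):
            X[[0, 1], j] = 1
        for j in range(6, 10):
            X[[2, 3, 4], j] = 1
        assert jackknife(inc(X), 1).value == pytest.approx(13.6)
        assert jackknife(inc(X), 2).value == pytest.approx(10 + 4 * 17 / 10 - 2 * 64 / 90)

    def test_no_rare_species_returns_sobs_both_orders(self):
        X = np.ones((5, 3), dtype=int)
        assert jackknife(inc(X), 1).value == 3
        assert jackknife(inc(X), 2).value == 3

    def test_insufficient_samples_rejected(self):
        X = np.ones((2, 3), dtype=int)
        with pytest.raises(ValueError):
            jackknife(inc(X), 2)


class TestOracleEquivalence:
    def test_incidence_estimators_match_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            X = oracle.random_incidence(rng)
            m = inc(X)
            assert chao2(m).value == pytest.approx(oracle.chao2_oracle(X.tolist()), abs=1e-9)
            assert ice(m).value == pytest.approx(oracle.ice_oracle(X.tolist()), abs=1e-9)
            if X.shape[0] >= 3:
                assert jackknife(m, 1).value == pytest.approx(
                    oracle.jack1_oracle(X.tolist()), abs=1e-9
                )
                assert jackknife(m, 2).value == pytest.approx(
                    oracle.jack2_oracle(X.tolist()), abs=1e-9
                )

    def test_abundance_estimators_match_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            n = oracle.random_abundance(rng)
            assert chao1(n).value == pytest.approx(oracle.chao1_oracle(n), abs=1e-9)
            assert ace(n).value == pytest.approx(oracle.ace_oracle(n), abs=1e-9)

    def test_rare_class_empty_limit_all_estimators_equal_sobs(self):
        # every species in >= 3 samples but <= 10: no uniques/duplicates/
        # singletons/doubletons, so Chao and jackknife collapse to Sobs
        X = np.zeros((8, 5), dtype=int)
        X[:4, :] = 1
        m = inc(X)
        for name in ("Chao2", "Jack1", "Jack2"):
            assert estimate(m, name).value == 5
        counts = m.sum(axis=0)
        assert chao1(counts).value == 5

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_estimators_match_vegan(self, rng, tmp_path):
        """Cross-check against an independent community-ecology implementation."""
        X = oracle.random_incidence(rng, max_m=12, max_s=30)
        counts = rng.poisson(2.5, size=25) + (rng.random(25) < 0.3)
        counts = counts.astype(int)
        counts[0] = max(counts[0], 1)
        np.savetxt(tmp_path / "inc.csv", X, fmt="%d", delimiter=",")
        np.savetxt(tmp_path / "ab.csv", counts[None, :], fmt="%d", delimiter=",")
        script = f"""
        suppressMessages(library(vegan))
        X <- as.matrix(read.csv("{tmp_path}/inc.csv", header=FALSE))
        ab <- as.numeric(read.csv("{tmp_path}/ab.csv", header=FALSE))
        sp <- specpool(X)
        er <- estimateR(ab)
        cat(jsonlite::toJSON(list(chao2=sp$chao, jack1=sp$jack1, jack2=sp$jack2,
            ace=unname(er["S.ACE"]))))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        m = inc(X)
        assert chao2(m).value == pytest.approx(ref["chao2"][0], abs=1e-3)
        assert jackknife(m, 1).value == pytest.approx(ref["jack1"][0], abs=1e-3)
        assert jackknife(m, 2).value == pytest.approx(ref["jack2"][0], abs=1e-3)
        assert ace(counts).value == pytest.approx(ref["ace"][0], abs=1e-3)


class TestAccumulation:
    def test_identical_samples_give_flat_curve(self):
        X = np.tile([1, 1, 0, 1], (6, 1))
        curve = accumulation_curve(inc(X), n_runs=10, seed=1)
        assert np.allclose(curve.s_mean, 3)

    def test_final_point_equals_sobs_for_every_seed(self, rng):
        for seed in rng.integers(0, 2**31 - 1, size=5):
            X = oracle.random_incidence(rng)
            curve = accumulation_curve(inc(X), n_runs=20, seed=int(seed))
            assert curve.s_mean[-1] == (X.sum(axis=0) > 0).sum()
            assert (np.diff(curve.s_mean) >= -1e-12).all()

    def test_same_seed_reproduces_curve(self, rng):
        X = oracle.random_incidence(rng)
        c1 = accumulation_curve(inc(X), n_runs=30, seed=7)
        c2 = accumulation_curve(inc(X), n_runs=30, seed=7)
        assert np.array_equal(c1.runs, c2.runs)

    def test_n_runs_below_one_rejected(self):
        with pytest.raises(ValueError):
            accumulation_curve(inc(np.ones((3, 2), dtype=int)), n_runs=0)


class TestMichaelisMenten:
    def test_recovers_exact_hyperbola(self):
        t = np.arange(1, 30)
        s = 50.0 * t / (3.0 + t)
        from listcensus.richness import AccumulationCurve

        curve = AccumulationCurve(t=t, s_mean=s, runs=np.tile(s, (3, 1)), n_runs=3, seed=0)
        assert michaelis_menten(curve, "means").value == pytest.approx(50.0, abs=1e-6)
        assert michaelis_menten(curve, "runs").value == pytest.approx(50.0, abs=1e-6)

    def test_two_point_algebraic_solution(self):
        from listcensus.richness import AccumulationCurve

        t = np.array([1, 2])
        s = np.array([5.0, 8.0])  # hyperbola through both: Smax = 20, B = 3
        curve = AccumulationCurve(t=t, s_mean=s, runs=s[None, :], n_runs=1, seed=0)
        assert michaelis_menten(curve, "means").value == pytest.approx(20.0)

    def test_flat_zero_curve_rejected(self):
        from listcensus.richness import AccumulationCurve

        t = np.arange(1, 5)
        curve = AccumulationCurve(
            t=t, s_mean=np.zeros(4), runs=np.zeros((2, 4)), n_runs=2, seed=0
        )
        with pytest.raises(ValueError):
            michaelis_menten(curve, "means")


class TestTrajectory:
    def test_final_rate_on_published_estimate_pairs(self):
        assert final_rate_of_change(97.00, 93.18) == pytest.approx(3.82)
        assert final_rate_of_change(39.04, 39.21) == pytest.approx(0.17)

    def test_constant_trajectory_has_zero_final_rate(self):
        X = np.ones((6, 4), dtype=int)
        traj = estimate_trajectory(inc(X), "Chao2")
        assert traj.final_rate == 0.0

    def test_trajectory_tracks_prefix_estimates(self, rng):
        X = oracle.random_incidence(rng, max_m=8)
        m = inc(X)
        traj = estimate_trajectory(m, "Chao2")
        assert traj.values[-1] == pytest.approx(chao2(m).value)
        assert traj.values[-2] == pytest.approx(chao2(m.iloc[:-1]).value)


class TestRichnessTable:
    def test_four_by_nine_table_with_chao_jack_above_sobs(self, small_survey):
        events, videos, _ = small_survey
        for method in ("mlt", "maxn"):
            table = richness_table(events, videos, method=method, n_runs=10, seed=3)
            assert table.shape == (4, 9)
            for name in ("Chao2", "Jack1", "Jack2", "Chao1"):
                ok = table[name] >= table["Sobs"] - 1e-9
                assert ok[table[name].notna()].all()

    def test_mlt_with_pooled_sobs_at_least_complete_only(self, small_survey):
        from listcensus.mlt import incidence_matrix, lists_for_survey

        events, videos, _ = small_survey
        samples = lists_for_survey(events, videos)
        with_pooled = incidence_matrix(samples, include_pooled=True)
        without = incidence_matrix(samples, include_pooled=False)
        assert (with_pooled.sum(0) > 0).sum() >= (without.sum(0) > 0).sum()
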