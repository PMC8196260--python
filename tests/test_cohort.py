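"""Cohort-level scoring: composite, imputation, adjustment, tests, groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from axispls import cohort as ch
from axispls import pls
from axispls.synthgen import gen_memory_trials

from conftest import make_cohort, seed_map_stack


def trial_table(rows):
    """rows: dict of task -> list of (t1, t2) tuples per subject."""
    data = {}
    for task, pairs in rows.items():
        data[f"{task}_t1"] = [p[0] for p in pairs]
        data[f"{task}_t2"] = [p[1] for p in pairs]
    return pd.DataFrame(data)


class TestCompositeMemory:
    def test_sample_mean_50_sd_10(self):
        trials = gen_memory_trials(80, seed=1)
        comp = ch.composite_memory(trials)
        assert comp.mean() == pytest.approx(50.0, abs=1e-9)
        assert comp.std(ddof=1) == pytest.approx(10.0, abs=1e-9)

    def test_subject_at_task_means_scores_50(self):
        trials = trial_table({
            "word": [(10, 12), (14, 16), (12, 14)],
            "numword": [(4, 6), (8, 6), (6, 6)],
            "objloc": [(6, 8), (10, 12), (8, 10)],
        })
        comp = ch.composite_memory(trials)
        # subject 2 sits at the mean of every task sum
        assert comp.iloc[2] == pytest.approx(50.0, abs=1e-9)

    def test_matches_spreadsheet_oracle(self):
        """Five-subject toy table against step-by-step arithmetic."""
        trials = trial_table({
            "word": [(10, 11), (12, 15), (8, 9), (14, 16), (11, 12)],
            "numword": [(3, 5), (6, 7), (2, 4), (7, 8), (5, 5)],
            "objloc": [(6, 7), (9, 10), (5, 6), (11, 12), (7, 9)],
        })
        comp = ch.composite_memory(trials)
        sums = {t: np.array([trials[f"{t}_t1"][i] + trials[f"{t}_t2"][i] for i in range(5)],
                            dtype=float) for t in ("word", "numword", "objloc")}
        zbar = np.zeros(5)
        for t, s in sums.items():
            zbar += (s - s.mean()) / s.std(ddof=1)
        zbar /= 3.0
        expected = 50.0 + 10.0 * (zbar - zbar.mean()) / zbar.std(ddof=1)
        np.testing.assert_allclose(comp.to_numpy(), expected, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 40))
    def test_transform_invariant_property(self, seed, n):
        trials = gen_memory_trials(n, seed=seed)
        sums = ch.task_sums(trials)
        if (sums.std(ddof=1) == 0).any():
            return  # degenerate draw handled by the error path
        comp = ch.composite_memory(trials)
        assert comp.mean() == pytest.approx(50.0, abs=1e-9)
        assert comp.std(ddof=1) == pytest.approx(10.0, abs=1e-9)

    def test_zero_variance_task_names_task(self):
        trials = trial_table({
            "word": [(10, 10), (10, 10), (10, 10)],
            "numword": [(3, 5), (6, 7), (2, 4)],
            "objloc": [(6, 7), (9, 10), (5, 6)],
        })
        with pytest.raises(ValueError, match="word"):
            ch.composite_memory(trials)


class TestImputation:
    def test_no_missing_is_identity(self):
        trials = gen_memory_trials(10, seed=2)
        out, log = ch.impute_missing(trials)
        pd.testing.assert_frame_equal(out, trials)
        assert log["n_missing"].sum() == 0

    def test_single_missing_gets_observed_mean(self):
        df = pd.DataFrame({"word_t1": [10.0, 12.0, 14.0, np.nan]})
        out, log = ch.impute_missing(df)
        assert out["word_t1"].iloc[3] == pytest.approx(12.0)
        assert log.loc[0, "n_missing"] == 1

    def test_generator_missingness_fully_repaired(self):
        trials = gen_memory_trials(170, seed=3, missing_rate=0.01)
        planted = int(trials.isna().sum().sum())
        out, log = ch.impute_missing(trials)
        assert out.isna().sum().sum() == 0
        assert int(log["n_missing"].sum()) == planted

    def test_entirely_missing_column_rejected(self):
        df = pd.DataFrame({"word_t1": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            ch.impute_missing(df)


class TestIcvAdjust:
    def test_subject_at_mean_icv_unchanged(self):
        icv = np.array([1.0e6, 1.2e6, 1.4e6, 1.2e6])
        raw = np.array([500.0, 530.0, 560.0, 540.0])
        adj = ch.icv_adjust(raw, icv)
        # subjects 1 and 3 sit exactly at the mean ICV
        assert adj[1] == pytest.approx(raw[1])
        assert adj[3] == pytest.approx(raw[3])

    def test_uncorrelated_volume_unchanged(self):
        icv = np.array([1.0, 2.0, 3.0, 4.0])
        raw = np.array([5.0, 7.0, 7.0, 5.0])  # slope zero by construction
        np.testing.assert_allclose(ch.icv_adjust(raw, icv), raw, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        icv = 1.4e6 + 1e5 * rng.standard_normal(4)
        raw = 500 + 0.001 * icv + 20 * rng.standard_normal(4)
        n = 4
        b = (n * np.sum(icv * raw) - icv.sum() * raw.sum()) / (
            n * np.sum(icv**2) - icv.sum() ** 2
        )
        expected = raw - b * (icv - icv.mean())
        np.testing.assert_allclose(ch.icv_adjust(raw, icv), expected, atol=1e-8)

    def test_adjusted_uncorrelated_with_icv(self):
        rng = np.random.default_rng(2)
        icv = 1.5e6 + 1.5e5 * rng.standard_normal(50)
        raw = 520 + 3e-4 * icv + 50 * rng.standard_normal(50)
        adj = ch.icv_adjust(raw, icv)
        assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10

    def test_zero_icv_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ch.icv_adjust(np.array([1.0, 2.0, 3.0]), np.full(3, 1e6))


class TestResidualize:
    def test_orthogonal_nuisance_is_identity(self):
        t = np.arange(8, dtype=float)
        values = np.cos(2 * np.pi * t / 8)
        nuisance = np.sin(2 * np.pi * t / 8)[:, None]  # orthogonal, zero-mean
        np.testing.assert_allclose(ch.residualize(values, nuisance), values, atol=1e-10)

    def test_exact_linear_function_collapses_to_mean(self):
        rng = np.random.default_rng(3)
        N = rng.standard_normal((10, 2))
        values = 2.0 + 3.0 * N[:, 0] - 1.5 * N[:, 1]
        out = ch.residualize(values, N)
        np.testing.assert_allclose(out, np.full(10, values.mean()), atol=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        N = rng.standard_normal((6, 2))
        v = rng.standard_normal(6)
        design = np.column_stack([np.ones(6), N])
        expected = v - design @ (np.linalg.pinv(design) @ v) + v.mean()
        np.testing.assert_allclose(ch.residualize(v, N), expected, atol=1e-10)

    def test_residuals_uncorrelated_with_each_nuisance(self):
        rng = np.random.default_rng(5)
        N = rng.standard_normal((40, 3))
        v = N @ [1.0, -2.0, 0.5] + rng.standard_normal(40)
        out = ch.residualize(v, N)
        for j in range(3):
            assert abs(np.corrcoef(out, N[:, j])[0, 1]) < 1e-10

    def test_collinear_nuisance_rejected(self):
        N = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            ch.residualize(np.arange(6.0), N)


class TestManova:
    def make_table(self, rng, n=60, effect=0.0):
        pred = rng.standard_normal(n)
        cov1 = rng.standard_normal(n)
        deps = {
            f"y{j}": effect * pred + 0.3 * cov1 + rng.standard_normal(n) for j in range(3)
        }
        return pd.DataFrame({"pred": pred, "cov1": cov1, **deps})

    def test_single_dependent_reduces_to_univariate_f(self):
        rng = np.random.default_rng(0)
        df = self.make_table(rng, effect=0.4)
        res = ch.manova_predict(df, ["y0"], ["pred"], ["cov1"])
        uni = res.per_dependent.iloc[0]
        assert res.F == pytest.approx(uni["F"], abs=1e-8)
        assert res.p == pytest.approx(uni["p"], abs=1e-8)

    def test_null_calibration(self):
        """Dependents independent of the predictor: rejection at alpha=.05
        over 300 null simulations stays in the exact binomial band."""
        rng = np.random.default_rng(1)
        rej = 0
        N = 300
        for _ in range(N):
            df = self.make_table(rng, n=40, effect=0.0)
            res = ch.manova_predict(df, ["y0", "y1", "y2"], ["pred"], ["cov1"])
            rej += res.p < 0.05
        lo = stats.binom.ppf(0.025, N, 0.05) / N
        hi = stats.binom.ppf(0.975, N, 0.05) / N
        assert lo <= rej / N <= hi

    def test_power_at_planted_effect(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            df = self.make_table(rng, n=60, effect=0.5)
            hits += ch.manova_predict(df, ["y0", "y1", "y2"], ["pred"], ["cov1"]).p < 0.05
        assert hits / 50 >= 0.8

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(3)
        df = self.make_table(rng)
        df["pred2"] = df["pred"]
        with pytest.raises(ValueError, match="singular"):
            ch.manova_predict(df, ["y0"], ["pred", "pred2"], ["cov1"])


class TestCorrelationTable:
    def test_perfect_negative(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        y = pd.DataFrame({"b": [-1.0, -2.0, -3.0, -4.0, -5.0]})
        out = ch.correlation_table(x, y)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 5))
        out = ch.correlation_table(pd.DataFrame({"a": a}), pd.DataFrame({"b": b}))
        n = 5
        r = (n * np.sum(a * b) - a.sum() * b.sum()) / (
            np.sqrt(n * np.sum(a**2) - a.sum() ** 2) * np.sqrt(n * np.sum(b**2) - b.sum() ** 2)
        )
        assert out.loc[0, "r"] == pytest.approx(r, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Independent columns: p-values over 1000 repetitions are uniform
        (Kolmogorov distance < 0.05)."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(1000):
            a, b = rng.standard_normal((2, 30))
            ps.append(stats.pearsonr(a, b)[1])
        grid = np.sort(ps)
        ks = np.max(np.abs(grid - np.arange(1, 1001) / 1000))
        assert ks < 0.05

    def test_constant_column_skipped_with_warning(self):
        x = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "c": [1.0, 2.0, 3.0, 4.0]})
        y = pd.DataFrame({"b": [1.0, 2.0, 3.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = ch.correlation_table(x, y)
        assert len(out) == 1  # only (c, b) survives


class TestAxisGroups:
    @pytest.mark.parametrize(
        "a, m, p, expected",
        [
            (1.2, 0.3, -0.8, "division-mid-anterior"),
            (1.2, -0.3, -0.8, "division-mid-posterior"),
            (0.5, 0.1, 0.9, "all-anterior"),
            (-0.5, -0.1, -2.0, "all-posterior"),
            (0.5, -0.2, 0.9, "excluded"),
            (-0.5, 0.2, -0.9, "excluded"),
            (-1.0, 0.4, 0.8, "division-mid-anterior"),
        ],
    )
    def test_sign_rules(self, a, m, p, expected):
        df = pd.DataFrame({"aHC": [a], "mHC": [m], "pHC": [p]})
        assert ch.classify_axis_groups(df).iloc[0] == expected

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=["aHC", "mHC", "pHC"])
        labels = ch.classify_axis_groups(df)
        assert len(labels) == 200
        assert set(labels).issubset(set(ch.GROUP_LABELS))
        assert labels.value_counts().sum() == 200

    def test_zero_score_is_error_without_tolerance(self):
        df = pd.DataFrame({"aHC": [0.0], "mHC": [1.0], "pHC": [-1.0]})
        with pytest.raises(ValueError, match="zero brain score"):
            ch.classify_axis_groups(df)
        # with a tolerance the tie is broken deterministically
        assert ch.classify_axis_groups(df, zero_tol=1e-9).iloc[0] in ch.GROUP_LABELS

    def test_missing_score_is_error(self):
        df = pd.DataFrame({"aHC": [np.nan], "mHC": [1.0], "pHC": [-1.0]})
        with pytest.raises(ValueError, match="missing"):
            ch.classify_axis_groups(df)


class TestGroupCompare:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = ch.group_compare(a, a.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_matches_textbook_pooled_t(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        t, p = ch.group_compare(a, b, direction="less")
        na, nb = 3, 3
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert p == pytest.approx(stats.t.cdf(t_exp, na + nb - 2), abs=1e-10)

    def test_one_tailed_null_calibration(self):
        rng = np.random.default_rng(7)
        rej = 0
        N = 1000
        for _ in range(N):
            a, b = rng.standard_normal((2, 15))
            rej += ch.group_compare(a, b, "greater")[1] < 0.05
        lo = stats.binom.ppf(0.025, N, 0.05) / N
        hi = stats.binom.ppf(0.975, N, 0.05) / N
        assert lo <= rej / N <= hi

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ch.group_compare(np.array([1.0]), np.array([1.0, 2.0]))


class TestEndToEnd:
    def test_behavioral_pipeline_recovers_planted_coupling(self):
        """Behaviour coupled to the shared network: the full pipeline
        (seed maps -> behavioural PLS -> permutation) must find a
        significant LV whose correlation scores match the planted sign in
        >= 90% of seeded replicates."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            c = make_cohort(seed=seed, n=24, T=80,
                            couplings={"memory": {"w_shared": 0.6},
                                       "d2dr": {"w_shared": 0.5}})
            stack = seed_map_stack(c)
            sub_beh = c.table.set_index("subject")[["memory", "d2dr"]]
            Y = sub_beh.loc[stack.subjects].reset_index(drop=True)
            res = pls.behavioral_pls(stack, Y)
            p = pls.permutation_test("behavioral", stack, Y, n_perm=200, seed=seed + 500)
            res = pls.orient_result(res)
            ok = p[0] <= 0.05 and np.all(res.corr_scores[:, :, 0] > 0)
            hits += ok
        assert hits / n_rep >= 0.9
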