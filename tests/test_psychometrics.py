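"""Reliability, adjusted correlations, known-groups, and structure analyses,
each checked against an independent oracle."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pinchtest.psychometrics import (
    AnalysisError,
    _anova_icc21,
    _vc_icc21,
    adjusted_spearman,
    bh_fdr,
    correlation_band,
    factor_summary,
    fatigue_subgroups,
    icc21,
    icc_band,
    known_groups,
    mann_whitney_auc,
    ms_subgroups,
    partial_spearman,
    pca_summary,
    rm_correlation,
    rm_correlation_matrix,
)


def _long(table: np.ndarray) -> pd.DataFrame:
    n, k = table.shape
    return pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(n)], k),
        "window": np.tile(np.arange(k), n),
        "value": table.ravel(),
    })


class TestICC:
    def test_identical_windows_distinct_subjects_gives_one(self):
        table = np.repeat(np.array([[1.0], [2.0], [5.0], [9.0]]), 3, axis=1)
        res = icc21(_long(table), n_boot=10)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.band == "excellent"

    def test_pure_noise_within_is_near_zero(self):
        rng = np.random.default_rng(0)
        table = rng.normal(0, 1, (200, 6))
        res = icc21(_long(table), n_boot=30, rng=np.random.default_rng(1))
        assert abs(res.icc) < 0.08
        assert res.ci_low <= 0.05

    def test_balanced_matches_classical_anova_formula(self):
        rng = np.random.default_rng(5)
        n, k = 4, 3
        table = (rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.5, (1, k))
                 + rng.normal(0, 0.8, (n, k)))
        # hand-rolled ANOVA oracle
        mean = table.mean()
        msr = k * np.sum((table.mean(1) - mean) ** 2) / (n - 1)
        msc = n * np.sum((table.mean(0) - mean) ** 2) / (k - 1)
        mse = (np.sum((table - mean) ** 2)
               - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc21(_long(table), n_boot=5)
        assert res.icc == pytest.approx(oracle, abs=1e-6)

    def test_unbalanced_estimator_agrees_with_anova_when_balanced(self):
        rng = np.random.default_rng(7)
        table = (rng.normal(0, 1, (10, 1)) + rng.normal(0, 0.4, (1, 4))
                 + rng.normal(0, 0.6, (10, 4)))
        assert _vc_icc21(_long(table)) == pytest.approx(
            _anova_icc21(table), abs=1e-9
        )

    def test_cross_check_against_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        table = (rng.normal(0, 1, (12, 4)) + rng.normal(0, 0.5, (12, 1)))
        long = _long(table)
        res = icc21(long, n_boot=5)
        icc_pg = pingouin.intraclass_corr(
            data=long, targets="subject", raters="window", ratings="value"
        )
        # two-way random, absolute agreement, single measurement
        sel = icc_pg["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(icc_pg.loc[sel, "ICC"].iloc[0])
        assert res.icc == pytest.approx(ref, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_parameter_recovery(self, rho):
        # averaged over replicate cohorts so the check isolates estimator
        # bias from single-draw Monte-Carlo noise
        rng = np.random.default_rng(int(rho * 100))
        n, k = 100, 6
        estimates = []
        for _ in range(10):
            table = (rng.normal(0, np.sqrt(rho), (n, 1))
                     + rng.normal(0, np.sqrt(1 - rho), (n, k)))
            estimates.append(icc21(_long(table), n_boot=0).icc)
        assert np.mean(estimates) == pytest.approx(rho, abs=0.05)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(AnalysisError):
            icc21(_long(np.ones((5, 3))))
        with pytest.raises(AnalysisError):
            icc21(_long(np.random.default_rng(0).normal(size=(1, 4))))

    def test_band_cuts(self):
        assert icc_band(0.49) == "poor"
        assert icc_band(0.5) == "moderate"
        assert icc_band(0.74) == "moderate"
        assert icc_band(0.75) == "good"
        assert icc_band(0.9) == "good"
        assert icc_band(0.91) == "excellent"


def _covariates(n, rng):
    age = rng.uniform(20, 60, n)
    sex = rng.choice(["F", "M"], n)
    return age, sex


class TestAdjustedSpearman:
    def test_perfect_monotone_relation(self):
        rng = np.random.default_rng(1)
        age, sex = _covariates(200, rng)
        x = rng.normal(0, 1, 200)
        res = adjusted_spearman(x, x.copy(), age, sex, n_boot=20)
        assert res.r >= 0.95
        assert res.band == "good-to-excellent"

    def test_age_confound_removed(self):
        rng = np.random.default_rng(2)
        age, sex = _covariates(300, rng)
        x = 2.0 * age + 1.0           # pure function of age
        y = rng.normal(0, 1, 300)     # independent noise
        res = adjusted_spearman(x, y, age, sex, n_boot=50,
                                rng=np.random.default_rng(3))
        null_band = 1.96 / np.sqrt(300 - 3)
        assert abs(res.r) < null_band
        assert res.ci_low <= 0 <= res.ci_high

    def test_matches_two_stage_oracle(self):
        rng = np.random.default_rng(4)
        n = 40
        age, sex = _covariates(n, rng)
        x = rng.normal(0, 1, n) + 0.02 * age
        y = 0.5 * x + rng.normal(0, 1, n)
        res = adjusted_spearman(x, y, age, sex, n_boot=5)
        # oracle: explicit residualization then ranks then Pearson
        X = np.column_stack([np.ones(n), age, (sex == "M").astype(float)])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        oracle = stats.pearsonr(stats.rankdata(rx), stats.rankdata(ry)).statistic
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(5)
        age, sex = _covariates(20, rng)
        with pytest.raises(AnalysisError):
            adjusted_spearman(np.ones(20), rng.normal(0, 1, 20), age, sex)


class TestPartialSpearman:
    def test_full_mediation_gives_zero(self):
        rng = np.random.default_rng(6)
        n = 300
        age, sex = _covariates(n, rng)
        z = rng.normal(0, 1, n)
        y = z.copy()                   # y IS z
        x = z + rng.normal(0, 0.5, n)  # x related to y only through z
        res = partial_spearman(x, y, z, age, sex, n_boot=10)
        assert abs(res.r) < 0.1

    def test_irrelevant_conditioning_matches_adjusted(self):
        rng = np.random.default_rng(7)
        n = 300
        age, sex = _covariates(n, rng)
        x = rng.normal(0, 1, n)
        y = 0.7 * x + rng.normal(0, 0.5, n)
        z = rng.normal(0, 1, n)        # independent of both
        res_partial = partial_spearman(x, y, z, age, sex, n_boot=5)
        res_adj = adjusted_spearman(x, y, age, sex, n_boot=5)
        assert res_partial.r == pytest.approx(res_adj.r, abs=0.05)

    def test_matches_residual_oracle_and_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n = 50
        age = np.full(n, 40.0)         # constant covariates: pure partial corr
        sex = np.array(["F"] * n)
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        y = 0.5 * x + 0.5 * z + rng.normal(0, 0.5, n)
        res = partial_spearman(x, y, z, age, sex, n_boot=5)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = float(
            pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")["r"].iloc[0]
        )
        assert res.r == pytest.approx(ref, abs=1e-6)


def pair_count_auc(a: np.ndarray, b: np.ndarray) -> float:
    """O(n^2) oracle: P(b > a) + 0.5 P(b = a)."""
    wins = ties = 0
    for va in a:
        for vb in b:
            if vb > va:
                wins += 1
            elif vb == va:
                ties += 1
    return (wins + 0.5 * ties) / (len(a) * len(b))


class TestKnownGroups:
    def test_disjoint_ranges_give_auc_one(self):
        rng = np.random.default_rng(9)
        n = 40
        values = pd.DataFrame({"f": np.r_[rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)]})
        ga = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        age = np.full(n, 40.0)
        sex = ["F"] * n
        res = known_groups(values, ga, ~ga, age, sex, "test")[0]
        assert res.auc == pytest.approx(1.0)
        assert res.p_raw < 1e-6

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(10)
        n = 400
        values = pd.DataFrame({"f": rng.normal(0, 1, n)})
        ga = np.arange(n) < n // 2
        age = np.full(n, 40.0)
        sex = ["F"] * n
        res = known_groups(values, ga, ~ga, age, sex, "null")[0]
        assert res.auc == pytest.approx(0.5, abs=0.08)
        assert abs(res.cohen_d) < 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 30, 2)
        a = rng.integers(0, 8, n1).astype(float)  # integer-valued: many ties
        b = rng.integers(0, 8, n2).astype(float)
        _, auc = mann_whitney_auc(a, b)
        assert auc == pytest.approx(pair_count_auc(a, b), abs=1e-12)

    def test_bh_fdr_matches_step_up_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(3, 25))
            adj = bh_fdr(p)
            # from-scratch step-up
            m = len(p)
            order = np.argsort(p)
            adj_oracle = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                adj_oracle[i] = prev
            assert np.allclose(adj, adj_oracle, atol=1e-12)

    def test_cohen_d_sign_and_magnitude(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 1, 2000)
        values = pd.DataFrame({"f": np.r_[a, b]})
        ga = np.arange(4000) < 2000
        res = known_groups(values, ga, ~ga, np.full(4000, 40.0), ["F"] * 4000, "d")[0]
        assert res.cohen_d == pytest.approx(1.0, abs=0.1)

    def test_subgroup_thresholds(self):
        anchors = pd.DataFrame({
            "participant_id": ["h", "m1", "m2", "m3"],
            "group": ["HC", "MS", "MS", "MS"],
            "hpt_dominant": [18.0, 22.14, 22.15, 30.0],
            "fsmc_total": [25.0, 42.9, 43.0, 80.0],
        })
        labels = ms_subgroups(anchors)
        assert list(labels) == ["HC", "MS-Normal", "MS-Abnormal", "MS-Abnormal"]
        fat = fatigue_subgroups(anchors)
        assert list(fat) == ["", "non-fatigued", "fatigued", "fatigued"]

    def test_empty_group_rejected(self):
        values = pd.DataFrame({"f": np.arange(10.0)})
        ga = np.zeros(10, bool)
        with pytest.raises(AnalysisError):
            known_groups(values, ga, ~ga, np.full(10, 40.0), ["F"] * 10, "x")


class TestRmCorrelation:
    def test_exact_within_subject_linearity(self):
        rng = np.random.default_rng(13)
        rows = []
        for s in range(5):
            x = rng.normal(0, 1, 8)
            rows.append(pd.DataFrame({"subject": s, "x": x, "y": x + 10 * s}))
        r, dof = rm_correlation(pd.concat(rows))
        assert r == pytest.approx(1.0, abs=1e-9)
        assert dof == 5 * 8 - 5 - 1

    def test_within_subject_null(self):
        rng = np.random.default_rng(14)
        rows = []
        for s in range(30):
            rows.append(pd.DataFrame({
                "subject": s, "x": rng.normal(0, 1, 10), "y": rng.normal(0, 1, 10)
            }))
        r, dof = rm_correlation(pd.concat(rows))
        assert abs(r) < 2 / np.sqrt(dof)

    def test_matches_dummy_coded_ancova_oracle(self):
        rng = np.random.default_rng(15)
        rows = []
        for s in range(3):
            x = rng.normal(0, 1, 6)
            y = 0.6 * x + rng.normal(0, 0.5, 6) + 2 * s
            rows.append(pd.DataFrame({"subject": f"s{s}", "x": x, "y": y}))
        df = pd.concat(rows, ignore_index=True)
        r, dof = rm_correlation(df)
        # oracle: explicit design matrix least squares
        D = np.zeros((18, 3))
        for i, s in enumerate(df["subject"]):
            D[i, int(s[1])] = 1.0
        X = np.column_stack([D, df["x"]])
        beta, *_ = np.linalg.lstsq(X, df["y"], rcond=None)
        resid_full = df["y"] - X @ beta
        beta0, *_ = np.linalg.lstsq(D, df["y"], rcond=None)
        resid_null = df["y"] - D @ beta0
        ss_x = float(resid_null @ resid_null - resid_full @ resid_full)
        oracle = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + float(resid_full @ resid_full)))
        assert r == pytest.approx(oracle, abs=1e-9)
        assert dof == 18 - 3 - 1

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(16)
        rows = []
        for s in range(6):
            x = rng.normal(0, 1, 7)
            y = -0.5 * x + rng.normal(0, 0.8, 7) + s
            rows.append(pd.DataFrame({"subject": f"s{s}", "x": x, "y": y}))
        df = pd.concat(rows, ignore_index=True)
        r, dof = rm_correlation(df)
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert dof == int(ref["dof"].iloc[0])

    def test_constant_x_subjects_dropped(self):
        rng = np.random.default_rng(17)
        good = pd.DataFrame({"subject": "a", "x": rng.normal(0, 1, 5),
                             "y": rng.normal(0, 1, 5)})
        good2 = pd.DataFrame({"subject": "c", "x": rng.normal(0, 1, 5),
                              "y": rng.normal(0, 1, 5)})
        bad = pd.DataFrame({"subject": "b", "x": np.ones(5), "y": rng.normal(0, 1, 5)})
        with pytest.warns(UserWarning, match="dropped"):
            r, dof = rm_correlation(pd.concat([good, bad, good2]))
        assert dof == 10 - 2 - 1


class TestStructure:
    def test_duplicated_column_dominates_first_component(self):
        rng = np.random.default_rng(18)
        base = rng.normal(0, 1, (60, 1))
        X = pd.DataFrame(np.hstack([base, base, rng.normal(0, 1, (60, 3))]))
        fractions, counts = pca_summary(X)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert fractions[0] >= 2 / 5 - 0.05

    def test_isotropic_columns_equal_fractions(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.normal(0, 1, (5000, 4)))
        fractions, _ = pca_summary(X)
        assert np.allclose(fractions, 0.25, atol=0.03)

    def test_fractions_match_eigen_oracle(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.normal(0, 1, (50, 8)))
        fractions, counts = pca_summary(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(fractions, eig / 8, atol=1e-8)
        cum = np.cumsum(eig / 8)
        assert counts[0.80] == int(np.argmax(cum >= 0.80)) + 1

    def test_two_factor_recovery(self):
        rng = np.random.default_rng(21)
        n, p = 400, 8
        f = rng.normal(0, 1, (n, 2))
        load = np.zeros((p, 2))
        load[:4, 0] = 0.8
        load[4:, 1] = 0.7
        X = pd.DataFrame(f @ load.T + rng.normal(0, 0.5, (n, p)))
        loadings, comm = factor_summary(X, n_factors=2)
        L = loadings.to_numpy()
        # congruence up to permutation/sign
        best = np.abs(L.T @ load) / (
            np.linalg.norm(L, axis=0)[:, None] * np.linalg.norm(load, axis=0)[None, :]
        )
        assert best.max(axis=0).min() >= 0.95

    def test_single_factor_communalities(self):
        rng = np.random.default_rng(22)
        n, p = 500, 6
        f = rng.normal(0, 1, (n, 1))
        lam = np.full((p, 1), 0.75)
        X = pd.DataFrame(f @ lam.T + rng.normal(0, np.sqrt(1 - 0.75**2), (n, p)))
        loadings, comm = factor_summary(X, n_factors=1)
        assert np.allclose(comm, 0.75**2, atol=0.1)

    def test_boundary_n_factors_runs(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(0, 1, (30, 4)))
        loadings, comm = factor_summary(X, n_factors=3)
        assert np.isfinite(loadings.to_numpy()).all()

    def test_rm_matrix_symmetric_bounded(self):
        rng = np.random.default_rng(24)
        rows = []
        for s in range(8):
            base = rng.normal(0, 1, 6)
            rows.append(pd.DataFrame({
                "subject": s,
                "a": base + rng.normal(0, 0.3, 6),
                "b": -base + rng.normal(0, 0.3, 6),
                "c": rng.normal(0, 1, 6),
            }))
        mat = rm_correlation_matrix(pd.concat(rows), ["a", "b", "c"])
        assert np.allclose(mat, mat.T)
        assert (mat.abs().to_numpy() <= 1 + 1e-9).all()
        assert mat.loc["a", "b"] < -0.7

    def test_correlation_band_cuts(self):
        assert correlation_band(0.24) == "uncorrelated"
        assert correlation_band(-0.25) == "fair"
        assert correlation_band(0.49) == "fair"
        assert correlation_band(0.5) == "moderate-to-good"
        assert correlation_band(-0.76) == "good-to-excellent"
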