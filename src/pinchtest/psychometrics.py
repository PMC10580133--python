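"""Psychometric evaluation: reliability, validity, and feature-space
structure.

Four analysis arms:

* **Test-retest reliability** — ICC(2,1): two-way random effects, absolute
  agreement, single measurement, over consecutive 2-week windows.  Bands:
  poor (< 0.5), moderate (0.5-0.74), good (0.75-0.9), excellent (> 0.9).
* **Convergent validity** — age- and sex-adjusted Spearman rank
  correlations between features and clinical anchors (adjustment by linear
  residualization), plus partial Spearman correlations given a third
  variable.  Strength bands: uncorrelated (|r| < 0.25), fair (0.25-0.49),
  moderate-to-good (0.50-0.75), good-to-excellent (> 0.75).
* **Known-groups validity** — Mann-Whitney U on age/sex residuals with
  Benjamini-Hochberg correction within each feature category, Cohen d and
  AUC (oriented >= 0.5).  Subgroups: MS-Normal vs MS-Abnormal split at a
  dominant-hand 9HPT time of 22.15 s; fatigued vs non-fatigued split at an
  FSMC total score of 43.
* **Feature structure** — repeated-measures correlation (common slope with
  per-subject intercepts), PCA of the correlation matrix, and
  principal-axis factor analysis with varimax rotation.

95% CIs are percentile bootstrap over subjects (200 replicates by default).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

HPT_ABNORMAL_CUT = 22.15  # s, dominant hand; at or above = MS-Abnormal
FSMC_FATIGUE_CUT = 43.0   # total score; >= 43 = at least mild fatigue

class AnalysisError(ValueError):
    pass


def icc_band(icc: float) -> str:
    """poor < 0.5, moderate 0.5-0.74, good 0.75-0.9, excellent > 0.9."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def correlation_band(r: float) -> str:
    """uncorrelated |r| < 0.25, fair 0.25-0.49, moderate-to-good 0.50-0.75,
    good-to-excellent > 0.75."""
    a = abs(r)
    if a > 0.75:
        return "good-to-excellent"
    if a >= 0.50:
        return "moderate-to-good"
    if a >= 0.25:
        return "fair"
    return "uncorrelated"


@dataclass
class ICCResult:
    feature: str
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_windows_total: int
    band: str = ""

    def __post_init__(self) -> None:
        self.band = icc_band(self.icc)


@dataclass
class CorrelationResult:
    feature: str
    anchor: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    band: str = ""

    def __post_init__(self) -> None:
        self.band = correlation_band(self.r)


@dataclass
class KnownGroupsResult:
    feature: str
    contrast: str
    p_raw: float
    p_fdr: float
    auc: float
    direction: int        # +1: group B tends higher on the raw scale
    cohen_d: float
    n_a: int
    n_b: int


@dataclass
class StructureResult:
    rm_corr: pd.DataFrame
    pca_fractions: np.ndarray
    pca_components_80: int
    pca_components_90: int
    loadings: pd.DataFrame
    communalities: pd.Series


# ---------------------------------------------------------------------------
# reliability

def _anova_icc21(table: np.ndarray) -> float:
    """Classical two-way ANOVA ICC(2,1) on a complete subjects x raters
    table."""
    n, k = table.shape
    mean = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - mean) ** 2)
    ss_cols = n * np.sum((col_means - mean) ** 2)
    ss_total = np.sum((table - mean) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise AnalysisError("no variance")
    return float((msr - mse) / denom)


def _vc_icc21(df: pd.DataFrame) -> float:
    """ICC(2,1) on unbalanced long data via variance components for the
    crossed random model  y = mu + subject + window + residual.

    Moment estimator (Henderson's method III): equate the sequential sums
    of squares SS(subject | mu, window), SS(window | mu) and SSE to their
    expectations, which are computed exactly from the projector traces, and
    solve the resulting 3x3 linear system.  Reduces to the classical
    two-way ANOVA estimator on balanced data.  Negative component estimates
    are truncated at zero.
    """
    from scipy.linalg import orth

    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    zs = pd.get_dummies(df["subject"]).to_numpy(dtype=float)
    zw = pd.get_dummies(df["window"]).to_numpy(dtype=float)
    ones = np.ones((n, 1))

    q1 = orth(np.hstack([ones, zw]))            # mean + window
    q2 = orth(np.hstack([ones, zw, zs]))        # mean + window + subject
    r1, r2 = q1.shape[1], q2.shape[1]

    def _proj_sq(q: np.ndarray, v: np.ndarray) -> float:
        return float(np.sum((q.T @ v) ** 2))

    yy = float(y @ y)
    p1y = _proj_sq(q1, y[:, None])
    p2y = _proj_sq(q2, y[:, None])
    p0y = float(y.sum() ** 2 / n)
    ss_subject = p2y - p1y                      # SS(subject | mu, window)
    ss_window = p1y - p0y                       # SS(window | mu)
    ss_error = yy - p2y

    # trace coefficients: E[y'Qy] = cs*var_s + cw*var_w + ce*var_e for each
    # quadratic form Q (the fixed mean is annihilated by all three)
    n0 = np.sqrt(1.0 / n) * ones
    rows = []
    # Q = P2 - P1
    cs = _proj_sq(q2, zs) - _proj_sq(q1, zs)
    cw = _proj_sq(q2, zw) - _proj_sq(q1, zw)
    rows.append([cs, cw, r2 - r1])
    # Q = P1 - P0
    cs = _proj_sq(q1, zs) - _proj_sq(n0, zs)
    cw = _proj_sq(q1, zw) - _proj_sq(n0, zw)
    rows.append([cs, cw, r1 - 1])
    # Q = I - P2
    cs = float(np.sum(zs**2)) - _proj_sq(q2, zs)
    cw = float(np.sum(zw**2)) - _proj_sq(q2, zw)
    rows.append([cs, cw, n - r2])

    A = np.array(rows)
    b = np.array([ss_subject, ss_window, ss_error])
    try:
        var_s, var_w, var_e = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(f"degenerate variance-component system: {exc}") from exc
    # component estimates may come out negative (as in classical ANOVA
    # decompositions); they are kept so that the balanced case reproduces
    # the textbook ICC(2,1) formula exactly
    total = var_s + var_w + var_e
    if total == 0:
        raise AnalysisError("no variance")
    return float(np.clip(var_s / total, -1.0, 1.0))


def _icc21_point(df: pd.DataFrame) -> float:
    counts = df.groupby("subject")["value"].size()
    windows = df["window"].unique()
    balanced = (
        counts.nunique() == 1
        and counts.iloc[0] == len(windows)
        and df.groupby("subject")["window"].nunique().min() == len(windows)
    )
    if balanced:
        table = df.pivot_table(index="subject", columns="window", values="value")
        return _anova_icc21(table.to_numpy(dtype=float))
    return _vc_icc21(df)


def icc21(
    long_data: pd.DataFrame,
    feature: str = "",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> ICCResult:
    """ICC(2,1) from long data with columns (subject, window, value).

    Balanced data use the exact two-way ANOVA formula; unbalanced data use
    REML variance components with crossed subject and window effects.  The
    95% CI is a percentile bootstrap over subjects.
    """
    df = long_data[["subject", "window", "value"]].dropna()
    subjects = df["subject"].unique()
    if len(subjects) < 2:
        raise AnalysisError("need >= 2 subjects")
    if df.groupby("subject")["value"].size().max() < 2:
        raise AnalysisError("need >= 2 windows for some subject")
    if float(df["value"].var()) == 0:
        raise AnalysisError("no variance")
    est = _icc21_point(df)

    rng = rng or np.random.default_rng(0)
    boots = []
    groups = {s: g for s, g in df.groupby("subject")}
    for _ in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        parts = []
        for j, s in enumerate(pick):
            g = groups[s].copy()
            g["subject"] = f"b{j}"
            parts.append(g)
        bdf = pd.concat(parts, ignore_index=True)
        if float(bdf["value"].var()) == 0:
            continue
        try:
            boots.append(_icc21_point(bdf))
        except AnalysisError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return ICCResult(
        feature=feature,
        icc=est,
        ci_low=float(lo),
        ci_high=float(hi),
        n_subjects=len(subjects),
        n_windows_total=len(df),
    )


# ---------------------------------------------------------------------------
# adjusted / partial correlations

def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y on [1, covariates]."""
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design(age: np.ndarray, sex: Sequence[str] | np.ndarray) -> np.ndarray:
    sex_num = np.asarray([1.0 if s in ("M", 1, 1.0, True) else 0.0 for s in sex])
    return np.column_stack([np.asarray(age, dtype=float), sex_num])


def adjusted_spearman(
    x: np.ndarray,
    y: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
    feature: str = "",
    anchor: str = "",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Age- and sex-adjusted Spearman correlation.

    Both variables are residualized on an intercept + age + sex by least
    squares, then the Spearman rank correlation of the residual pairs is
    computed; the 95% CI is a case-resampling percentile bootstrap.

    A variable lying in the covariate span (to numerical precision) has no
    variation left after adjustment; its adjusted correlation is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(np.asarray(age, dtype=float))
    x, y = x[mask], y[mask]
    cov = _design(np.asarray(age, dtype=float)[mask], np.asarray(sex, dtype=object)[mask])
    n = len(x)
    if n < 10:
        raise AnalysisError(f"need >= 10 complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance")

    def _adj_r(px: np.ndarray, py: np.ndarray, pcov: np.ndarray) -> float:
        rx = residualize(px, pcov)
        ry = residualize(py, pcov)
        # collinear with the covariates: only floating-point noise remains
        if np.ptp(rx) <= 1e-10 * np.ptp(px) or np.ptp(ry) <= 1e-10 * np.ptp(py):
            return 0.0
        return float(stats.spearmanr(rx, ry).statistic)

    r = _adj_r(x, y, cov)
    rng = rng or np.random.default_rng(0)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            continue
        boots.append(_adj_r(x[idx], y[idx], cov[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (float("nan"),) * 2)
    return CorrelationResult(feature, anchor, r, float(lo), float(hi), n)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    given: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
    feature: str = "",
    anchor: str = "",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Age/sex-adjusted partial Spearman correlation of x and y given z.

    All three variables are residualized on age and sex, rank-transformed,
    and the partial Pearson correlation of the ranked x and y given ranked
    z is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(given, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z) & np.isfinite(np.asarray(age, dtype=float))
    x, y, z = x[mask], y[mask], z[mask]
    cov = _design(np.asarray(age, dtype=float)[mask], np.asarray(sex, dtype=object)[mask])
    n = len(x)
    if n < 10:
        raise AnalysisError(f"need >= 10 complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance")

    def _partial(px, py, pz, pcov) -> float:
        rx = stats.rankdata(residualize(px, pcov))
        ry = stats.rankdata(residualize(py, pcov))
        rz = stats.rankdata(residualize(pz, pcov))
        ex = residualize(rx, rz[:, None])
        ey = residualize(ry, rz[:, None])
        return float(stats.pearsonr(ex, ey).statistic)

    r = _partial(x, y, z, cov)
    rng = rng or np.random.default_rng(0)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0 or np.ptp(z[idx]) == 0:
            continue
        boots.append(_partial(x[idx], y[idx], z[idx], cov[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (float("nan"),) * 2)
    return CorrelationResult(feature, anchor, r, float(lo), float(hi), n)


# ---------------------------------------------------------------------------
# known-groups validity

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def mann_whitney_auc(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p-value and the U/(n1*n2) AUC for 'b tends
    higher than a', with the midrank tie convention."""
    res = stats.mannwhitneyu(b, a, alternative="two-sided", method="auto")
    auc = float(res.statistic) / (len(a) * len(b))
    return float(res.pvalue), auc


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean(b) - mean(a)) / pooled SD."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)) if na + nb > 2 else float("nan")
    if pooled == 0 or not np.isfinite(pooled):
        return float("nan")
    return float((b.mean() - a.mean()) / pooled)


def known_groups(
    values: pd.DataFrame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
    contrast: str,
    features: Sequence[str] | None = None,
) -> list[KnownGroupsResult]:
    """Known-groups comparison of group B against group A for each feature.

    Values are residualized on age and sex (both groups pooled), then
    compared with a two-sided Mann-Whitney U test; BH correction is applied
    across the supplied features (one feature category per call).  AUC is
    oriented to be >= 0.5 with the raw direction retained; Cohen d uses the
    pooled-SD denominator on residuals.
    """
    features = list(features or values.columns)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if group_a.sum() < 2 or group_b.sum() < 2:
        raise AnalysisError("each group needs >= 2 members")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=object)
    results = []
    for feat in features:
        v = values[feat].to_numpy(dtype=float)
        mask = np.isfinite(v) & (group_a | group_b) & np.isfinite(age)
        a_mask, b_mask = mask & group_a, mask & group_b
        if a_mask.sum() < 2 or b_mask.sum() < 2:
            results.append(KnownGroupsResult(feat, contrast, float("nan"), float("nan"),
                                             float("nan"), 0, float("nan"),
                                             int(a_mask.sum()), int(b_mask.sum())))
            continue
        resid = residualize(v[mask], _design(age[mask], sex[mask]))
        sel_a = group_a[mask]
        ra, rb = resid[sel_a], resid[~sel_a]
        p, auc = mann_whitney_auc(ra, rb)
        direction = 1 if auc >= 0.5 else -1
        results.append(
            KnownGroupsResult(feat, contrast, p, float("nan"),
                              max(auc, 1 - auc), direction, cohen_d(ra, rb),
                              int(len(ra)), int(len(rb)))
        )
    p_raw = np.array([r.p_raw for r in results])
    p_adj = bh_fdr(p_raw)
    for r, padj in zip(results, p_adj):
        r.p_fdr = float(padj)
    return results


def ms_subgroups(anchors: pd.DataFrame, hpt_cut: float = HPT_ABNORMAL_CUT) -> pd.Series:
    """Label each participant HC, MS-Normal, or MS-Abnormal.

    MS participants with a dominant-hand 9HPT time strictly below the
    normative cut (22.15 s) are MS-Normal; the rest are MS-Abnormal.
    """
    labels = []
    for _, row in anchors.iterrows():
        if row["group"] == "HC":
            labels.append("HC")
        elif row.get("hpt_dominant", float("nan")) < hpt_cut:
            labels.append("MS-Normal")
        else:
            labels.append("MS-Abnormal")
    return pd.Series(labels, index=anchors.index, name="subgroup")


def fatigue_subgroups(anchors: pd.DataFrame, fsmc_cut: float = FSMC_FATIGUE_CUT) -> pd.Series:
    """Label MS participants fatigued (FSMC total >= 43) or non-fatigued;
    non-MS rows get an empty label."""
    labels = []
    for _, row in anchors.iterrows():
        if row["group"] != "MS" or not np.isfinite(row.get("fsmc_total", float("nan"))):
            labels.append("")
        elif row["fsmc_total"] >= fsmc_cut:
            labels.append("fatigued")
        else:
            labels.append("non-fatigued")
    return pd.Series(labels, index=anchors.index, name="fatigue_subgroup")


# ---------------------------------------------------------------------------
# feature-space structure

def rm_correlation(long_data: pd.DataFrame) -> tuple[float, int]:
    """Repeated-measures correlation from (subject, x, y) rows.

    Fits the common-slope ANCOVA y ~ subject + x; the correlation is the
    signed square root of SS_x / (SS_x + SS_error) with
    df = N - n_subjects - 1.  Subjects with constant x are dropped.
    """
    df = long_data[["subject", "x", "y"]].dropna().copy()
    keep = df.groupby("subject")["x"].transform(lambda s: s.nunique() > 1)
    dropped = df[~keep]["subject"].nunique()
    if dropped:
        warnings.warn(f"rm_correlation: dropped {dropped} subject(s) with constant x")
    df = df[keep]
    counts = df.groupby("subject").size()
    if len(counts) < 2:
        raise AnalysisError("need >= 2 subjects with varying x")
    subjects = pd.get_dummies(df["subject"], drop_first=False).to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    X_full = np.column_stack([subjects, x])
    X_null = subjects
    beta_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_null, *_ = np.linalg.lstsq(X_null, y, rcond=None)
    sse_full = float(np.sum((y - X_full @ beta_full) ** 2))
    sse_null = float(np.sum((y - X_null @ beta_null) ** 2))
    ss_x = sse_null - sse_full
    if ss_x + sse_full == 0:
        raise AnalysisError("no variance")
    slope = float(beta_full[-1])
    r = math.copysign(math.sqrt(max(ss_x, 0.0) / (ss_x + sse_full)), slope)
    dof = len(df) - len(counts) - 1
    return r, dof


def rm_correlation_matrix(
    long_data: pd.DataFrame, features: Sequence[str]
) -> pd.DataFrame:
    """Pairwise repeated-measures correlations over repeated rows per
    subject."""
    mat = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    for i, fa in enumerate(features):
        for fb in features[i + 1:]:
            sub = long_data[["subject", fa, fb]].dropna()
            sub = sub.rename(columns={fa: "x", fb: "y"})
            try:
                r, _ = rm_correlation(sub)
            except AnalysisError:
                r = float("nan")
            mat.loc[fa, fb] = mat.loc[fb, fa] = r
    return mat


def pca_summary(
    matrix: pd.DataFrame, thresholds: tuple[float, float] = (0.80, 0.90)
) -> tuple[np.ndarray, dict[float, int]]:
    """Explained-variance fractions of the z-scored feature matrix.

    Eigen-decomposes the correlation matrix of complete cases; constant
    (or numerically degenerate) columns are dropped with a warning.
    Returns the ordered fractions and the minimal component counts
    reaching each cumulative threshold.
    """
    X, corr = _correlation_matrix(matrix, "pca_summary")
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0, None)
    fractions = eigvals / eigvals.sum()
    cum = np.cumsum(fractions)
    counts = {thr: int(np.searchsorted(cum, thr - 1e-12) + 1) for thr in thresholds}
    return fractions, counts


def _correlation_matrix(
    matrix: pd.DataFrame, caller: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-case correlation matrix with degenerate columns dropped."""
    X = matrix.dropna()
    arr = X.to_numpy(dtype=float)
    scale = np.maximum(1.0, np.abs(arr).max(axis=0, initial=0.0))
    stds = arr.std(axis=0, ddof=0)
    keep = [c for c, s, m in zip(X.columns, stds, scale) if s > 1e-9 * m]
    if len(keep) < len(X.columns):
        warnings.warn(
            f"{caller}: dropped {len(X.columns) - len(keep)} constant column(s)"
        )
    X = X[keep]
    if X.shape[1] < 2:
        raise AnalysisError("need >= 2 non-constant columns")
    corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise AnalysisError("correlation matrix is not finite")
    return X, corr


def _varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation (Kaiser, unnormalized)."""
    p, k = loadings.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L @ np.diag(np.sum(L**2, axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ R


def factor_summary(
    matrix: pd.DataFrame, n_factors: int, max_iter: int = 200, tol: float = 1e-6
) -> tuple[pd.DataFrame, pd.Series]:
    """Principal-axis factoring with varimax rotation.

    Iterates communality estimates (starting from squared multiple
    correlations) until convergence, then rotates the retained loadings.
    Returns the loading matrix and communalities.  Raises on
    non-convergence with iteration diagnostics.
    """
    X, corr = _correlation_matrix(matrix, "factor_summary")
    names = list(X.columns)
    p = len(names)
    if n_factors >= p:
        raise AnalysisError("n_factors must be < number of features")
    try:
        inv = np.linalg.inv(corr)
        comm = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        comm = np.full(p, 0.5)
    comm = np.clip(comm, 0.05, 0.995)
    converged = False
    for it in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, comm)
        eigvals, eigvecs = np.linalg.eigh(reduced)
        order = np.argsort(eigvals)[::-1][:n_factors]
        lam = np.clip(eigvals[order], 0, None)
        loadings = eigvecs[:, order] * np.sqrt(lam)
        new_comm = np.clip(np.sum(loadings**2, axis=1), 0.0, 0.995)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            converged = True
            break
        comm = new_comm
    if not converged:
        raise AnalysisError(
            f"principal-axis factoring did not converge in {max_iter} iterations "
            f"(last max communality change {np.max(np.abs(new_comm - comm)):.2e})"
        )
    if n_factors > 1:
        loadings = _varimax(loadings)
    # sign convention: dominant direction of each factor positive
    signs = np.sign(np.sum(loadings, axis=0))
    signs[signs == 0] = 1
    loadings = loadings * signs
    load_df = pd.DataFrame(
        loadings, index=names, columns=[f"factor_{j + 1}" for j in range(n_factors)]
    )
    return load_df, pd.Series(comm, index=names, name="communality")
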