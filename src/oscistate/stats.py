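"""Cohort statistics for microstate parameters and demographics.

Implements the statistics battery applied to the subject x band x state
parameter grid: chi-square tests on demographic counts, one-way ANOVA per
cell with a Levene homogeneity gate that switches the post hoc procedure
between Tukey's HSD (homogeneous variances) and Tamhane's T2 (Welch t
pairs with a Sidak-type multiplicity adjustment), Pearson age
correlations, Bonferroni correction, paired t for the sensor-type GEV
contrast, and a standardized multiple regression of age on the parameter
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "RegressionResult",
    "PairwiseComparison",
    "chi_square_gof",
    "chi_square_contingency",
    "one_way_anova",
    "homogeneity_gate",
    "tukey_hsd",
    "tamhane_t2",
    "anova_with_posthoc",
    "age_correlation",
    "bonferroni",
    "paired_t",
    "standardized_regression",
    "demographics_tests",
]


@dataclass
class PairwiseComparison:
    group_i: int
    group_j: int
    estimate: float
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    homogeneity_p: float = float("nan")
    posthoc_method: str = ""
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int


@dataclass
class RegressionResult:
    """Standardized (beta) coefficients with overall fit statistics."""

    betas: np.ndarray
    names: list[str]
    r_squared: float
    f_p: float


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def chi_square_gof(
    observed, expected_proportions=None
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against stated (default uniform)
    proportions.  Returns (chi2, df, p)."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need a 1-D count vector with at least two cells")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.size != obs.size or not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must match cells and sum to 1")
    exp = obs.sum() * props
    if np.any(exp == 0):
        raise ValueError("zero expected count")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return chi2, df, float(sps.chi2.sf(chi2, df))


def chi_square_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova(groups) -> AnovaResult:
    """Classic between/within decomposition; F = MSB / MSW.

    If every group has zero internal variance and all means agree, F is
    defined as 0.
    """
    gs = _as_groups(groups)
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in gs))
    df1, df2 = k - 1, N - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0:
        if msb == 0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=float("inf"), df1=df1, df2=df2, p=0.0)
    F = msb / msw
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(sps.f.sf(F, df1, df2)))


def homogeneity_gate(groups, alpha_homog: float = 0.05) -> tuple[str, float]:
    """Choose the post hoc family by Levene's test (mean-centered).

    Returns ``("TamhaneT2", p)`` iff Levene p < ``alpha_homog``, else
    ``("Tukey", p)``.  A degenerate Levene statistic (identical spreads)
    counts as homogeneous.
    """
    gs = _as_groups(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.levene(*gs, center="mean")
    if not np.isfinite(p):
        p = 1.0
    method = "TamhaneT2" if p < alpha_homog else "Tukey"
    return method, float(p)


def tukey_hsd(groups) -> list[PairwiseComparison]:
    """Tukey(-Kramer) honestly-significant-difference pairwise tests.

    q(i,j) = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)); p-values
    from the studentized range distribution with (k, N-k).  Tukey p's are
    already family-adjusted, so ``p_adjusted == p_raw``.
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    df2 = N - k
    if df2 <= 0:
        raise ValueError("nonpositive error degrees of freedom")
    msw = sum(np.sum((g - g.mean()) ** 2) for g in gs) / df2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            if msw == 0:
                q, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df2))
            out.append(PairwiseComparison(i, j, float(diff), float(q), p, p))
    return out


def tamhane_t2(groups) -> list[PairwiseComparison]:
    """Tamhane's T2: Welch t pairs with a Sidak-type adjustment.

    Per pair, t = (mean_i - mean_j) / sqrt(s_i^2/n_i + s_j^2/n_j) with
    Welch-Satterthwaite degrees of freedom; the adjusted p-value is
    1 - (1 - p_raw)^m over the m pairs, capped at 1.
    """
    gs = _as_groups(groups)
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    k = len(gs)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            diff = a.mean() - b.mean()
            if va + vb == 0:
                t, df, p_raw = (0.0, a.size + b.size - 2, 1.0) if diff == 0 else (
                    float("inf"),
                    a.size + b.size - 2,
                    0.0,
                )
            else:
                t = diff / np.sqrt(va + vb)
                df = (va + vb) ** 2 / (
                    va**2 / (a.size - 1) + vb**2 / (b.size - 1)
                )
                p_raw = float(2.0 * sps.t.sf(abs(t), df))
            p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
            out.append(
                PairwiseComparison(i, j, float(diff), float(t), p_raw, p_adj)
            )
    return out


def anova_with_posthoc(groups, alpha_homog: float = 0.05) -> AnovaResult:
    """One-way ANOVA with the homogeneity-gated post hoc attached."""
    res = one_way_anova(groups)
    method, p_homog = homogeneity_gate(groups, alpha_homog)
    res.homogeneity_p = p_homog
    res.posthoc_method = method
    res.pairwise = tukey_hsd(groups) if method == "Tukey" else tamhane_t2(groups)
    return res


def age_correlation(age, param) -> CorrelationResult:
    """Pearson correlation between age and one microstate parameter."""
    x = np.asarray(age, dtype=float).ravel()
    y = np.asarray(param, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), r_squared=float(r) ** 2, p=float(p), n=x.size)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) per test; m is the family size."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than {p.size} tests")
    return np.minimum(1.0, m * p)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired-sample t test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, a.size - 1, 1.0
        raise FloatingPointError("zero-variance nonzero difference: t overflows")
    t = d.mean() / (sd / np.sqrt(a.size))
    df = a.size - 1
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


def standardized_regression(response, predictors, names=None) -> RegressionResult:
    """OLS of z-scored response on z-scored predictors (standardized betas).

    With a single predictor the beta equals the Pearson correlation.
    Rank-deficient predictor sets are refused, naming the collinear
    columns.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("response/predictor length mismatch")
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant predictor(s): {bad}")
    Xz = (X - X.mean(axis=0)) / sds
    if np.linalg.matrix_rank(Xz) < p:
        # name the columns involved in the dependency via QR pivoting
        r = np.linalg.qr(Xz, mode="r")
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-10)]
        raise ValueError(f"collinear predictor set, involving: {bad}")
    yz = (y - y.mean()) / y.std(ddof=1)
    fit = sm.OLS(yz, Xz).fit()
    return RegressionResult(
        betas=np.asarray(fit.params),
        names=list(names),
        r_squared=float(fit.rsquared),
        f_p=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else float("nan"),
    )


def demographics_tests(table: pd.DataFrame) -> dict[str, dict]:
    """The demographics chi-square battery on a per-group count table.

    Expects the columns of :func:`oscistate.synthetic.table1_fixture`.
    Per group: sex goodness of fit (female vs male, uniform) and
    handedness goodness of fit (right vs left, uniform, ambidextrous
    excluded).  Across groups: 5x2 sex and right/left handedness
    contingency tests.  Returns a nested dict of
    ``{"chi2": ..., "df": ..., "p": ...}`` records.
    """
    out: dict[str, dict] = {}
    for _, row in table.iterrows():
        g = row["group"]
        chi2, df, p = chi_square_gof([row["female"], row["male"]])
        out[f"sex_gof_{g}"] = {"chi2": chi2, "df": df, "p": p}
        chi2, df, p = chi_square_gof([row["right"], row["left"]])
        out[f"handedness_gof_{g}"] = {"chi2": chi2, "df": df, "p": p}
    sex_tab = table[["female", "male"]].to_numpy()
    chi2, df, p = chi_square_contingency(sex_tab)
    out["sex_contingency"] = {"chi2": chi2, "df": df, "p": p}
    hand_tab = table[["right", "left"]].to_numpy()
    chi2, df, p = chi_square_contingency(hand_tab)
    out["handedness_contingency"] = {"chi2": chi2, "df": df, "p": p}
    return out
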