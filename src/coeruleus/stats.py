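"""Group comparisons and craving correlations with covariate adjustment.

Implements the association tests used to relate imaging measures to group
membership and craving (CCQ score): partial correlation with nuisance
covariates (age, sex, AUDIT, FTND), covariate-adjusted two-sample group
differences, the plain two-sample t and the 2x2 chi-square for the
demographics table, plus a threshold-robustness profile that repeats the
partial correlation across fraction-of-peak mask definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AssociationResult:
    """One association test: r (partial correlation) or t (adjusted group
    difference), its two-tailed p, degrees of freedom and sample size."""

    statistic: float
    p: float
    df: int
    n: int
    kind: str = "r"
    covariates: tuple[str, ...] = ()

    @property
    def r(self) -> float:
        if self.kind != "r":
            raise AttributeError("not a correlation result")
        return self.statistic

    @property
    def t(self) -> float:
        if self.kind != "t":
            raise AttributeError("not a t result")
        return self.statistic


def _covariate_matrix(covs, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if covs is None:
        return np.empty((n, 0)), ()
    if isinstance(covs, pd.DataFrame):
        names = tuple(map(str, covs.columns))
        Z = covs.to_numpy(dtype=float)
    else:
        Z = np.asarray(covs, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        names = tuple(f"cov{j}" for j in range(Z.shape[1]))
    if Z.shape[0] != n:
        raise ValueError("covariate rows do not match sample size")
    if not np.all(np.isfinite(Z)):
        raise ValueError("missing values among covariates")
    return Z, names


def _residualize(v: np.ndarray, Z1: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z1, v, rcond=None)
    return v - Z1 @ beta


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covs=None) -> AssociationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares;
    r is the Pearson correlation of the residuals and the two-tailed p
    comes from t = r sqrt(df / (1 - r^2)) with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    Z, names = _covariate_matrix(covs, n)
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError("too few observations for the covariate set")
    Z1 = np.column_stack([np.ones(n), Z])
    rx = _residualize(x, Z1)
    ry = _residualize(y, Z1)
    if np.allclose(rx, 0) or np.allclose(ry, 0) \
            or rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant variable after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_cl = min(abs(r), 1.0 - 1e-15)
    t = np.sign(r) * r_cl * np.sqrt(df / (1.0 - r_cl ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationResult(statistic=r, p=p, df=df, n=n, kind="r",
                             covariates=names)


def adjusted_group_difference(values: np.ndarray, group: np.ndarray,
                              covs=None) -> AssociationResult:
    """Two-sample group difference adjusted for covariates.

    Least-squares fit of values on [1, group, covariates]; reports the t
    statistic and two-tailed p of the group coefficient.  With no
    covariates this equals the pooled-variance two-sample t exactly.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=float)
    n = len(v)
    if len(g) != n:
        raise ValueError("values and group lengths differ")
    if min((g == g.min()).sum(), (g == g.max()).sum()) < 2 or g.std() == 0:
        raise ValueError("need >= 2 subjects in each group")
    Z, names = _covariate_matrix(covs, n)
    X = np.column_stack([np.ones(n), g, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = float(beta[1] / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationResult(statistic=t, p=p, df=df, n=n, kind="t",
                             covariates=names)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance independent-sample t, two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 observations per group")
    pooled = ((len(a) - 1) * a.var(ddof=1)
              + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 contingency table, no continuity
    correction, df = 1."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal")
    stat, p, _df, _exp = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


@dataclass
class RobustnessProfile:
    """Partial correlation of an outcome with a per-subject measure
    repeated across fraction-of-peak mask thresholds; p values are raw
    (per threshold, uncorrected), with the test count reported."""

    results: dict[float, AssociationResult] = field(default_factory=dict)

    @property
    def n_tests(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fraction": f, "r": res.statistic, "p": res.p,
                 "df": res.df, "n": res.n, "n_tests": self.n_tests}
                for f, res in sorted(self.results.items())]
        return pd.DataFrame(rows)


def robustness_profile(measures: dict[float, np.ndarray],
                       outcome: np.ndarray,
                       covs=None) -> RobustnessProfile:
    """Apply ``partial_correlation`` for each threshold fraction."""
    if len(measures) < 2:
        raise ValueError("need measures at >= 2 fractions")
    prof = RobustnessProfile()
    for f, m in measures.items():
        prof.results[float(f)] = partial_correlation(m, outcome, covs)
    return prof
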