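"""Group-comparison inference suite.

Rank-based two-group tests (Mann-Whitney U with tie-corrected normal
approximation), Pearson chi-square on contingency tables without continuity
correction, Spearman rank correlation, and inverse-Gaussian identity-link
GLMs with per-covariate Wald tests and an omnibus model-vs-null deviance
test.  The chi-square default (no Yates correction) is fixed because it is
the convention under which printed 2x2 statistics from count tables are
exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TestResult:
    statistic_name: str  # "U" | "chi_square" | "rho"
    statistic: float
    p_value: float
    n: tuple[int, ...]
    df: int | None = None


@dataclasses.dataclass
class GLMSpec:
    """Inverse-Gaussian identity-link model of a shifted response.

    ``response_shift`` (default 10) is added to the response before fitting
    so the inverse-Gaussian support (strictly positive) is respected for
    acceleration residuals that straddle zero.
    """

    response: str
    covariates: list[str]
    response_shift: float = 10.0


@dataclasses.dataclass
class GLMFit:
    spec: GLMSpec
    coefficients: pd.Series
    standard_errors: pd.Series
    wald: pd.Series
    wald_p: pd.Series
    dispersion: float
    deviance: float
    null_deviance: float
    omnibus_chi2: float
    omnibus_p: float
    converged: bool
    iterations: int
    n: int


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U for the first (exposure) group.

    U = #{(i,j): x_i > y_j} + half the tied pairs; p from the normal
    approximation with tie-corrected variance and continuity correction.
    An exact p is used automatically only for small tie-free samples
    (n1*n2 <= 400), where enumeration is cheap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic_name="U",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size), int(y.size)),
    )


def pearson_chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square for an r x c count table; no Yates correction by
    default."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c contingency table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    res = scipy.stats.chi2_contingency(table, correction=correction)
    return TestResult(
        statistic_name="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(table.sum()),),
        df=int(res.dof),
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman's rho (Pearson correlation of midranks) with the
    t-approximation p-value on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must share length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rank correlation undefined")
    res = scipy.stats.spearmanr(x, y)
    return TestResult(
        statistic_name="rho",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size),),
    )


def fit_invgauss_glm(
    design: pd.DataFrame, response: pd.Series, spec: GLMSpec
) -> GLMFit:
    """Fit the inverse-Gaussian identity-link GLM by IRLS.

    The shifted response must be strictly positive; dispersion is the
    Pearson X^2 / (n - p) estimate; per-covariate Wald statistics are
    (beta / SE)^2 against chi-square(1); the omnibus statistic is the
    dispersion-scaled deviance drop from the intercept-only model against
    chi-square(p - 1).
    """
    cols = [c for c in spec.covariates if c in design.columns]
    missing = set(spec.covariates) - set(cols)
    if missing:
        raise ValueError(f"covariates absent from design: {sorted(missing)}")
    X = design[cols].astype(float)
    y = response.loc[X.index].astype(float) + spec.response_shift
    if (y <= 0).any():
        raise ValueError(
            "shifted response has non-positive values; increase response_shift "
            f"(min shifted value {y.min():.3f})"
        )
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    import warnings

    with warnings.catch_warnings():
        # identity link outside the family's canonical domain is deliberate:
        # the response shift guarantees positivity of the fitted means
        warnings.filterwarnings("ignore", category=sm.tools.sm_exceptions.DomainWarning)
        family = sm.families.InverseGaussian(link=sm.families.links.Identity())
        model = sm.GLM(y, X, family=family)
        result = model.fit(maxiter=100, tol=1e-8)
        if not result.converged:
            logger.warning("inverse-Gaussian GLM did not converge in 100 iterations")
        null_result = sm.GLM(y, np.ones((len(y), 1)), family=family).fit(
            maxiter=100, tol=1e-8
        )
    dispersion = float(result.scale)  # Pearson X2 / (n - p)
    omnibus = float((null_result.deviance - result.deviance) / dispersion)
    df_model = X.shape[1] - 1
    omnibus_p = float(scipy.stats.chi2.sf(omnibus, df_model)) if df_model > 0 else np.nan

    wald = (result.params / result.bse) ** 2
    wald_p = pd.Series(scipy.stats.chi2.sf(wald, 1), index=wald.index)
    return GLMFit(
        spec=spec,
        coefficients=result.params,
        standard_errors=result.bse,
        wald=wald,
        wald_p=wald_p,
        dispersion=dispersion,
        deviance=float(result.deviance),
        null_deviance=float(null_result.deviance),
        omnibus_chi2=omnibus,
        omnibus_p=omnibus_p,
        converged=bool(result.converged),
        iterations=len(result.fit_history.get("deviance", [])),
        n=int(len(y)),
    )


def run_group_comparisons(
    cohort_table: pd.DataFrame,
    variables: dict[str, str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-variable two-group tests: Mann-Whitney for continuous variables,
    Pearson chi-square for categorical ones.

    ``variables`` maps column name to ``"continuous"`` or ``"categorical"``.
    The group column must be binary; the first level in sorted order of its
    unique values is taken as the exposure group unless the column is
    categorical with an explicit order.  Returns one row per variable with
    per-group summaries (median/IQR or count/percent), the statistic and p.
    """
    groups = cohort_table[group_col]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"group column must be binary, found levels {levels}")
    g1, g2 = levels
    rows = []
    for var, kind in variables.items():
        col = cohort_table[var]
        if col.nunique(dropna=True) <= 1:
            logger.warning("variable %r constant across samples; skipped", var)
            continue
        a = col[groups == g1].dropna()
        b = col[groups == g2].dropna()
        if kind == "continuous":
            res = mann_whitney_u(a, b)
            rows.append(
                {
                    "variable": var,
                    f"{g1}_summary": float(a.median()),
                    f"{g1}_spread": float(a.quantile(0.75) - a.quantile(0.25)),
                    f"{g2}_summary": float(b.median()),
                    f"{g2}_spread": float(b.quantile(0.75) - b.quantile(0.25)),
                    "statistic_name": "U",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        elif kind == "categorical":
            tab = pd.crosstab(groups, col)
            res = pearson_chi_square(tab.to_numpy())
            pos = tab.columns.max()  # summarize the higher/"positive" level
            rows.append(
                {
                    "variable": var,
                    f"{g1}_summary": int(tab.loc[g1, pos]),
                    f"{g1}_spread": float(100 * tab.loc[g1, pos] / tab.loc[g1].sum()),
                    f"{g2}_summary": int(tab.loc[g2, pos]),
                    f"{g2}_spread": float(100 * tab.loc[g2, pos] / tab.loc[g2].sum()),
                    "statistic_name": "chi_square",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
    return pd.DataFrame(rows)
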