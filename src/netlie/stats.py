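"""Inferential statistics over per-subject AUC summaries and behavior.

The repeated-measures design has one two-level within-subjects factor (the
state: segment 1 vs segment 2) and age in years as a continuous
between-subjects covariate. With exactly two within levels the RM-ANOVA is
algebraically equivalent to two ordinary regressions:

* difference scores ``d_i = auc2_i - auc1_i`` regressed on centered age:
  the intercept test is the State main effect, the slope test the State×Age
  interaction (both on (1, n-2) df);
* subject means ``(auc1_i + auc2_i)/2`` regressed on centered age: the slope
  test is the between-subjects Age effect.

Effect sizes are partial eta squared, F/(F + df2). The battery also includes
the one-sample t on difference scores, Pearson and partial correlations, and
a two-block hierarchical regression whose second block enters candidates
stepwise (p_enter 0.05, p_remove 0.10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateModelError,
    InvalidParameterError,
    RankDeficiencyError,
    ZeroVarianceError,
)

__all__ = [
    "AnovaResult",
    "StepwiseStep",
    "StepwiseResult",
    "rm_anova_state_by_age",
    "between_group_anova",
    "one_sample_t",
    "pearson_with_p",
    "partial_correlation",
    "hierarchical_stepwise_regression",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f: float
    df1: int
    df2: int
    p: float
    eta_squared: float  # partial eta squared


def _simple_ols(y: np.ndarray, x_centered: np.ndarray):
    """OLS of y on [1, x]; returns (coefs, se, df_resid, degenerate flag)."""
    n = y.size
    if n < 3:
        raise InvalidParameterError("need at least 3 subjects")
    X = np.column_stack([np.ones(n), x_centered])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < 2:
        raise RankDeficiencyError("age has zero variance")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = n - 2
    rss = float(resid @ resid)
    # residual variance indistinguishable from rounding error of the fit
    degenerate = rss <= 1e-12 * float(y @ y) + 1e-300
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return beta, se, df, degenerate


def _coef_test(effect: str, beta: float, se: float, df: int, degenerate: bool) -> AnovaResult:
    if degenerate:
        # zero residual variance: F = 0/0; only the all-zero case is well defined
        if abs(beta) < 1e-12:
            return AnovaResult(effect, 0.0, 1, df, 1.0, 0.0)
        raise DegenerateModelError(
            f"{effect}: zero residual variance with nonzero effect (F would be infinite)"
        )
    t = beta / se
    f = float(t * t)
    p = float(2 * sps.t.sf(abs(t), df))
    return AnovaResult(effect, f, 1, df, p, f / (f + df))


def rm_anova_state_by_age(
    table: pd.DataFrame,
    metric: str,
    state_cols: tuple[str, str] | None = None,
    age_col: str = "age_years",
) -> list[AnovaResult]:
    """State, Age, and State×Age effects for one metric's paired AUCs.

    ``table`` must hold per-subject columns ``{metric}_s1``/``{metric}_s2``
    (or explicit ``state_cols``) and an age column. Age is mean-centered
    before the interaction is formed.
    """
    c1, c2 = state_cols or (f"{metric}_s1", f"{metric}_s2")
    for c in (c1, c2, age_col):
        if c not in table.columns:
            raise InvalidParameterError(f"missing column {c!r}")
        if table[c].isna().any():
            raise InvalidParameterError(f"column {c!r} has missing values")
    y1 = table[c1].to_numpy(float)
    y2 = table[c2].to_numpy(float)
    age = table[age_col].to_numpy(float)
    age_c = age - age.mean()
    d = y2 - y1
    m = (y1 + y2) / 2.0

    beta_d, se_d, df, degen_d = _simple_ols(d, age_c)
    state = _coef_test("State", beta_d[0], se_d[0], df, degen_d)
    interaction = _coef_test("State x Age", beta_d[1], se_d[1], df, degen_d)
    beta_m, se_m, _, degen_m = _simple_ols(m, age_c)
    age_effect = _coef_test("Age", beta_m[1], se_m[1], df, degen_m)
    return [state, age_effect, interaction]


def between_group_anova(
    y: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
) -> list[AnovaResult]:
    """Group (2 levels) × continuous-age between-subjects ANOVA on one outcome.

    Model: y ~ group + age_c + group:age_c with effect-coded group (±1/2) and
    centered age, so each coefficient's t-test is the marginal (Type III)
    effect test on (1, n-4) df.
    """
    y = np.asarray(y, float)
    group = np.asarray(group)
    age = np.asarray(age, float)
    n = y.size
    if n < 5:
        raise InvalidParameterError("need at least 5 subjects")
    levels = np.unique(group)
    if levels.size != 2:
        raise InvalidParameterError("group must have exactly 2 levels")
    g = np.where(group == levels[1], 0.5, -0.5)
    a = age - age.mean()
    X = np.column_stack([np.ones(n), g, a, g * a])
    if np.linalg.matrix_rank(X) < 4:
        raise RankDeficiencyError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 4
    rss = float(resid @ resid)
    degenerate = rss <= 1e-12 * float(y @ y) + 1e-300
    cov = rss / df * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    names = ["Intercept", "Group", "Age", "Group x Age"]
    return [
        _coef_test(name, beta[i], se[i], df, degenerate)
        for i, name in enumerate(names)
        if name != "Intercept"
    ]


def one_sample_t(differences: np.ndarray) -> tuple[float, int, float, float]:
    """(t, df, p, Cohen's d) against a zero population mean.

    d = mean / SD of the differences (the paired-contrast convention).
    """
    d = np.asarray(differences, float)
    if d.size < 2:
        raise InvalidParameterError("need at least 2 observations")
    if np.std(d, ddof=1) == 0:
        raise ZeroVarianceError("differences have zero variance")
    res = sps.ttest_1samp(d, 0.0)
    cohens_d = float(d.mean() / d.std(ddof=1))
    return float(res.statistic), d.size - 1, float(res.pvalue), cohens_d


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t-transform on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Correlation of x and y after linearly removing the covariates from both.

    p uses the t-transform with n - 2 - k df (k covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if x.size != n or y.size != n:
        raise InvalidParameterError("x, y, covariates must share n")
    if n <= k + 2:
        raise InvalidParameterError("need n > k + 2")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("collinear covariates")
    h = X @ np.linalg.lstsq(X, np.column_stack([x, y]), rcond=None)[0]
    rx = x - h[:, 0]
    ry = y - h[:, 1]
    # a variable that is an exact linear function of the covariates has a
    # null residual: its partial correlation with anything is zero
    if np.std(rx) <= 1e-10 * np.std(x) or np.std(ry) <= 1e-10 * np.std(y):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# hierarchical stepwise regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "block1" | "enter" | "remove"
    variable: str | None
    r_squared: float
    delta_r_squared: float
    delta_f: float
    df1: int
    df2: int
    p: float


@dataclass
class StepwiseResult:
    steps: list[StepwiseStep]
    final_predictors: list[str]
    #: per-predictor rows: b, beta_std, t, p, part_r
    coefficients: pd.DataFrame
    r_squared: float


def _fit(y: np.ndarray, cols: list[np.ndarray]):
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((y.size, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("collinear predictors")
    return sm.OLS(y, X).fit()


def hierarchical_stepwise_regression(
    y: np.ndarray,
    block1: dict[str, np.ndarray],
    block2_candidates: dict[str, np.ndarray],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Two-block hierarchical regression with a stepwise second block.

    Block 1 variables are forced into the model. Block 2 candidates then
    enter one at a time by smallest p-value while p <= ``p_enter``; after each
    entry, any block-2 variable whose p has risen to >= ``p_remove`` is
    removed again. Each step reports the R² change and its F-change test.
    Final coefficients include standardized betas and part (semipartial)
    correlations.
    """
    y = np.asarray(y, float)
    names1 = list(block1)
    cand = {k: np.asarray(v, float) for k, v in block2_candidates.items()}
    data = {k: np.asarray(v, float) for k, v in block1.items()} | cand
    n = y.size
    if any(v.size != n for v in data.values()):
        raise InvalidParameterError("all variables must have length n")
    if n <= len(data) + 2:
        raise InvalidParameterError("need n > total predictors + 2")

    steps: list[StepwiseStep] = []
    in_model: list[str] = []

    def record(action, variable, r2_old, model):
        r2 = model.rsquared
        m = 1 if variable else len(names1)
        df2 = int(model.df_resid)
        if m == 0:
            return
        delta = r2 - r2_old
        denom = (1 - r2) / df2
        f = (delta / m) / denom if denom > 0 else np.inf
        p = float(sps.f.sf(f, m, df2)) if np.isfinite(f) else 0.0
        steps.append(StepwiseStep(action, variable, r2, delta, float(f), m, df2, p))

    model = _fit(y, [data[k] for k in names1])
    in_model = list(names1)
    record("block1", None, 0.0, model)

    changed = True
    while changed:
        changed = False
        # entry: smallest p among candidates not yet in the model
        best_name, best_p = None, None
        for name in cand:
            if name in in_model:
                continue
            trial = _fit(y, [data[k] for k in in_model + [name]])
            p_val = trial.pvalues[-1]
            if best_p is None or p_val < best_p:
                best_name, best_p = name, p_val
        if best_name is not None and best_p <= p_enter:
            r2_old = model.rsquared
            in_model.append(best_name)
            model = _fit(y, [data[k] for k in in_model])
            record("enter", best_name, r2_old, model)
            changed = True
        # removal: any entered block-2 variable drifting above p_remove
        for name in [v for v in in_model if v in cand]:
            idx = in_model.index(name) + 1  # +1 for the constant
            if model.pvalues[idx] >= p_remove:
                r2_old = model.rsquared
                in_model.remove(name)
                model = _fit(y, [data[k] for k in in_model])
                record("remove", name, r2_old, model)
                changed = True
                break

    r2 = float(model.rsquared)
    sy = y.std(ddof=1)
    rows = []
    for j, name in enumerate(in_model, start=1):
        b = model.params[j]
        t = model.tvalues[j]
        p = model.pvalues[j]
        beta_std = b * data[name].std(ddof=1) / sy
        part = np.sign(t) * np.sqrt(t * t * (1 - r2) / model.df_resid)
        rows.append((name, float(b), float(beta_std), float(t), float(p), float(part)))
    coef = pd.DataFrame(rows, columns=["variable", "b", "beta_std", "t", "p", "part_r"])
    return StepwiseResult(steps, list(in_model), coef, r2)
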