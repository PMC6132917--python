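"""Group-comparison and pain-association statistics.

Four procedures, mirroring the analysis plan the pipeline serves:

* Mann-Whitney U for pain-score group differences (non-normal scores),
* uncorrected Pearson chi-square for a 2x2 prevalence table,
* MANCOVA-style group comparison of the network measures with the scan's
  mean motion as covariate (per-DV type-III F plus multivariate Wilks'
  lambda),
* hierarchical forward-stepwise linear regression of clinical pain on the
  network measures, with the motion covariate forced into the first block.

All tests are two-sided at alpha = 0.05 and no multiple-testing correction
is applied (each analysis reports its own number of tests).  scipy and
statsmodels provide the underlying machinery; the stepwise procedure is
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic of the first-listed sample
    (U1; the printed U of any given report depends on this convention, so it
    is fixed and documented here).  The p-value is exact by enumeration when
    ``n1 * n2 <= 400`` and the pooled data are tie-free, else the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square for a 2x2 count table.

    Returns ``(chi2, df=1, p)``.  No Yates continuity correction is applied.
    All four margins must be positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_float = np.asarray(table, dtype=float)
        if np.any(t_float < 0) or np.any(t_float != np.round(t_float)):
            raise ValueError("table must contain non-negative integer counts")
        t = t_float.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class AncovaTerm:
    """Group-term F test for one dependent variable."""

    f: float
    df_num: int
    df_den: int
    p: float


@dataclass
class GroupComparisonResult:
    """Covariate-adjusted group comparison across a set of DVs."""

    per_dv: dict[str, AncovaTerm]
    wilks_lambda: float | None = None
    wilks_f: float | None = None
    wilks_df: tuple[float, float] | None = None
    wilks_p: float | None = None
    group_means: pd.DataFrame | None = None


def ancova_group(
    dvs: pd.DataFrame, group, covariate
) -> GroupComparisonResult:
    """Per-DV ANCOVA F for the group term, plus multivariate Wilks' lambda.

    Fits ``dv ~ intercept + group + covariate`` per dependent variable and
    tests the group term with type-III sums of squares; with two or more DVs
    a MANCOVA Wilks' lambda for the group term is reported as well.

    Raises on a rank-deficient design (e.g. a single group level).
    """
    dvs = pd.DataFrame(dvs).reset_index(drop=True)
    g = pd.Series(group).reset_index(drop=True).astype(str)
    cov = pd.Series(np.asarray(covariate, dtype=float), name="covariate")
    n = len(dvs)
    if not (len(g) == len(cov) == n):
        raise ValueError("dvs, group and covariate must have equal length")
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    n_params = 1 + (len(levels) - 1) + 1
    if n <= n_params:
        raise ValueError("more fitted parameters than observations")

    safe = {c: f"dv{i}" for i, c in enumerate(dvs.columns)}
    data = dvs.rename(columns=safe).copy()
    data["group"] = g.values
    data["covariate"] = cov.values
    # a zero-variance covariate is collinear with the intercept: drop it so
    # the model degenerates to the plain group comparison
    rhs = "C(group) + covariate" if cov.std() > 0 else "C(group)"

    per_dv: dict[str, AncovaTerm] = {}
    for orig, name in safe.items():
        fit = sm.OLS.from_formula(f"{name} ~ {rhs}", data).fit()
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError("rank-deficient design matrix")
        tab = sm.stats.anova_lm(fit, typ=3)
        row = tab.loc["C(group)"]
        per_dv[str(orig)] = AncovaTerm(
            f=float(row["F"]),
            df_num=int(row["df"]),
            df_den=int(tab.loc["Residual", "df"]),
            p=float(row["PR(>F)"]),
        )

    result = GroupComparisonResult(per_dv=per_dv)
    result.group_means = (
        pd.concat([dvs, g.rename("group")], axis=1)
        .groupby("group")
        .agg(["mean", "std"])
    )
    if dvs.shape[1] >= 2:
        formula = " + ".join(safe.values()) + f" ~ {rhs}"
        try:
            mv = MANOVA.from_formula(formula, data).mv_test()
        except np.linalg.LinAlgError:
            # linearly dependent DV set (e.g. mean z-scores of subnetworks
            # that exhaust the brain sum to zero): the multivariate test is
            # undefined; per-DV results above remain valid
            return result
        wl = mv.results["C(group)"]["stat"].loc["Wilks' lambda"]
        result.wilks_lambda = float(wl["Value"])
        result.wilks_f = float(wl["F Value"])
        result.wilks_df = (float(wl["Num DF"]), float(wl["Den DF"]))
        result.wilks_p = float(wl["Pr > F"])
    return result


@dataclass
class StepwiseStep:
    """One model in the stepwise sequence."""

    predictors: list[str]
    coefficients: pd.DataFrame  # index: term; columns: B, se_B, std_B, p
    r_squared: float
    f: float
    df_model: int
    df_resid: int
    model_p: float
    entered: str | None = None


@dataclass
class StepwiseResult:
    """The full forward-stepwise sequence; step 1 is the covariate-only model."""

    steps: list[StepwiseStep] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.entered for s in self.steps if s.entered]

    @property
    def final(self) -> StepwiseStep:
        return self.steps[-1]


def _fit_step(
    y: np.ndarray, x: pd.DataFrame, entered: str | None
) -> StepwiseStep:
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    rows = {}
    for term in x.columns:
        b = float(fit.params[term])
        rows[term] = {
            "B": b,
            "se_B": float(fit.bse[term]),
            "std_B": b * x[term].std(ddof=1) / sd_y if sd_y > 0 else np.nan,
            "p": float(fit.pvalues[term]),
        }
    return StepwiseStep(
        predictors=list(x.columns),
        coefficients=pd.DataFrame.from_dict(rows, orient="index"),
        r_squared=float(fit.rsquared),
        f=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        model_p=float(fit.f_pvalue),
        entered=entered,
    )


def forward_stepwise(
    y,
    candidates: pd.DataFrame,
    forced_covariate,
    p_enter: float = 0.05,
    p_remove: float | None = None,
) -> StepwiseResult:
    """Forward-stepwise regression with a forced covariate block.

    Step 1 fits the covariate-only model.  At each later step the candidate
    with the smallest entry p-value (the t-test of its coefficient given the
    current model, equivalent to the partial F) enters if ``p <= p_enter``;
    the procedure stops when no candidate qualifies.  Pure forward selection
    by default; passing ``p_remove`` (e.g. 0.10) additionally drops an
    entered candidate whose p-value rises above it.

    Each step reports unstandardized B, its standard error, standardized B
    (``B * sd(x)/sd(y)``), per-predictor p, and the model R-squared / F / p.
    """
    y = np.asarray(y, dtype=float)
    candidates = pd.DataFrame(candidates).reset_index(drop=True)
    forced = pd.DataFrame(forced_covariate).reset_index(drop=True)
    if forced.shape[1] == 0:
        raise ValueError("a forced covariate is required")
    if forced.columns.tolist() == [0]:
        forced.columns = ["covariate"]
    n = y.size
    if n <= candidates.shape[1] + forced.shape[1] + 1:
        raise ValueError("too few observations for the candidate set")
    full = pd.concat([forced, candidates], axis=1)
    if np.linalg.matrix_rank(sm.add_constant(full)) < full.shape[1] + 1:
        # name a candidate involved in the exact collinearity
        base_rank = np.linalg.matrix_rank(sm.add_constant(forced))
        cols, bad = list(forced.columns), None
        for c in candidates.columns:
            r = np.linalg.matrix_rank(sm.add_constant(full[cols + [c]]))
            if r < len(cols) + 2:
                bad = c
                break
            cols.append(c)
        raise ValueError(
            f"exact collinearity among predictors (candidate {bad!r})"
            if bad is not None
            else f"rank-deficient forced covariate block (rank {base_rank})"
        )

    included: list[str] = []
    result = StepwiseResult()
    result.steps.append(_fit_step(y, forced.copy(), entered=None))
    remaining = list(candidates.columns)
    while remaining:
        best, best_p = None, np.inf
        for c in remaining:
            x = pd.concat([forced, candidates[included + [c]]], axis=1)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            p = float(fit.pvalues[c])
            if p < best_p:
                best, best_p = c, p
        if best is None or best_p > p_enter:
            break
        included.append(best)
        remaining.remove(best)
        x = pd.concat([forced, candidates[included]], axis=1)
        result.steps.append(_fit_step(y, x, entered=best))
        if p_remove is not None:
            step = result.steps[-1]
            worst = (
                step.coefficients.loc[included, "p"].idxmax()
                if included
                else None
            )
            if worst is not None and step.coefficients.loc[worst, "p"] > p_remove:
                included.remove(worst)
                remaining.append(worst)
                x = pd.concat([forced, candidates[included]], axis=1)
                result.steps.append(_fit_step(y, x, entered=None))
    return result
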