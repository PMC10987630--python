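"""Patient-level cohort statistics.

All tests operate on patient mean D (the average of a patient's per-cell
nuclear means), never on pooled cells, so patients are the unit of
inference. The two-group contrast uses Welch's t (unequal n and variance
across diagnostic groups) with Cohen's d on the pooled sd as the effect
size; a Mann-Whitney alternative is available. No multiple-testing
correction is applied — comparisons report raw p-values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from cspws.errors import ValidationError
from cspws.models import Cohort, GroupComparison, RocResult

#: Groups counted as "case" in the confounder screen (diminutive adenomas
#: and HNPCC are excluded, matching the demographics table's definition).
CASE_GROUPS: tuple[str, ...] = ("NDA", "AA", "cancer")


def _patient_means(cohort: Cohort, groups: Sequence[str]) -> np.ndarray:
    vals = [p.mean_d for p in cohort.select(groups)]
    return np.asarray(vals, dtype=float)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled sd; positive when mean(b) > mean(a).

    Complete separation with (numerically) zero within-group spread
    returns a signed infinity, which callers flag as degenerate.
    """
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    diff = b.mean() - a.mean()
    tol = 1e-12 * max(1.0, abs(a.mean()), abs(b.mean()))
    if pooled <= tol:
        return math.copysign(math.inf, diff) if diff else 0.0
    return float(diff / pooled)


def compare_groups(
    cohort: Cohort,
    a: Sequence[str] | str,
    b: Sequence[str] | str,
    test: str = "welch",
) -> GroupComparison:
    """Contrast patient mean D between two group sets.

    ``a`` is the reference (control-like) side and ``b`` the case-like
    side, so positive ``mean_diff`` and ``effect_size`` mean the case
    side is elevated. ``test`` is ``"welch"`` (default) or
    ``"mannwhitney"``.
    """
    a = [a] if isinstance(a, str) else list(a)
    b = [b] if isinstance(b, str) else list(b)
    va, vb = _patient_means(cohort, a), _patient_means(cohort, b)
    if va.size < 2 or vb.size < 2:
        raise ValidationError("each side needs >= 2 patients")
    if test == "welch":
        stat = sps.ttest_ind(vb, va, equal_var=False)
        p = float(stat.pvalue)
    elif test == "mannwhitney":
        p = float(sps.mannwhitneyu(vb, va, alternative="two-sided").pvalue)
    else:
        raise ValidationError(f"unknown test '{test}'")
    d = cohens_d(va, vb)
    degenerate = not math.isfinite(d)
    if degenerate and math.isnan(p):
        p = 0.0  # complete separation with zero variance
    return GroupComparison(
        group_a="+".join(a),
        group_b="+".join(b),
        n_a=int(va.size),
        n_b=int(vb.size),
        mean_diff=float(vb.mean() - va.mean()),
        p_value=p,
        effect_size=d,
        degenerate=degenerate,
    )


def ancova_confounders(
    cohort: Cohort,
    case_groups: Sequence[str] = CASE_GROUPS,
    control_groups: Sequence[str] = ("control",),
) -> pd.DataFrame:
    """Covariance screen of patient mean D on case status and demographics.

    Fits ``mean_d ~ case + age + sex + smoking + drinking`` by OLS on the
    control + case arms and returns a per-covariate table of coefficient,
    standard error and p-value. Raises on zero-variance covariates or a
    rank-deficient design (naming the collinear columns).
    """
    import statsmodels.api as sm

    records = cohort.select(list(control_groups) + list(case_groups))
    case_set = set(case_groups)
    n_case = sum(p.group in case_set for p in records)
    n_ctrl = len(records) - n_case
    if n_case < 10 or n_ctrl < 10:
        raise ValidationError("need >= 10 patients per arm for the screen")

    X = pd.DataFrame(
        {
            "case": [1.0 if p.group in case_set else 0.0 for p in records],
            "age": [p.age for p in records],
            "sex_female": [1.0 if p.sex == "F" else 0.0 for p in records],
            "smoking": [1.0 * p.smoking for p in records],
            "drinking": [1.0 * p.drinking for p in records],
        }
    )
    zero_var = [c for c in X.columns if X[c].nunique() <= 1]
    if zero_var:
        raise ValidationError(f"zero-variance covariates: {zero_var}")
    y = np.array([p.mean_d for p in records])
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        corr = X.corr().abs()
        pairs = [
            (i, j)
            for i in corr.columns
            for j in corr.columns
            if i < j and corr.loc[i, j] > 0.999
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {"coef": fit.params, "stderr": fit.bse, "p_value": fit.pvalues}
    ).drop(index="const")


def age_regression(cohort: Cohort) -> tuple[float, float, float]:
    """OLS of patient mean D on age: returns (slope, intercept, r)."""
    ages = np.array([p.age for p in cohort.patients])
    d = np.array([p.mean_d for p in cohort.patients])
    if np.unique(ages).size < 3:
        raise ValidationError("need >= 3 distinct ages")
    if np.ptp(d) == 0:
        return 0.0, float(d[0]), 0.0
    res = sps.linregress(ages, d)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def univariate_roc(
    cohort: Cohort,
    case_groups: Sequence[str],
    control_groups: Sequence[str],
    split: float = 0.5,
    seed: int = 0,
) -> RocResult:
    """Split-sample ROC of patient mean D as a univariate biomarker.

    The cohort is split (stratified by class, fraction ``split`` held out
    for testing); the optimal cutpoint is chosen on the training half and
    applied to the test half, where sensitivity, specificity and the
    rank-statistic AUC are evaluated.
    """
    from sklearn.model_selection import train_test_split

    from cspws.classifier import optimal_cutpoint, roc_auc

    cases = _patient_means(cohort, case_groups)
    controls = _patient_means(cohort, control_groups)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("both classes must be present")
    scores = np.concatenate([controls, cases])
    labels = np.concatenate([np.zeros(controls.size, int), np.ones(cases.size, int)])
    try:
        s_tr, s_te, y_tr, y_te = train_test_split(
            scores, labels, test_size=split, stratify=labels, random_state=seed
        )
    except ValueError as exc:
        raise ValidationError(f"stratified split failed: {exc}") from exc
    for name, y in (("training", y_tr), ("test", y_te)):
        if len(set(y)) < 2:
            raise ValidationError(
                f"class absent from the {name} half; re-seed the split"
            )
    thr, _, _ = optimal_cutpoint(s_tr, y_tr)
    pred = s_te >= thr
    se = float(pred[y_te == 1].mean())
    sp = float((~pred[y_te == 0]).mean())
    return RocResult(
        auc=roc_auc(s_te, y_te),
        sensitivity=se,
        specificity=sp,
        threshold=float(thr),
        split_seed=seed,
    )
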