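"""Behavioural statistics: stay-probability regression, RT contrasts,
nonparametric group comparisons, lesion-volume regression, and
age/education residualization.

The stay-probability analysis asks whether repeating the previous Step-1
choice depends on the previous trial's outcome, transition type, and
their interaction (the model-based signature), with a binary "correct"
control regressor (whether the previous Step-1 choice commonly led to
the state holding the currently high-reward shape) that guards against
inflated model-based estimates in block-stationary schedules.

Group comparisons use rank-based tests throughout (the behavioural
metrics are generally non-normal), with exact small-sample null
distributions where feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .twostep_task import COMMON, common_state

GROUPS = ("vmPFC", "LC", "HC")
EXACT_MAX_N = 10  # exact rank-test nulls below this group size (no ties)


# ---------------------------------------------------------------------------
# stay-probability regression


@dataclass
class StayDesign:
    """Design matrix for the stay regression: one row per trial t >= 2.

    ``stay`` = 1 iff choice1_t equals choice1_{t-1}; predictors are the
    previous trial's outcome (+/-0.5), transition (+/-0.5, common
    positive), their product, and the binary correct indicator.
    """

    stay: np.ndarray
    outcome: np.ndarray
    transition: np.ndarray
    interaction: np.ndarray
    correct: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.column_stack(
            [np.ones_like(self.outcome), self.outcome, self.transition,
             self.interaction, self.correct]
        )


@dataclass
class StayCoefs:
    intercept: float
    outcome: float
    transition: float
    interaction: float
    correct: float
    separation_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept, "outcome": self.outcome,
            "transition": self.transition, "interaction": self.interaction,
            "correct": self.correct, "separation_flag": self.separation_flag,
        }


def build_stay_design(trials: pd.DataFrame) -> StayDesign:
    """Lagged design from one subject's trial table (needs the
    ``high_shape`` column to form the correct regressor)."""
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    c1 = trials["choice1"].to_numpy(int)
    trans = (trials["transition"].to_numpy() == COMMON).astype(float)
    rew = trials["reward"].to_numpy(float)
    high = trials["high_shape"].to_numpy(int)
    high_state = high // 2 + 1
    prev_correct = np.array(
        [float(common_state(a) == hs) for a, hs in zip(c1[:-1], high_state[:-1])]
    )
    return StayDesign(
        stay=(c1[1:] == c1[:-1]).astype(float),
        outcome=rew[:-1] - 0.5,
        transition=trans[:-1] - 0.5,
        interaction=(rew[:-1] - 0.5) * (trans[:-1] - 0.5),
        correct=prev_correct,
    )


def stay_regression(design: StayDesign, ridge: float = 1e-3) -> StayCoefs:
    """Maximum-likelihood logistic fit of staying on the lagged
    predictors; falls back to a weak-ridge fit (flagged) under
    (quasi-)separation or non-convergence."""
    y = design.stay
    if y.min() == y.max():
        raise ValueError("single-class stay response; cannot fit")
    X = design.matrix()
    flag = False
    params = None
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and \
                np.all(np.abs(res.params) < 30):
            params = res.params
    except Exception:
        params = None
    if params is None:
        flag = True
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge, L1_wt=0.0
        )
        params = res.params
    return StayCoefs(*[float(b) for b in params], separation_flag=flag)


def stay_coefficients(trials: pd.DataFrame) -> StayCoefs:
    """Convenience: design + regression for one subject."""
    return stay_regression(build_stay_design(trials))


def pooled_stay_design(per_subject_trials) -> StayDesign:
    """Concatenate per-subject lagged designs (lags never cross subject
    boundaries). Pooling gives a consistent low-variance estimate of a
    shared coefficient vector, useful when per-subject fits sit near
    separation."""
    designs = [build_stay_design(t) for t in per_subject_trials]
    return StayDesign(
        stay=np.concatenate([d.stay for d in designs]),
        outcome=np.concatenate([d.outcome for d in designs]),
        transition=np.concatenate([d.transition for d in designs]),
        interaction=np.concatenate([d.interaction for d in designs]),
        correct=np.concatenate([d.correct for d in designs]),
    )


# ---------------------------------------------------------------------------
# response-time contrast


def rt_contrast(trials: pd.DataFrame) -> float:
    """Mean Step-2 RT after rare minus after common transitions (ms)."""
    rt = trials["rt2_ms"].to_numpy(float)
    common = trials["transition"].to_numpy() == COMMON
    ok = np.isfinite(rt)
    if not (ok & common).any() or not (ok & ~common).any():
        raise ValueError("need finite RTs for both transition types")
    return float(rt[ok & ~common].mean() - rt[ok & common].mean())


# ---------------------------------------------------------------------------
# group tests


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    sidedness: str
    group_sizes: tuple

    def as_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "p": self.p_value, "sidedness": self.sidedness,
            "n": list(self.group_sizes),
        }


def _clean_groups(values, labels) -> dict:
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    out = {}
    for g in pd.unique(labels):
        v = values[labels == g]
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
        out[g] = v
    return out


def group_tests(
    values,
    labels=None,
    test: str = "kruskal",
    alternative: str = "two-sided",
    popmean: float = 0.0,
) -> GroupTestResult:
    """Dispatch one of the group-comparison tests.

    ``test`` is one of 'kruskal', 'mannwhitney', 'wilcoxon' (one-sample
    signed-rank against ``popmean``), 'ttest_1samp', or 'fisher' (2x2
    counts passed directly as ``values``). Rank tests use midranks with
    tie correction; the Mann-Whitney null is exact when the smaller
    group has at most 10 observations and no ties occur, normal
    approximation otherwise.
    """
    if test == "fisher":
        table = np.asarray(values)
        odds, p = sps.fisher_exact(table, alternative=alternative)
        return GroupTestResult("fisher", float(odds), float(p), alternative,
                               tuple(int(n) for n in table.sum(axis=1)))
    if test in ("wilcoxon", "ttest_1samp"):
        v = np.asarray(values, float)
        if len(v) == 0:
            raise ValueError("empty sample")
        if test == "wilcoxon":
            res = sps.wilcoxon(v - popmean, alternative=alternative)
            return GroupTestResult("wilcoxon", float(res.statistic),
                                   float(res.pvalue), alternative, (len(v),))
        res = sps.ttest_1samp(v, popmean, alternative=alternative)
        return GroupTestResult("ttest_1samp", float(res.statistic),
                               float(res.pvalue), alternative, (len(v),))
    groups = _clean_groups(values, labels)
    sizes = tuple(len(v) for v in groups.values())
    if test == "kruskal":
        if len(groups) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        res = sps.kruskal(*groups.values())
        return GroupTestResult("kruskal", float(res.statistic),
                               float(res.pvalue), "two-sided", sizes)
    if test == "mannwhitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney needs exactly 2 groups")
        a, b = groups.values()
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= EXACT_MAX_N
                             and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
        return GroupTestResult("mannwhitney", float(res.statistic),
                               float(res.pvalue), alternative, sizes)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# lesion-volume regression and covariate residualization


@dataclass
class CovariateRecord:
    subject_id: str
    group: str
    age: float
    education: float
    v_vmpfc: float  # lesion volume inside the vmPFC mask (voxels)
    v_total: float  # total lesion volume (voxels)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.v_vmpfc > self.v_total:
            raise ValueError("v_vmpfc cannot exceed v_total")
        if self.group in ("LC", "HC") and self.v_vmpfc != 0:
            raise ValueError(f"{self.group} subjects must have v_vmpfc = 0")


@dataclass
class VolumeRegressionResult:
    intercept: float
    beta_vmpfc: float
    beta_total: float
    p_vmpfc: float
    p_total: float
    residual_var: float


def covariates_to_frame(records: list[CovariateRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def lesion_volume_regression(
    covariates: pd.DataFrame, metric: np.ndarray
) -> VolumeRegressionResult:
    """OLS of a performance metric on vmPFC lesion volume controlling
    for total lesion volume: metric ~ a + b0 * V_vmPFC + b1 * V_total."""
    metric = np.asarray(metric, float)
    if len(metric) != len(covariates):
        raise ValueError("metric and covariates length mismatch")
    if len(metric) < 4:
        raise ValueError("need >= 4 subjects")
    X = sm.add_constant(covariates[["v_vmpfc", "v_total"]].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant/collinear volumes)")
    res = sm.OLS(metric, X).fit()
    return VolumeRegressionResult(
        intercept=float(res.params[0]),
        beta_vmpfc=float(res.params[1]),
        beta_total=float(res.params[2]),
        p_vmpfc=float(res.pvalues[1]),
        p_total=float(res.pvalues[2]),
        residual_var=float(res.mse_resid),
    )


def residualize(
    metric: np.ndarray,
    covariates: pd.DataFrame,
    reference_group: str = "HC",
) -> np.ndarray:
    """Remove the age/education contribution estimated within the
    reference group: fit metric ~ age + education there, subtract the
    prediction for every subject."""
    metric = np.asarray(metric, float)
    cov = covariates[["age", "education"]].to_numpy(float)
    if np.isnan(cov).any() or np.isnan(metric).any():
        raise ValueError("missing covariate or metric values")
    ref = (covariates["group"] == reference_group).to_numpy()
    if not ref.any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    Xr = sm.add_constant(cov[ref])
    res = sm.OLS(metric[ref], Xr).fit()
    X_all = sm.add_constant(cov, has_constant="add")
    return metric - X_all @ res.params
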