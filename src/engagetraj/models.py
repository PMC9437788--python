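"""Outcome and group-membership models.

Two analysis surfaces mirror the published tables: (1) a logistic model
of 30-day point-prevalence abstinence at 12 months on trajectory-group
dummies (lowest-use group as reference), adjusted for AIC-stepwise-
selected baseline covariates that passed a univariate screen; (2) a
multinomial (k >= 3) or logistic (k = 2) model of trajectory-group
membership on screened, stepwise-selected baseline covariates.

Fits are maximum likelihood via statsmodels (IRLS for the binomial GLM,
Newton for the baseline-category multinomial logit).  Inference is Wald:
OR = exp(beta), 95% CI = exp(beta +/- 1.96 SE).  Complete-case outcome
analysis by default, with a missing=smoker sensitivity switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from scipy.linalg import qr
from scipy.stats import norm

from engagetraj.clustering import ClusterSolution

Z975 = norm.ppf(0.975)
#: |coefficient| beyond which a logistic fit is treated as separated.
SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE diverges."""


class RankDeficiencyError(ValueError):
    """Collinear design columns; names the offending terms."""


@dataclass
class FittedModel:
    """A fitted (multinomial) logistic model with Wald inference.

    ``table`` has one row per coefficient — indexed by term for logistic
    fits and by (category, term) for multinomial fits — with columns
    coef, se, odds_ratio, ci_low, ci_high, p_value.
    """

    model_family: str
    terms: list[str]
    table: pd.DataFrame
    log_likelihood: float
    aic: float
    n_used: int
    reference_levels: dict = field(default_factory=dict)

    def odds_ratio(self, term: str, category: str | None = None) -> float:
        if category is not None:
            return float(self.table.loc[(category, term), "odds_ratio"])
        return float(self.table.loc[term, "odds_ratio"])


def _check_design(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(A.shape[1]) if diag[i] <= tol]
        raise RankDeficiencyError(f"design is rank deficient; collinear terms: {bad}")


def _with_intercept(design: pd.DataFrame) -> pd.DataFrame:
    if "Intercept" in design.columns:
        return design
    X = design.copy()
    X.insert(0, "Intercept", 1.0)
    return X


def _wald_table(params: np.ndarray, bse: np.ndarray, index) -> pd.DataFrame:
    z = np.divide(params, bse, out=np.full_like(params, np.nan), where=bse > 0)
    return pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - Z975 * bse),
            "ci_high": np.exp(params + Z975 * bse),
            "p_value": 2 * norm.sf(np.abs(z)),
        },
        index=index,
    )


def fit_logistic(outcome: Sequence, design: pd.DataFrame) -> FittedModel:
    """Binomial-GLM logistic regression (IRLS) with Wald inference.

    ``design`` holds named covariate columns; an intercept is added if
    absent.  Raises ``SeparationError`` when the MLE diverges
    (|coefficient| > 15) and ``RankDeficiencyError`` on collinear designs.
    """
    y = np.asarray(outcome, dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome must contain at least one event and one non-event")
    X = _with_intercept(design)
    _check_design(X)
    with warnings.catch_warnings():
        # separation is detected below and raised as SeparationError
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = sm.GLM(y, X.to_numpy(float), family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-10
        )
    if np.abs(res.params).max() > SEPARATION_BOUND:
        raise SeparationError(
            "coefficients diverged (|beta| > 15); data are (quasi-)separated"
        )
    table = _wald_table(res.params, res.bse, pd.Index(X.columns, name="term"))
    return FittedModel(
        model_family="logistic",
        terms=list(X.columns),
        table=table,
        log_likelihood=float(res.llf),
        aic=float(2 * len(res.params) - 2 * res.llf),
        n_used=len(y),
    )


def fit_multinomial(
    groups: Sequence, design: pd.DataFrame, reference: str | None = None
) -> FittedModel:
    """Baseline-category multinomial logit (one logit per non-reference
    category against ``reference``, default the first sorted level)."""
    groups = pd.Series(groups).astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 categories")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among categories {levels}")
    ordered = [reference] + [l for l in levels if l != reference]
    codes = pd.Categorical(groups, categories=ordered).codes
    if (np.bincount(codes, minlength=len(ordered)) == 0).any():
        raise ValueError("every category must be present")
    X = _with_intercept(design)
    _check_design(X)
    res = sm.MNLogit(codes, X.to_numpy(float)).fit(
        method="newton", maxiter=100, disp=0, tol=1e-10
    )
    params = np.asarray(res.params)       # p x (G-1)
    if np.abs(params).max() > SEPARATION_BOUND:
        raise SeparationError(
            "coefficients diverged (|beta| > 15); data are (quasi-)separated"
        )
    bse = np.asarray(res.bse)
    index = pd.MultiIndex.from_product(
        [ordered[1:], X.columns], names=["category", "term"]
    )
    table = _wald_table(params.T.ravel(), bse.T.ravel(), index)
    return FittedModel(
        model_family="multinomial",
        terms=list(X.columns),
        table=table,
        log_likelihood=float(res.llf),
        aic=float(2 * params.size - 2 * res.llf),
        n_used=len(codes),
        reference_levels={"group": reference},
    )


def _fit(outcome, design, family: str, reference: str | None) -> FittedModel:
    if family == "logistic":
        return fit_logistic(outcome, design)
    return fit_multinomial(outcome, design, reference)


@dataclass
class ScreenResult:
    kept: list[str]
    p_values: dict[str, float]
    separating: list[str]


def univariate_screen(
    outcome: Sequence,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "logistic",
    reference: str | None = None,
) -> ScreenResult:
    """Single-predictor fits; keep covariates with Wald p < alpha.

    For multinomial outcomes a covariate passes if its smallest Wald p
    across category logits is < alpha.  Covariates that separate the
    outcome are retained and flagged."""
    kept, pvals, separating = [], {}, []
    for name in covariates.columns:
        design = covariates[[name]]
        try:
            fit = _fit(outcome, design, family, reference)
        except (SeparationError, np.linalg.LinAlgError):
            kept.append(name)
            separating.append(name)
            pvals[name] = 0.0
            continue
        if fit.model_family == "logistic":
            p = float(fit.table.loc[name, "p_value"])
        else:
            p = float(fit.table.xs(name, level="term")["p_value"].min())
        pvals[name] = p
        if p < alpha:
            kept.append(name)
    return ScreenResult(kept, pvals, separating)


def stepwise_aic(
    outcome: Sequence,
    forced: pd.DataFrame,
    candidates: pd.DataFrame,
    direction: str = "both",
    family: str = "logistic",
    reference: str | None = None,
) -> FittedModel:
    """Stepwise covariate selection minimizing AIC.

    Starts from the forced-terms-only model (forced terms never leave);
    at each step evaluates single-term additions and, with direction
    "both", removals of non-forced terms; applies the AIC-minimizing move
    and stops when no move lowers AIC.  Deterministic: ties break by term
    name order.  Moves whose fit fails (separation, collinearity) are
    skipped.
    """
    if direction not in ("both", "forward"):
        raise ValueError("direction must be 'both' or 'forward'")
    included: list[str] = []

    def build(terms: list[str]) -> pd.DataFrame:
        return pd.concat([forced, candidates[terms]], axis=1)

    current = _fit(outcome, build(included), family, reference)
    while True:
        moves: list[tuple[float, str, str]] = []
        for name in sorted(c for c in candidates.columns if c not in included):
            try:
                fit = _fit(outcome, build(sorted(included + [name])), family, reference)
            except (SeparationError, RankDeficiencyError, ValueError,
                    np.linalg.LinAlgError):
                continue
            moves.append((fit.aic, "add", name))
        if direction == "both":
            for name in sorted(included):
                rest = sorted(t for t in included if t != name)
                try:
                    fit = _fit(outcome, build(rest), family, reference)
                except (SeparationError, RankDeficiencyError, ValueError,
                    np.linalg.LinAlgError):
                    continue
                moves.append((fit.aic, "drop", name))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, name = moves[0]
        if best_aic >= current.aic - 1e-9:
            break
        if action == "add":
            included = sorted(included + [name])
        else:
            included = sorted(t for t in included if t != name)
        current = _fit(outcome, build(included), family, reference)
    return current


def _group_dummies(
    solution: ClusterSolution,
) -> tuple[pd.DataFrame, str, list[str]]:
    """Reference-coded group dummies, reference = least persistent group."""
    if solution.order is None:
        raise ValueError("solution must be named (name_groups) first")
    order = list(solution.order)
    names = solution.group_names
    ref_g = order[0]
    cols = {}
    for g in order[1:]:
        cols[f"group[{names[g]}]"] = (solution.labels == g).astype(float)
    return pd.DataFrame(cols), names[ref_g], [names[g] for g in order]


def group_outcome_model(
    solution: ClusterSolution,
    table: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
    missing_as_smoker: bool = False,
) -> FittedModel:
    """Abstinence ~ trajectory group + AIC-selected covariates.

    ``table`` rows align with the clustered matrix and must carry an
    ``abstinent`` column (NaN = missing outcome).  Complete-case by
    default; ``missing_as_smoker`` recodes missing outcomes as 0.  Group
    dummies (reference = least persistent group) are forced; covariates
    that pass the univariate screen enter stepwise-AIC selection.
    """
    if len(table) != solution.n:
        raise ValueError("participant table must align with cluster labels")
    if "abstinent" not in table.columns:
        raise ValueError("participant table must have an 'abstinent' column")
    y = table["abstinent"].to_numpy(dtype=float)
    if missing_as_smoker:
        y = np.nan_to_num(y, nan=0.0)
    keep = ~np.isnan(y)
    dummies, ref, _ = _group_dummies(solution)
    labels = solution.labels[keep]
    if len(np.unique(labels)) < solution.k:
        raise ValueError("a trajectory group has zero retained outcomes")
    cov_names = [c for c in (covariates if covariates is not None else [])
                 if c in table.columns]
    cov = table.loc[keep, cov_names].astype(float) if cov_names else pd.DataFrame(
        index=table.index[keep])
    cov = cov.reset_index(drop=True)
    forced = dummies.loc[keep].reset_index(drop=True)
    yk = y[keep]
    screened = univariate_screen(yk, cov, alpha).kept if cov_names else []
    fit = stepwise_aic(yk, forced, cov[screened], family="logistic")
    fit.reference_levels["group"] = ref
    return fit


def baseline_predictor_model(
    solution: ClusterSolution,
    table: pd.DataFrame,
    covariates: Sequence[str],
    alpha: float = 0.05,
) -> FittedModel:
    """Trajectory-group membership ~ AIC-selected baseline covariates.

    Multinomial for k >= 3 groups, plain logistic for k = 2; reference is
    the least persistent (lowest-use) group in both cases."""
    if len(table) != solution.n:
        raise ValueError("participant table must align with cluster labels")
    _, ref, ordered_names = _group_dummies(solution)
    names = np.array(solution.group_names)[solution.labels]
    cov = table[list(covariates)].astype(float).reset_index(drop=True)
    if solution.k == 2:
        y = (names != ref).astype(float)
        family, reference = "logistic", None
    else:
        y, family, reference = names, "multinomial", ref
    screened = univariate_screen(y, cov, alpha, family, reference).kept
    empty = pd.DataFrame(index=cov.index)
    fit = stepwise_aic(y, empty, cov[screened], family=family, reference=reference)
    fit.reference_levels["group"] = ref
    return fit


def model_report(fit: FittedModel) -> pd.DataFrame:
    """Flat CSV-ready report: term, OR, CI bounds, p, AIC."""
    tbl = fit.table.reset_index()
    tbl["aic"] = fit.aic
    tbl["log_likelihood"] = fit.log_likelihood
    tbl["n_used"] = fit.n_used
    return tbl
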