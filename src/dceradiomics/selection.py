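"""Cohort split, three-stage feature selection and logistic rad-scores.

The selection cascade mirrors standard radiomic-signature practice:

1. reproducibility filter — two-way random-effects, single-rater,
   absolute-agreement intraclass correlation ICC(2,1) between two
   readers' feature tables; keep ICC > 0.8;
2. univariate screen — Welch two-sample t-test, keep p < 0.1;
3. LASSO — L1-penalized logistic path, λ chosen by 10-fold
   cross-validated binomial deviance (minimum rule by default, 1-SE
   available);
4. backward stepwise elimination under AIC.

Surviving features enter an unpenalized logistic model whose linear
predictor is the rad-score.  Intratumoral and peritumoral signatures
are selected independently; the multiregional signature re-runs LASSO
and stepwise on the union of their survivors.  Every stage uses
training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm

from .features import FeatureTable, standardize

__all__ = [
    "EmptyCandidateError",
    "SelectionResult",
    "RadScoreModel",
    "EndpointResult",
    "split_cohort",
    "icc_2_1",
    "icc_filter",
    "ttest_filter",
    "lasso_select",
    "stepwise_select",
    "fit_radscore",
    "build_multiregional",
    "run_endpoint",
]


class EmptyCandidateError(RuntimeError):
    """Raised when a selection stage leaves an empty candidate set."""


@dataclass
class SelectionResult:
    """Audit trail of one region's selection cascade."""

    stage_survivors: dict[str, list[str]] = field(default_factory=dict)
    icc_values: pd.Series | None = None
    p_values: pd.Series | None = None
    lasso_lambda: float | None = None
    aic_final: float | None = None
    flags: list[str] = field(default_factory=list)

    def assert_nested(self) -> None:
        order = [s for s in ("icc", "ttest", "lasso", "stepwise")
                 if s in self.stage_survivors]
        for outer, inner in zip(order, order[1:]):
            if not set(self.stage_survivors[inner]) <= set(self.stage_survivors[outer]):
                raise AssertionError(f"{inner} survivors not nested in {outer}")


@dataclass
class RadScoreModel:
    """Logistic rad-score: intercept + Σ coef·feature (standardized units)."""

    endpoint: str
    region_scope: str   # intra | peri | multi
    intercept: float
    coefficients: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def rad_score(self, df: pd.DataFrame) -> pd.Series:
        score = pd.Series(self.intercept, index=df.index, dtype=float)
        for name, coef in self.coefficients.items():
            score = score + coef * df[name]
        return score

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RadScoreModel":
        return cls(**json.loads(text))


def split_cohort(cohort, train_fraction: float = 0.8):
    """Temporal 4:1-style split: earliest patients train, latest validate.

    ``cohort`` is a list of studies (with ``acquisition_index``) or an
    array of acquisition indices.  Returns positional index arrays
    (train, validation); the first floor(train_fraction·n) patients by
    acquisition order form the training set.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    acq = np.asarray(
        [getattr(s, "acquisition_index", s) for s in cohort], dtype=float
    )
    n = acq.size
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    order = np.argsort(acq, kind="stable")
    return order[:n_train], order[n_train:]


def icc_2_1(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) for two raters over columns of features.

    Two-way random effects, absolute agreement, single rater:
    (MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n) for k = 2 raters.
    Zero-variance features return NaN.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("reader tables must have identical shape")
    n = x1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = 2
    data = np.stack([x1, x2])                       # (k, n, F)
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=0)                        # (n, F)
    rater = data.mean(axis=1)                       # (k, F)
    ssr = k * ((subj - grand) ** 2).sum(axis=0)
    ssc = n * ((rater - grand) ** 2).sum(axis=0)
    sst = ((data - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc[sst == 0] = np.nan
    return icc


def icc_filter(
    df_reader1: pd.DataFrame,
    df_reader2: pd.DataFrame,
    threshold: float = 0.8,
) -> tuple[list[str], pd.Series, list[str]]:
    """Keep features whose inter-reader ICC(2,1) is strictly > threshold.

    Returns (retained names, per-feature ICC, flagged undefined names).
    Zero-variance features have undefined ICC and are dropped.
    """
    if not df_reader1.columns.equals(df_reader2.columns):
        raise ValueError("reader tables must share feature columns")
    if not df_reader1.index.equals(df_reader2.index):
        raise ValueError("reader tables must share rows")
    icc = pd.Series(
        icc_2_1(df_reader1.to_numpy(), df_reader2.to_numpy()),
        index=df_reader1.columns,
        name="icc",
    )
    undefined = icc.index[icc.isna()].tolist()
    retained = icc.index[icc > threshold].tolist()
    return retained, icc, undefined


def ttest_filter(
    df: pd.DataFrame,
    labels,
    alpha: float = 0.1,
    features: list[str] | None = None,
    equal_var: bool = False,
) -> tuple[list[str], pd.Series]:
    """Per-feature two-sample t-test screen (Welch by default)."""
    if features is not None:
        df = df[features]
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need at least 2 members")
    a = df.to_numpy()[y == 1]
    b = df.to_numpy()[y == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = pd.Series(res.pvalue, index=df.columns, name="p_value")
    p = p.fillna(1.0)  # zero variance in both groups, equal means
    return p.index[p < alpha].tolist(), p


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which the L1 logistic solution is all-zero."""
    n = y.size
    resid = y - y.mean()
    return float(np.abs(X.T @ resid).max() / n)


def lasso_select(
    df: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
    lambda_rule: str = "min",
    n_lambdas: int = 25,
    lambda_min_ratio: float = 1e-2,
    lambda_override: float | None = None,
) -> tuple[list[str], float]:
    """L1-penalized logistic selection with cross-validated λ.

    The λ path runs geometrically from λ_max (all coefficients zero)
    down to ``lambda_min_ratio``·λ_max; λ is chosen to minimize the
    mean out-of-fold binomial deviance (``lambda_rule='min'``) or by
    the one-standard-error rule (``'1se'``).  Folds are stratified and
    seeded; on small cohorts the fold count is capped at the minority
    class size.  Returns (features with nonzero coefficients at λ
    refit on the full data, chosen λ).
    """
    if features is not None:
        df = df[features]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant")
    if df.shape[0] < n_folds:
        raise ValueError("fewer rows than folds")
    X = df.to_numpy()
    n = X.shape[0]
    lam_max = _lambda_max(X, y)
    if lam_max == 0:
        return [], 0.0

    if lambda_override is not None:
        lam = float(lambda_override)
    else:
        n_folds = min(n_folds, int((y == 0).sum()), int((y == 1).sum()))
        if n_folds < 2:
            raise ValueError("too few members per class for cross-validation")
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        deviance = np.zeros((n_folds, n_lambdas))
        for f, (tr, te) in enumerate(cv.split(X, y)):
            for j, lam_j in enumerate(lambdas):
                model = _l1_logistic(X[tr], y[tr], lam_j)
                p = model.predict_proba(X[te])[:, 1]
                deviance[f, j] = 2.0 * log_loss(
                    y[te], p, normalize=True, labels=[0, 1]
                )
        mean_dev = deviance.mean(axis=0)
        j_min = int(np.argmin(mean_dev))
        if lambda_rule == "1se":
            se = deviance.std(axis=0, ddof=1) / np.sqrt(n_folds)
            ok = mean_dev <= mean_dev[j_min] + se[j_min]
            j_min = int(np.nonzero(ok)[0][0])  # largest λ within 1 SE
        elif lambda_rule != "min":
            raise ValueError("lambda_rule must be 'min' or '1se'")
        lam = float(lambdas[j_min])

    model = _l1_logistic(X, y, lam)
    coefs = model.coef_.ravel()
    survivors = [c for c, w in zip(df.columns, coefs) if w != 0.0]
    return survivors, lam


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C·Σlogloss + |w|_1; glmnet-style λ maps to C = 1/(nλ).
    C = 1.0 / max(lam * X.shape[0], 1e-12)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0
    )
    model.fit(X, y)
    return model


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit; (params, aic, converged flag).

    ``X`` excludes the constant; an intercept column is prepended.
    Falls back to a weakly ridge-penalized fit (flagged) when maximum
    likelihood fails, e.g. under perfect separation.
    """
    import warnings

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, warn_convergence=False)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
            return np.asarray(res.params), float(res.aic), True
    except Exception:
        pass
    ridge = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000)
    if X.shape[1] > 0:
        ridge.fit(X, y)
        params = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
        p = ridge.predict_proba(X)[:, 1]
    else:
        p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        params = np.array([np.log(p0 / (1 - p0))])
        p = np.full(y.shape, p0)
    loglik = -log_loss(y, p, normalize=False, labels=[0, 1])
    aic = 2.0 * params.size - 2.0 * loglik
    return params, float(aic), False


def stepwise_select(
    df: pd.DataFrame, labels, start_features: list[str]
) -> tuple[list[str], float, bool]:
    """Backward elimination under AIC.

    Repeatedly removes the feature whose removal most decreases the
    AIC of the logistic model; stops at a local minimum.  AIC ties are
    broken by dropping the feature with the largest Wald p-value.
    Returns (survivors, final AIC, all-fits-converged flag).
    """
    if not start_features:
        raise ValueError("start_features must be non-empty")
    y = np.asarray(labels, dtype=int)
    current = list(start_features)
    params, aic, ok = _fit_logit(df[current].to_numpy(), y)
    all_converged = ok
    while len(current) > 0:
        trials = []
        for feat in current:
            reduced = [f for f in current if f != feat]
            _, aic_r, ok_r = _fit_logit(df[reduced].to_numpy(), y)
            trials.append((aic_r, feat, ok_r))
        best_aic = min(t[0] for t in trials)
        if best_aic >= aic - 1e-10:
            break
        candidates = [t for t in trials if abs(t[0] - best_aic) <= 1e-10]
        if len(candidates) > 1:
            # tie-break: drop the least significant feature
            pvals = _wald_pvalues(df[current].to_numpy(), y, current)
            candidates.sort(key=lambda t: -pvals.get(t[1], 0.0))
        aic, drop, ok = candidates[0][0], candidates[0][1], candidates[0][2]
        all_converged = all_converged and ok
        current.remove(drop)
    return current, float(aic), all_converged


def _wald_pvalues(X: np.ndarray, y: np.ndarray, names: list[str]) -> dict[str, float]:
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200, warn_convergence=False
            )
        return dict(zip(names, np.asarray(res.pvalues)[1:]))
    except Exception:
        return {}


def fit_radscore(
    df: pd.DataFrame, labels, features: list[str], scope: str, endpoint: str = ""
) -> RadScoreModel:
    """Unpenalized logistic fit over the selected features.

    With an empty feature list the model is intercept-only and the
    rad-score is constant.  A non-ML fallback fit is flagged.
    """
    y = np.asarray(labels, dtype=int)
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise KeyError(f"features not in table: {missing[:5]}")
    params, _, converged = _fit_logit(df[features].to_numpy(), y)
    flags = [] if converged else ["penalized_fallback"]
    return RadScoreModel(
        endpoint=endpoint,
        region_scope=scope,
        intercept=float(params[0]),
        coefficients={f: float(w) for f, w in zip(features, params[1:])},
        flags=flags,
    )


def _select_region(
    df_train: pd.DataFrame,
    y_train: np.ndarray,
    candidates: list[str],
    icc_values: pd.Series,
    seed: int,
    alpha: float,
    n_folds: int,
    lambda_rule: str,
    equal_var: bool,
) -> SelectionResult:
    result = SelectionResult(icc_values=icc_values)
    result.stage_survivors["icc"] = list(candidates)
    if not candidates:
        raise EmptyCandidateError("empty candidate set after ICC filter")
    tt_survivors, pvals = ttest_filter(
        df_train, y_train, alpha=alpha, features=candidates, equal_var=equal_var
    )
    result.p_values = pvals
    result.stage_survivors["ttest"] = tt_survivors
    if not tt_survivors:
        raise EmptyCandidateError("empty candidate set after t-test")
    lasso_survivors, lam = lasso_select(
        df_train, y_train, n_folds=n_folds, seed=seed,
        features=tt_survivors, lambda_rule=lambda_rule,
    )
    result.lasso_lambda = lam
    result.stage_survivors["lasso"] = lasso_survivors
    if not lasso_survivors:
        # Full shrinkage: intercept-only signature downstream.
        result.stage_survivors["stepwise"] = []
        result.flags.append("lasso_selected_none")
        return result
    sw_survivors, aic, converged = stepwise_select(df_train, y_train, lasso_survivors)
    result.stage_survivors["stepwise"] = sw_survivors
    result.aic_final = aic
    if not converged:
        result.flags.append("penalized_fallback")
    return result


def build_multiregional(
    intra_survivors: list[str],
    peri_survivors: list[str],
    df_train: pd.DataFrame,
    y_train,
    seed: int,
    n_folds: int = 10,
    lambda_rule: str = "min",
    endpoint: str = "",
) -> tuple[RadScoreModel, SelectionResult]:
    """Fuse regions: LASSO + stepwise over the union of survivors."""
    seen = set()
    union = [f for f in list(intra_survivors) + list(peri_survivors)
             if not (f in seen or seen.add(f))]
    if not union:
        raise EmptyCandidateError("no surviving features in either region")
    y = np.asarray(y_train, dtype=int)
    result = SelectionResult()
    result.stage_survivors["candidates"] = union
    lasso_survivors, lam = lasso_select(
        df_train, y, n_folds=n_folds, seed=seed, features=union,
        lambda_rule=lambda_rule,
    )
    result.lasso_lambda = lam
    result.stage_survivors["lasso"] = lasso_survivors
    if lasso_survivors:
        sw, aic, converged = stepwise_select(df_train, y, lasso_survivors)
        result.aic_final = aic
        if not converged:
            result.flags.append("penalized_fallback")
    else:
        sw = []
        result.flags.append("lasso_selected_none")
    result.stage_survivors["stepwise"] = sw
    model = fit_radscore(df_train, y, sw, scope="multi", endpoint=endpoint)
    return model, result


@dataclass
class EndpointResult:
    """Everything fitted for one receptor endpoint."""

    endpoint: str
    models: dict[str, RadScoreModel]
    selection: dict[str, SelectionResult]
    table: FeatureTable          # standardized with training μ/SD
    train_idx: np.ndarray
    val_idx: np.ndarray


def run_endpoint(
    table_reader1: FeatureTable,
    table_reader2: FeatureTable,
    labels,
    train_idx,
    val_idx,
    endpoint: str = "er",
    seed: int = 0,
    icc_threshold: float = 0.8,
    alpha: float = 0.1,
    n_folds: int = 10,
    lambda_rule: str = "min",
    equal_var: bool = False,
) -> EndpointResult:
    """Full selection and rad-score fitting for one endpoint.

    All selection statistics (ICC, t-tests, LASSO folds, stepwise,
    standardization μ/SD, coefficients) are computed on training rows
    only; validation rows are merely transformed and scored.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    y = np.asarray(labels, dtype=int)
    y_train = y[train_idx]

    std = standardize(table_reader1, train_idx)
    df_train = std.df.iloc[train_idx]

    models: dict[str, RadScoreModel] = {}
    selection: dict[str, SelectionResult] = {}
    endpoint_offset = {"er": 0, "pr": 1}.get(endpoint.lower(), 2)
    for i, region in enumerate(("intra", "peri")):
        cols = table_reader1.region_columns(region)
        if not cols:
            raise ValueError(f"no columns with prefix {region}_")
        stable, icc_vals, _ = icc_filter(
            table_reader1.df.iloc[train_idx][cols],
            table_reader2.df.iloc[train_idx][cols],
            threshold=icc_threshold,
        )
        sel = _select_region(
            df_train, y_train, stable, icc_vals,
            seed=seed + 1000 * endpoint_offset + 100 * i,
            alpha=alpha, n_folds=n_folds, lambda_rule=lambda_rule,
            equal_var=equal_var,
        )
        selection[region] = sel
        models[region] = fit_radscore(
            df_train, y_train, sel.stage_survivors["stepwise"],
            scope=region, endpoint=endpoint,
        )

    try:
        multi_model, multi_sel = build_multiregional(
            selection["intra"].stage_survivors["stepwise"],
            selection["peri"].stage_survivors["stepwise"],
            df_train, y_train,
            seed=seed + 1000 * endpoint_offset + 200,
            n_folds=n_folds, lambda_rule=lambda_rule, endpoint=endpoint,
        )
    except EmptyCandidateError:
        # Both regional signatures fully shrunk: constant multi score.
        multi_model = fit_radscore(df_train, y_train, [], "multi", endpoint)
        multi_sel = SelectionResult(
            stage_survivors={"candidates": [], "lasso": [], "stepwise": []},
            flags=["empty_union"],
        )
    models["multi"] = multi_model
    selection["multi"] = multi_sel

    return EndpointResult(
        endpoint=endpoint, models=models, selection=selection,
        table=std, train_idx=train_idx, val_idx=val_idx,
    )
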