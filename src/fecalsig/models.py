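"""Regression and classification models over the harmonized cohort tables.

Two stages:

* Linear mixed-effects regression of fecal calprotectin on host and
  clinical covariates (human-read percentage or neutrophil percentage,
  disease activity, treatment advancement, age) with random intercepts —
  per subject, optionally also per integer year of age.  Fits use REML;
  both Nakagawa marginal and conditional R-squared are reported.

* Gradient-boosted tree classifiers (XGBoost, logistic objective) over
  species features — presence-absence or relative abundance — optionally
  augmented with species count and human-read percentage, trained in
  stratified 5-fold cross-validation with fixed hyperparameters, then
  optionally validated on an external cohort with feature reconciliation.

Fold assignment is a deterministic hash of sample IDs so the protocol is
invariant to input order.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "LmmSpec",
    "LmmResult",
    "ClassifierSpec",
    "CvResult",
    "ValidationResult",
    "fit_calprotectin_lmm",
    "build_features",
    "assign_folds",
    "train_cv_classifier",
    "external_validate",
    "feature_importance",
    "shap_values",
    "DEFAULT_XGB_PARAMS",
]

DEFAULT_XGB_PARAMS: dict[str, float | int | str] = {
    "objective": "binary:logistic",
    "eval_metric": "auc",
    "eta": 0.05,
    "gamma": 1,
    "lambda": 3,
    "max_depth": 10,
    "min_child_weight": 1,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "nthread": 1,
}
DEFAULT_NROUNDS = 200
DEFAULT_NFOLDS = 5
EXCLUDED_FEATURES = ("age", "sex")  # never used as predictors


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmSpec:
    response: str = "calprotectin"
    fixed_terms: Sequence[str] = ("human_pct", "activity_active", "treatment_advancement", "age")
    random_intercepts: Sequence[str] = ("subject_id",)
    exclude_capped: bool = True
    capped_col: str = "calprotectin_capped"


@dataclass
class LmmResult:
    params: pd.DataFrame  # term, estimate, se, pvalue, ci_low, ci_high
    var_fixed: float
    var_random: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_excluded_capped: int
    fallback_ols: bool = False

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _prepare_lmm_frame(table: pd.DataFrame, spec: LmmSpec) -> tuple[pd.DataFrame, int]:
    df = table.copy()
    if "activity_active" in spec.fixed_terms and "activity_active" not in df.columns:
        df["activity_active"] = (df["activity"] == "active").astype(float)
    n_cap = 0
    if spec.exclude_capped and spec.capped_col in df.columns:
        n_cap = int(df[spec.capped_col].sum())
        df = df[~df[spec.capped_col].astype(bool)]
    cols = [spec.response, *spec.fixed_terms, *spec.random_intercepts]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    df = df.dropna(subset=list(dict.fromkeys(cols)))
    return df, n_cap


def fit_calprotectin_lmm(table: pd.DataFrame, spec: LmmSpec | None = None) -> LmmResult:
    """REML fit of the calprotectin mixed model.

    With a single grouping factor a standard random-intercept model is
    fitted; with several, crossed random intercepts are expressed as
    variance components over one all-encompassing group.  When every group
    has a single observation the random intercept is unidentifiable and the
    fit falls back to ordinary least squares with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    spec = spec or LmmSpec()
    df, n_cap = _prepare_lmm_frame(table, spec)
    if df.empty:
        raise ValueError("no rows left after exclusions")
    fixed = " + ".join(spec.fixed_terms) if spec.fixed_terms else "1"
    formula = f"{spec.response} ~ {fixed}"

    groups_col = spec.random_intercepts[0] if spec.random_intercepts else None
    singular = groups_col is not None and df.groupby(groups_col).size().max() == 1

    if groups_col is None or singular:
        if singular:
            warnings.warn(
                "one observation per group; falling back to fixed-effects-only fit",
                stacklevel=2,
            )
        fit = smf.ols(formula, data=df).fit()
        X = pd.DataFrame(fit.model.exog, columns=fit.model.exog_names)
        var_f = float(np.var(X.to_numpy() @ fit.params.to_numpy()))
        var_r = 0.0
        var_e = float(fit.mse_resid)
        ci = fit.conf_int()
        params = pd.DataFrame(
            {
                "estimate": fit.params,
                "se": fit.bse,
                "pvalue": fit.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
        denom = var_f + var_r + var_e
        return LmmResult(
            params, var_f, var_r, var_e,
            var_f / denom, (var_f + var_r) / denom,
            int(fit.nobs), n_cap, fallback_ols=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(spec.random_intercepts) == 1:
            model = smf.mixedlm(formula, data=df, groups=df[groups_col])
        else:
            df = df.copy()
            df["_all"] = 1
            vc = {g: f"0 + C({g})" for g in spec.random_intercepts}
            model = smf.mixedlm(formula, data=df, groups=df["_all"], vc_formula=vc)
        fit = model.fit(reml=True)

    beta = fit.fe_params
    X = pd.DataFrame(fit.model.exog, columns=fit.model.exog_names)
    var_f = float(np.var(X.to_numpy() @ beta.to_numpy()))
    if len(spec.random_intercepts) == 1:
        var_r = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
        var_r += float(np.sum(fit.vcomp)) if fit.vcomp.size else 0.0
    else:
        var_r = float(np.sum(fit.vcomp))
    var_e = float(fit.scale)

    k = len(beta)
    ci = fit.conf_int().iloc[:k]
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": fit.bse.iloc[:k],
            "pvalue": fit.pvalues.iloc[:k],
            "ci_low": ci.iloc[:, 0],
            "ci_high": ci.iloc[:, 1],
        }
    )
    denom = var_f + var_r + var_e
    return LmmResult(
        params, var_f, var_r, var_e,
        var_f / denom if denom > 0 else np.nan,
        (var_f + var_r) / denom if denom > 0 else np.nan,
        int(fit.nobs), n_cap,
    )


# ---------------------------------------------------------------------------
# gradient-boosted classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    task: str = "ControlVsIBD"  # ControlVsIBD | CDvsUC | RemissiveVsActive
    representation: str = "presence_absence"  # or relative_abundance
    feature_blocks: Sequence[str] = ("species", "species_count", "human_reads_pct")
    params: Mapping[str, float | int | str] = field(
        default_factory=lambda: dict(DEFAULT_XGB_PARAMS)
    )
    nrounds: int = DEFAULT_NROUNDS
    n_folds: int = DEFAULT_NFOLDS
    seed: int = 0


@dataclass
class CvResult:
    oof_pred: pd.Series
    auc: float
    roc: pd.DataFrame  # fpr, tpr, threshold
    best_round: int
    model: xgb.Booster
    feature_names: list[str]
    fold_assignment: pd.Series
    per_round_auc: np.ndarray


@dataclass
class ValidationResult:
    pred: pd.Series
    auc: float
    roc: pd.DataFrame
    n_features_dropped: int
    n_features_imputed: int


def build_features(
    species_pct: pd.DataFrame,
    representation: str = "presence_absence",
    feature_blocks: Sequence[str] = ("species",),
    human_reads_pct: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the classifier feature matrix (samples x features).

    ``species_pct`` is species x samples in percent.  Age and sex are never
    included as predictors.
    """
    blocks = []
    st = species_pct.T  # samples x species
    if "species" in feature_blocks:
        if representation == "presence_absence":
            blocks.append((st > 0).astype(np.int8))
        elif representation == "relative_abundance":
            blocks.append(st.astype(float))
        else:
            raise ValueError(f"unknown representation {representation!r}")
    if "species_count" in feature_blocks:
        blocks.append(pd.DataFrame({"species_count": (st > 0).sum(axis=1)}))
    if "human_reads_pct" in feature_blocks:
        if human_reads_pct is None:
            raise ValueError("human_reads_pct block requested but no values given")
        blocks.append(pd.DataFrame({"human_reads_pct": human_reads_pct.reindex(st.index)}))
    X = pd.concat(blocks, axis=1)
    bad = [c for c in X.columns if str(c).lower() in EXCLUDED_FEATURES]
    if bad:
        X = X.drop(columns=bad)
    return X


def assign_folds(
    sample_ids: Sequence[str], labels: Sequence[int], n_folds: int, seed: int
) -> pd.Series:
    """Deterministic, stratified, order-invariant fold assignment.

    Samples are ordered by an md5 hash of (seed, id) within each class and
    dealt round-robin, so every fold contains both classes whenever each
    class has at least ``n_folds`` members.
    """
    ids = list(sample_ids)
    y = np.asarray(labels)
    folds = pd.Series(index=ids, dtype=int)
    for cls in np.unique(y):
        members = [i for i, lab in zip(ids, y) if lab == cls]
        ranked = sorted(
            members,
            key=lambda s: hashlib.md5(f"{seed}:{s}".encode()).hexdigest(),
        )
        for pos, sid in enumerate(ranked):
            folds[sid] = pos % n_folds
    return folds


def train_cv_classifier(
    X: pd.DataFrame, y: Sequence[int], spec: ClassifierSpec | None = None
) -> CvResult:
    """Stratified k-fold CV of a gradient-boosted classifier.

    Per-round validation AUC is averaged across folds; the best round is
    the maximizer, out-of-fold predictions are taken at that round and
    pooled for the reported AUC, and the final model is refit on all data
    at the best round.
    """
    spec = spec or ClassifierSpec()
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    folds = assign_folds(X.index, y, spec.n_folds, spec.seed)
    for f in range(spec.n_folds):
        if np.unique(y[(folds == f).to_numpy()]).size < 2:
            raise ValueError(f"fold {f} is missing a class; too few samples")

    params = dict(spec.params)
    params.setdefault("seed", spec.seed)
    per_round = np.zeros((spec.n_folds, spec.nrounds))
    boosters = []
    for f in range(spec.n_folds):
        tr = (folds != f).to_numpy()
        va = ~tr
        dtr = xgb.DMatrix(X[tr], label=y[tr], feature_names=list(map(str, X.columns)))
        dva = xgb.DMatrix(X[va], label=y[va], feature_names=list(map(str, X.columns)))
        hist: dict = {}
        bst = xgb.train(
            params, dtr, num_boost_round=spec.nrounds,
            evals=[(dva, "val")], evals_result=hist, verbose_eval=False,
        )
        per_round[f] = hist["val"]["auc"][: spec.nrounds]
        boosters.append((bst, va))
    mean_auc = per_round.mean(axis=0)
    best_round = int(np.argmax(mean_auc)) + 1

    oof = pd.Series(np.nan, index=X.index)
    for bst, va in boosters:
        dva = xgb.DMatrix(X[va], feature_names=list(map(str, X.columns)))
        oof[va] = bst.predict(dva, iteration_range=(0, best_round))
    auc = float(roc_auc_score(y, oof.to_numpy()))
    fpr, tpr, thr = roc_curve(y, oof.to_numpy())
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    dall = xgb.DMatrix(X, label=y, feature_names=list(map(str, X.columns)))
    final = xgb.train(params, dall, num_boost_round=best_round)
    return CvResult(
        oof_pred=oof, auc=auc, roc=roc, best_round=best_round, model=final,
        feature_names=list(map(str, X.columns)), fold_assignment=folds,
        per_round_auc=mean_auc,
    )


def external_validate(
    cv: CvResult, X_val: pd.DataFrame, y_val: Sequence[int]
) -> ValidationResult:
    """Apply a fitted model to an external cohort.

    Features are reconciled by name: species absent from the validation
    table are imputed as 0/absent, extra features are dropped.  Below 50%
    overlap a hard warning is issued but prediction still runs.
    """
    y_val = np.asarray(y_val, dtype=int)
    cols = [str(c) for c in X_val.columns]
    overlap = len(set(cols) & set(cv.feature_names))
    n_dropped = len(cols) - overlap
    n_imputed = len(cv.feature_names) - overlap
    if overlap < 0.5 * len(cv.feature_names):
        warnings.warn(
            f"only {overlap}/{len(cv.feature_names)} model features present in "
            "validation cohort; results may be unreliable",
            stacklevel=2,
        )
    Xr = X_val.copy()
    Xr.columns = cols
    Xr = Xr.reindex(columns=cv.feature_names, fill_value=0)
    dmat = xgb.DMatrix(Xr, feature_names=cv.feature_names)
    pred = pd.Series(cv.model.predict(dmat), index=X_val.index)
    auc = float(roc_auc_score(y_val, pred.to_numpy()))
    fpr, tpr, thr = roc_curve(y_val, pred.to_numpy())
    return ValidationResult(
        pred=pred, auc=auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        n_features_dropped=n_dropped, n_features_imputed=n_imputed,
    )


def feature_importance(cv: CvResult) -> pd.DataFrame:
    """Gain/Cover/Frequency importance table, sorted by Gain."""
    booster = cv.model
    gain = booster.get_score(importance_type="gain")
    cover = booster.get_score(importance_type="cover")
    freq = booster.get_score(importance_type="weight")
    rows = []
    for f in cv.feature_names:
        rows.append(
            dict(feature=f, gain=gain.get(f, 0.0), cover=cover.get(f, 0.0),
                 frequency=freq.get(f, 0.0))
        )
    return (
        pd.DataFrame(rows).set_index("feature").sort_values("gain", ascending=False)
    )


def shap_values(cv: CvResult, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample Shapley values (TreeSHAP, log-odds scale) and base values.

    Per sample, the Shapley values plus the base value sum to the model's
    log-odds prediction.
    """
    dmat = xgb.DMatrix(
        X.reindex(columns=cv.feature_names, fill_value=0),
        feature_names=cv.feature_names,
    )
    contrib = cv.model.predict(dmat, pred_contribs=True)
    shap = pd.DataFrame(contrib[:, :-1], index=X.index, columns=cv.feature_names)
    base = pd.Series(contrib[:, -1], index=X.index, name="base_value")
    return shap, base
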