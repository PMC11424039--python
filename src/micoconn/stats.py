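"""Developmental statistics on network measures.

Two families of analysis operate on the per-subject, per-network metric
table:

* **Age-relationship models.** A linear mixed-effects model of each
  measure on age, sex and network with ICV as covariate and a
  subject-level random intercept; alternative models add age-by-network,
  age-by-sex and age-by-network-by-sex interactions and the most
  parsimonious model is chosen by lowest AIC (ML fits, so AICs are
  comparable across fixed-effect structures). Within single networks,
  ordinary least squares of the measure on age + sex + ICV gives the
  adjusted R-squared and the age p-value, judged at alpha = 0.005;
  the same models re-run with connection density as an extra covariate
  check robustness to differences in the number of reconstructed edges.

* **Feature importance.** Elastic-net regression predicting age from
  per-node local efficiencies: an 80:20 train/validation split, feature
  z-scaling with training statistics only, fivefold cross-validation
  over the L1-ratio grid (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1) and a
  log-spaced alpha grid, selection by mean CV R-squared, then ranking of
  nodes by absolute coefficient and their cumulative weight share.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelFit",
    "FeatureImportanceResult",
    "LMM_MODEL_SET",
    "L1_RATIO_GRID",
    "fit_metric_lmm",
    "select_model",
    "per_network_glm",
    "sex_contrasts",
    "density_adjusted_replication",
    "elasticnet_feature_importance",
    "cumulative_weight_share",
    "elasticnet_kkt_violation",
]

logger = logging.getLogger(__name__)

ALPHA = 0.005

LMM_MODEL_SET: dict[str, str] = {
    "main": "{y} ~ age + sex + network + icv",
    "age_by_network": "{y} ~ age + sex + network + icv + age:network",
    "age_by_sex": "{y} ~ age + sex + network + icv + age:sex",
    "age_by_network_by_sex": (
        "{y} ~ age + sex + network + icv + age:network + age:sex"
        " + sex:network + age:network:sex"
    ),
}

# likelihood-ratio tests: model -> (interaction term, reduced-model formula)
LMM_LRT_TESTS: dict[str, tuple[str, str]] = {
    "age_by_network": ("age:network", LMM_MODEL_SET["main"]),
    "age_by_sex": ("age:sex", LMM_MODEL_SET["main"]),
    "age_by_network_by_sex": (
        "age:network:sex",
        "{y} ~ age + sex + network + icv + age:network + age:sex + sex:network",
    ),
}

L1_RATIO_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)


@dataclass
class ModelFit:
    """Fitted-model summary: coefficients, AIC, fit quality, F-tests."""

    name: str
    formula: str
    coef_table: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    aic: float
    n_params: int
    converged: bool = True
    adj_r2: float | None = None
    f_tests: dict[str, dict[str, float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def term(self, name_contains: str) -> pd.DataFrame:
        """Coefficient rows whose term name contains a substring."""
        return self.coef_table[
            self.coef_table["term"].str.contains(name_contains, regex=False)
        ]

    def summary(self) -> str:
        lines = [
            f"Model {self.name!r}: {self.formula}",
            f"  AIC {self.aic:.2f}  params {self.n_params}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
        ]
        if self.adj_r2 is not None:
            lines.append(f"  adjusted R2 {self.adj_r2:.4f}")
        with pd.option_context("display.width", 120):
            lines.append(self.coef_table.to_string(index=False))
        for term, ft in self.f_tests.items():
            lines.append(
                f"  F-test {term}: F={ft['F']:.3f}, df={ft['df']:.0f}, p={ft['p']:.3g}"
            )
        return "\n".join(lines)


def _coef_table(res) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.values,
            "se": res.bse.values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
            "p": res.pvalues.values,
        }
    )


def _prepare(metric_table: pd.DataFrame, metric: str) -> pd.DataFrame:
    df = metric_table[metric_table["group"] != "whole_brain"].copy()
    df = df.rename(columns={"group": "network"})
    df = df.dropna(subset=[metric])
    return df


def fit_metric_lmm(
    metric_table: pd.DataFrame,
    metric: str,
    model_set: dict[str, str] | None = None,
) -> list[ModelFit]:
    """Fit the nested mixed-model set for one network measure.

    Each model carries the fixed effects of :data:`LMM_MODEL_SET` (or a
    caller-supplied set) plus a subject random intercept, fitted by
    maximum likelihood so AICs are comparable. Interaction terms get
    Wald F-tests. Non-converged fits are flagged and excluded from
    AIC selection.
    """
    df = _prepare(metric_table, metric)
    if df["network"].nunique() < 2 or df["subject"].nunique() < 2:
        raise ValueError("need >= 2 networks and >= 2 subjects")
    # z-score ICV: mm^3 values (~1.4e6) otherwise wreck the Hessian's
    # conditioning; slope tests and AIC are invariant to this rescaling
    sd = float(df["icv"].std())
    df["icv"] = (df["icv"] - df["icv"].mean()) / (sd if sd > 0 else 1.0)
    model_set = model_set or LMM_MODEL_SET

    def _fit_ml(formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["subject"])
            last_exc: Exception | None = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    return model.fit(reml=False, method=method)
                except Exception as exc:  # noqa: BLE001 - try next optimizer
                    last_exc = exc
            raise last_exc

    fits: list[ModelFit] = []
    reduced_cache: dict[str, object] = {}
    for name, template in model_set.items():
        formula = template.format(y=metric)
        try:
            res = _fit_ml(formula)
            converged = bool(res.converged)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            logger.warning("model %s failed to fit: %s", name, exc)
            fits.append(
                ModelFit(name, formula, pd.DataFrame(), np.inf, 0, converged=False)
            )
            continue
        k = res.params.size + 1  # fixed effects + RE variance + resid variance
        aic = float(-2 * res.llf + 2 * k)
        fit = ModelFit(
            name=name,
            formula=formula,
            coef_table=_coef_table(res),
            aic=aic,
            n_params=k,
            converged=converged,
            metadata={"pvalue_method": "lrt_chi2 (coef table: wald_normal)",
                      "reml": False},
        )
        reduced_cache[formula] = res
        if name in LMM_LRT_TESTS and model_set is LMM_MODEL_SET:
            term, reduced_template = LMM_LRT_TESTS[name]
            reduced_formula = reduced_template.format(y=metric)
            try:
                if reduced_formula not in reduced_cache:
                    reduced_cache[reduced_formula] = _fit_ml(reduced_formula)
                red = reduced_cache[reduced_formula]
                dfree = res.params.size - red.params.size
                lr = 2.0 * (res.llf - red.llf)
                p = float(scipy.stats.chi2.sf(max(lr, 0.0), dfree))
                fit.f_tests[term] = {
                    "F": max(lr, 0.0) / max(dfree, 1),
                    "df": dfree,
                    "p": p,
                    "method": "likelihood_ratio",
                }
            except Exception as exc:  # noqa: BLE001
                logger.warning("LRT for %s failed: %s", term, exc)
        fits.append(fit)
    return fits


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Most parsimonious fit: lowest AIC, ties toward fewer parameters."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fits to select from")
    return min(ok, key=lambda f: (round(f.aic, 10), f.n_params))


def per_network_glm(
    metric_table: pd.DataFrame,
    metric: str,
    group: str,
    alpha: float = ALPHA,
    extra_covariates: tuple[str, ...] = (),
) -> ModelFit:
    """OLS of one measure on age + sex + ICV within a single network.

    Reports the coefficient table, adjusted R-squared, the age p-value
    and its significance flag at ``alpha``. Zero-variance covariates are
    dropped with a warning.
    """
    df = _prepare(metric_table, metric)
    df = df[df["network"] == group]
    if df.empty:
        raise ValueError(f"no rows for group {group!r}")
    covs = ["age", "sex", "icv", *extra_covariates]
    kept_covs = []
    for c in covs:
        vals = df[c]
        if c != "sex" and float(np.var(vals.astype(float))) == 0.0:
            logger.warning("covariate %s has zero variance; dropped", c)
            continue
        kept_covs.append(c)
    formula = f"{metric} ~ " + " + ".join(kept_covs)
    if len(df) <= len(kept_covs) + 2:
        raise ValueError("fewer rows than model parameters")
    res = smf.ols(formula, data=df).fit()
    age_p = float(res.pvalues.get("age", np.nan))
    return ModelFit(
        name=f"glm_{group}",
        formula=formula,
        coef_table=_coef_table(res),
        aic=float(res.aic),
        n_params=int(res.df_model + 2),
        adj_r2=float(res.rsquared_adj),
        metadata={
            "group": group,
            "age_p": age_p,
            "significant": bool(age_p < alpha),
            "alpha": alpha,
        },
    )


def sex_contrasts(metric_table: pd.DataFrame, metric: str, group: str) -> pd.DataFrame:
    """Sex main effect and age-by-sex interaction within one network.

    Fits metric ~ age * sex + icv and returns the two sex-related
    coefficient rows (estimate, 95% CI, p).
    """
    df = _prepare(metric_table, metric)
    df = df[df["network"] == group]
    if df["sex"].nunique() < 2:
        raise ValueError(f"group {group!r} does not contain both sexes")
    res = smf.ols(f"{metric} ~ age * sex + icv", data=df).fit()
    table = _coef_table(res)
    return table[table["term"].str.contains("sex", regex=False)].reset_index(drop=True)


def density_adjusted_replication(
    metric_table: pd.DataFrame,
    metric: str,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Re-run every per-network GLM with connection density as covariate.

    Returns one row per network with the age p-value and significance
    flag of the unadjusted and density-adjusted models and whether the
    flag changed — the robustness replication of the main result.
    """
    groups = sorted(
        g for g in metric_table["group"].unique() if g != "whole_brain"
    )
    rows = []
    for g in groups:
        plain = per_network_glm(metric_table, metric, g, alpha)
        adj = per_network_glm(metric_table, metric, g, alpha, ("density",))
        rows.append(
            {
                "network": g,
                "age_p": plain.metadata["age_p"],
                "significant": plain.metadata["significant"],
                "age_p_density_adj": adj.metadata["age_p"],
                "significant_density_adj": adj.metadata["significant"],
                "flag_changed": plain.metadata["significant"]
                != adj.metadata["significant"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FeatureImportanceResult:
    """Elastic-net age-prediction outcome for one network's nodes."""

    weights: pd.Series  # per-node coefficients (scaled-feature space)
    validation_r2: float
    validation_rmse: float
    l1_ratio: float
    alpha: float
    ranked_nodes: list[str]
    cumulative_share: np.ndarray
    cv_r2: float
    dropped_features: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        top = ", ".join(self.ranked_nodes[:5])
        return (
            "Elastic-net age prediction\n"
            f"  l1_ratio {self.l1_ratio}, alpha {self.alpha:.4g}, "
            f"CV R2 {self.cv_r2:.3f}\n"
            f"  validation R2 {self.validation_r2:.3f}, "
            f"RMSE {self.validation_rmse:.2f} years\n"
            f"  top nodes: {top}"
        )


def elasticnet_kkt_violation(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float,
    alpha: float, l1_ratio: float,
) -> float:
    """Max violation of the elastic-net stationarity conditions.

    For objective (1/2n)||y - Xb - b0||^2 + alpha(rho||b||_1 +
    (1-rho)/2 ||b||_2^2): active coordinates must satisfy the smooth
    stationarity equation exactly, inactive ones must have gradient
    within the L1 subdifferential. Returns the largest absolute breach.
    """
    n = X.shape[0]
    r = y - X @ coef - intercept
    grad = -(X.T @ r) / n + alpha * (1 - l1_ratio) * coef
    active = coef != 0
    viol = 0.0
    if active.any():
        viol = np.abs(grad[active] + alpha * l1_ratio * np.sign(coef[active])).max()
    if (~active).any():
        viol = max(viol, max(0.0, np.abs(grad[~active]).max() - alpha * l1_ratio))
    return float(viol)


def elasticnet_feature_importance(
    node_features: pd.DataFrame,
    ages: np.ndarray,
    split: float = 0.8,
    l1_grid: tuple[float, ...] = L1_RATIO_GRID,
    k_folds: int = 5,
    seed: int = 0,
    stratify_by_age: bool = True,
    n_alphas: int = 50,
) -> FeatureImportanceResult:
    """Elastic-net age prediction with node-level feature importance.

    Splits subjects ``split``:(1-``split``) into training and validation
    (stratified by age tertile by default so small validation sets span
    the age range), z-scales features with training statistics, grid
    searches (l1_ratio x alpha) by mean ``k_folds``-fold CV R-squared on
    the training set, refits the winner on the full training set, and
    scores the held-out subjects.
    """
    y = np.asarray(ages, dtype=float)
    X = node_features.astype(float)
    if len(X) != y.size:
        raise ValueError("ages must align with the feature rows")
    if len(X) < 10:
        raise ValueError("need at least 10 subjects")

    dropped = [c for c in X.columns if float(X[c].std()) == 0.0]
    if dropped:
        logger.warning("dropping constant features: %s", dropped)
        X = X.drop(columns=dropped)
    names = list(X.columns)

    strat = None
    if stratify_by_age:
        strat = pd.qcut(y, q=3, labels=False, duplicates="drop")
    X_tr, X_va, y_tr, y_va = train_test_split(
        X.values, y, train_size=split, random_state=seed, stratify=strat
    )

    scaler = StandardScaler().fit(X_tr)
    Xs_tr = scaler.transform(X_tr)
    Xs_va = scaler.transform(X_va)

    alpha_max = np.abs(Xs_tr.T @ (y_tr - y_tr.mean())).max() / len(y_tr)
    alphas = alpha_max * np.logspace(1, -4, n_alphas)

    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xs_tr))
    best = None
    for rho in l1_grid:
        for a in alphas:
            scores = []
            for tr_idx, te_idx in folds:
                en = ElasticNet(alpha=a, l1_ratio=rho, max_iter=50_000, tol=1e-8)
                en.fit(Xs_tr[tr_idx], y_tr[tr_idx])
                pred = en.predict(Xs_tr[te_idx])
                ss_res = np.sum((y_tr[te_idx] - pred) ** 2)
                ss_tot = np.sum((y_tr[te_idx] - y_tr[te_idx].mean()) ** 2)
                if ss_tot > 0:  # degenerate folds carry no R2 information
                    scores.append(1.0 - ss_res / ss_tot)
            mean_r2 = float(np.mean(scores)) if scores else -np.inf
            if best is None or mean_r2 > best[0]:
                best = (mean_r2, rho, a)
    cv_r2, rho, a = best

    final = ElasticNet(alpha=a, l1_ratio=rho, max_iter=200_000, tol=1e-10)
    final.fit(Xs_tr, y_tr)
    pred = final.predict(Xs_va)
    ss_res = float(np.sum((y_va - pred) ** 2))
    ss_tot = float(np.sum((y_va - y_va.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_va - pred) ** 2)))

    weights = pd.Series(final.coef_, index=names)
    order = weights.abs().sort_values(ascending=False, kind="stable").index
    absw = weights.abs().loc[order].values
    total = absw.sum()
    cumshare = np.cumsum(absw) / total if total > 0 else np.full(absw.size, np.nan)

    return FeatureImportanceResult(
        weights=weights,
        validation_r2=r2,
        validation_rmse=rmse,
        l1_ratio=rho,
        alpha=float(a),
        ranked_nodes=list(order),
        cumulative_share=cumshare,
        cv_r2=cv_r2,
        dropped_features=dropped,
        metadata={
            "seed": seed,
            "split": split,
            "k_folds": k_folds,
            "n_alphas": n_alphas,
            "alpha_grid": (float(alphas.min()), float(alphas.max())),
            "stratified": stratify_by_age,
            "n_train": len(y_tr),
            "n_validation": len(y_va),
        },
    )


def cumulative_weight_share(result: FeatureImportanceResult, k: int) -> float:
    """Share of total |coefficient| mass held by the top-k nodes."""
    if not 1 <= k <= len(result.ranked_nodes):
        raise ValueError("k must be between 1 and the number of features")
    if np.all(np.isnan(result.cumulative_share)):
        logger.warning("all coefficients are zero; share undefined")
        return float("nan")
    return float(result.cumulative_share[k - 1])
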