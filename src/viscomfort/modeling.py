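"""Inference stage: PCA over interrelated image statistics, mixed-effects
models for discomfort ratings and SSVEP power, and quadratic
spatial-frequency tuning fits.

The image statistics are strongly inter-correlated, so dimension reduction
precedes regression: PCA is run on the correlation matrix (variables are
z-scored; they carry incommensurate units) and components are retained by
the Kaiser rule (eigenvalue > 1), with explicit overrides allowed.  Rows
with an invalid spectral slope (periodic stimuli) are excluded from the
PCA input.

Ratings and SSVEP power are modelled with linear mixed models: fixed
effects of interest plus an observer random intercept (random slopes
optional).  Estimation is delegated to statsmodels (MixedLM / OLS); the
contract here is the model structure and reporting, not the optimizer.
Spatial-frequency tuning is fitted with linear + quadratic terms in log2
frequency (the stimulus frequency grids are geometric), from which the
peak/trough frequency is the vertex -b/(2a) mapped back to c/deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


# ------------------------------------------------------------------ PCA

@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray           # variables x components (orthonormal cols)
    eigenvalues: np.ndarray        # descending
    variance_explained: np.ndarray  # fractions, sum to 1
    retained: list[int]            # Kaiser rule: eigenvalue > 1
    mean: np.ndarray | None = None
    std: np.ndarray | None = None


def pca_from_correlation(corr: np.ndarray, variables: list[str]) -> PCAResult:
    """Eigen-decomposition of a correlation matrix with a sign convention:
    each component is flipped so its largest-|loading| variable is positive."""
    corr = np.asarray(corr, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    retained = [int(i) for i in np.flatnonzero(eigvals > 1.0)]
    return PCAResult(
        variables=list(variables),
        loadings=eigvecs,
        eigenvalues=eigvals,
        variance_explained=eigvals / eigvals.sum(),
        retained=retained,
    )


def pca_image_stats(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    standardize: bool = True,
) -> PCAResult:
    """Correlation-matrix PCA over the image-statistics columns.

    Rows with missing values (e.g. invalid slope for gratings) are dropped,
    mirroring the exclusion of periodic stimuli.  A constant column is an
    error and is named.
    """
    variables = variables or list(table.columns)
    if len(variables) < 3:
        raise ValueError("PCA needs at least 3 variables")
    data = table[variables].dropna()
    if len(data) < len(variables) + 1:
        raise ValueError(
            f"need at least {len(variables) + 1} complete rows, got {len(data)}"
        )
    X = data.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=0)
    for name, s in zip(variables, std):
        if s == 0:
            raise ValueError(f"variable {name!r} is constant")
    mean = X.mean(axis=0)
    if standardize:
        corr = np.corrcoef(X, rowvar=False)
    else:
        corr = np.cov(X, rowvar=False)
    res = pca_from_correlation(corr, variables)
    res.mean, res.std = mean, std
    return res


def pca_scores(
    table: pd.DataFrame, res: PCAResult, n_components: int | None = None
) -> pd.DataFrame:
    """Project rows onto the principal components (z-scoring with the PCA's
    training mean/std); rows with missing variables get NaN scores."""
    n_components = n_components or len(res.variables)
    X = table[res.variables].to_numpy(dtype=float)
    Z = (X - res.mean) / res.std
    scores = Z @ res.loadings[:, :n_components]
    return pd.DataFrame(
        scores,
        index=table.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


# ----------------------------------------------------------- mixed models

@dataclass
class FitResult:
    formula: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame          # columns [lower, upper], 95%
    pvalues: pd.Series
    group_var: float
    resid_var: float
    marginal_r2: float
    converged: bool
    diagnostics: list[str] = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_lower": self.conf_int.iloc[:, 0],
                "ci_upper": self.conf_int.iloc[:, 1],
                "p": self.pvalues,
            }
        )


def _marginal_r2(fitted_fixed: np.ndarray, group_var: float, resid_var: float) -> float:
    """Variance explained by fixed effects relative to total (fixed + random
    intercept + residual); the standard mixed-model marginal R^2."""
    vf = float(np.var(fitted_fixed, ddof=0))
    denom = vf + group_var + resid_var
    return vf / denom if denom > 0 else float("nan")


def _build_formula(response: str, terms: list[str]) -> str:
    return f"{response} ~ " + " + ".join(terms) if terms else f"{response} ~ 1"


def _fit_mixed(
    formula: str,
    table: pd.DataFrame,
    group: str,
    re_formula: str | None,
) -> FitResult:
    # exactly-linear responses make the mixed model singular; report an OLS
    # fit with a diagnostic instead of a silently degenerate variance estimate
    ols = smf.ols(formula, data=table).fit()
    if np.allclose(ols.resid, 0.0, atol=1e-10):
        ci = ols.conf_int(alpha=0.05)
        return FitResult(
            formula=formula,
            params=ols.params,
            bse=ols.bse,
            conf_int=ci,
            pvalues=ols.pvalues,
            group_var=0.0,
            resid_var=0.0,
            marginal_r2=1.0,
            converged=True,
            diagnostics=["degenerate_zero_residual: OLS coefficients reported"],
        )

    model = smf.mixedlm(formula, data=table, groups=table[group], re_formula=re_formula)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "bfgs"):
            try:
                candidate = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            fit = candidate
            if fit.converged:
                break
    if fit is None:
        raise RuntimeError(f"mixed model failed to fit: {formula}")
    fe = fit.fe_params.index
    ci = fit.conf_int(alpha=0.05).loc[fe]
    group_var = float(np.asarray(fit.cov_re).sum() * fit.scale) if fit.cov_re.size else 0.0
    resid_var = float(fit.scale)
    fitted_fixed = fit.model.exog @ fit.fe_params.to_numpy()
    diagnostics = []
    if not fit.converged:
        diagnostics.append("mixed model did not converge")
    if np.asarray(fit.cov_re).size and np.min(np.diag(fit.cov_re)) < 1e-10:
        diagnostics.append("singular random-effects covariance")
    return FitResult(
        formula=formula,
        params=fit.fe_params,
        bse=fit.bse.loc[fe],
        conf_int=ci,
        pvalues=fit.pvalues.loc[fe],
        group_var=group_var,
        resid_var=resid_var,
        marginal_r2=_marginal_r2(fitted_fixed, group_var, resid_var),
        converged=bool(fit.converged),
        diagnostics=diagnostics,
    )


def fit_rating_model(
    table: pd.DataFrame,
    predictors: list[str],
    response: str = "rating",
    group: str = "observer",
    random_slope: str | None = None,
    baseline_category: str | None = None,
) -> FitResult:
    """Linear mixed model: ``response ~ predictors`` with an observer random
    intercept (plus an optional random slope).

    A ``category`` predictor is treatment-coded against
    ``baseline_category`` so the intercept is the baseline (natural-image)
    category mean.
    """
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 observers")
    terms = []
    for p in predictors:
        if p == "category" and baseline_category is not None:
            terms.append(f"C(category, Treatment('{baseline_category}'))")
        else:
            terms.append(p)
        if p != "category" and not np.all(np.isfinite(table[p].to_numpy(float))):
            raise ValueError(f"predictor {p!r} contains non-finite values")
    formula = _build_formula(response, terms)
    re_formula = f"~{random_slope}" if random_slope else None
    return _fit_mixed(formula, table, group, re_formula)


def fit_sf_tuning(
    table: pd.DataFrame,
    response: str = "rating",
    freq_col: str = "spatial_frequency",
    category_col: str | None = None,
    group: str = "observer",
    random_slope: str | None = None,
    use_log2: bool = True,
) -> FitResult:
    """Quadratic spatial-frequency tuning fit (+ optional category terms).

    The model is ``response ~ sf + sf^2 [+ category + sf:category]`` in log2
    frequency by default (geometric frequency grids).  The tuning vertex in
    c/deg is recovered with :func:`tuning_vertex`.
    """
    freqs = table[freq_col].dropna().unique()
    if len(freqs) < 3:
        raise ValueError(
            f"quadratic tuning needs >= 3 distinct frequencies, got {len(freqs)}"
        )
    data = table.dropna(subset=[freq_col]).copy()
    sf = data[freq_col].to_numpy(dtype=float)
    data["sf_lin"] = np.log2(sf) if use_log2 else sf
    data["sf_quad"] = data["sf_lin"] ** 2
    terms = ["sf_lin", "sf_quad"]
    if category_col is not None:
        terms += [f"C({category_col})", f"sf_lin:C({category_col})"]
    formula = _build_formula(response, terms)
    re_formula = f"~{random_slope}" if random_slope else None
    res = _fit_mixed(formula, data, group, re_formula)
    res.diagnostics.append("sf_scale=log2" if use_log2 else "sf_scale=linear")
    return res


def tuning_vertex(fit: FitResult, use_log2: bool = True) -> float:
    """Peak/trough frequency (c/deg) implied by the quadratic tuning fit."""
    a = fit.params["sf_quad"]
    b = fit.params["sf_lin"]
    if a == 0:
        return float("nan")
    v = -b / (2.0 * a)
    return float(2.0**v) if use_log2 else float(v)


def anova_like_category_test(fit: FitResult) -> pd.DataFrame:
    """Wald summary for the category contrasts of a fitted model."""
    rows = fit.coef_table()
    return rows[rows.index.str.contains("category", case=False)]


__all__ = [
    "PCAResult", "pca_from_correlation", "pca_image_stats", "pca_scores",
    "FitResult", "fit_rating_model", "fit_sf_tuning", "tuning_vertex",
    "anova_like_category_test",
]
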