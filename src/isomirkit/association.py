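"""Covariate-adjusted association of isomiR expression with clinical traits.

For each (isomiR, clinical parameter) pair an ordinary least squares model

    log2(normalized counts + 1) ~ parameter + age + sex + BMI

is fit, influential donors (Cook's distance > 4/n) are removed once and
the model refit, and the parameter's effect is summarized by its
coefficient, two-sided p value, and partial R-squared

    partial R^2 = t^2 / (t^2 + df_resid),

equivalently the relative SSE reduction against the model without the
parameter. The association matrix reports sign(coef) * sqrt(partial R^2)
for significant pairs, a signed effect bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_COVARIATES = ["age", "sex", "bmi"]


@dataclass
class AssociationResult:
    """Per (isomiR, parameter) fit summary."""

    isomir: str
    parameter: str
    coefficient: float
    p_value: float
    partial_r2: float
    n_used: int
    removed_donors: list[str] = field(default_factory=list)

    @property
    def signed_effect(self) -> float:
        return float(np.sign(self.coefficient) * np.sqrt(self.partial_r2))


def _check_design(design: pd.DataFrame) -> None:
    for column in design.columns:
        if column == "const":
            continue
        if np.ptp(design[column].to_numpy()) == 0:
            raise ValueError(f"constant predictor column {column!r} makes the design singular")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix (collinear predictors)")


def fit_adjusted_model(
    expression: pd.Series,
    parameter: pd.Series,
    covariates: pd.DataFrame,
    isomir: str = "isomiR",
    parameter_name: str | None = None,
    cooks_rule: float | None = None,
    log_transform: bool = True,
    min_donors: int = 8,
    swap_response: bool = False,
) -> AssociationResult:
    """Fit the covariate-adjusted linear model for one isomiR and parameter.

    Donors with missing values in any variable are dropped; at least
    `min_donors` complete donors are required. Cook's distance is
    computed on the initial fit and points above the threshold (default
    4/n) are removed in a single pass before refitting. With
    swap_response=True the clinical parameter becomes the response and
    log2 expression the focal predictor (the focal coefficient's t and p
    are not generally invariant to this choice once covariates are
    present).
    """
    parameter_name = parameter_name or (parameter.name if parameter.name else "parameter")
    data = pd.concat(
        {"expression": expression, "parameter": parameter}, axis=1
    ).join(covariates, how="inner")
    data = data.dropna()
    if len(data) < min_donors:
        raise ValueError(
            f"{isomir} ~ {parameter_name}: only {len(data)} complete donors "
            f"(minimum {min_donors})"
        )
    expr = np.log2(data["expression"] + 1.0) if log_transform else data["expression"]
    if swap_response:
        response, focal = data["parameter"], expr.rename("expression")
    else:
        response, focal = expr, data["parameter"]
    focal_name = str(focal.name)
    design = sm.add_constant(
        pd.concat([focal, data[covariates.columns]], axis=1), has_constant="add"
    )
    _check_design(design)

    def _fit(y: pd.Series, X: pd.DataFrame):
        model = sm.OLS(y.to_numpy(dtype=float), X.to_numpy(dtype=float))
        result = model.fit()
        return result

    fit = _fit(response, design)
    n = len(data)
    threshold = cooks_rule if cooks_rule is not None else 4.0 / n
    if np.isfinite(threshold):
        cooks = fit.get_influence().cooks_distance[0]
        influential = design.index[cooks > threshold]
    else:
        influential = design.index[:0]
    removed = [str(d) for d in influential]
    if removed:
        keep = design.index.difference(influential)
        if len(keep) < design.shape[1] + 2:
            raise ValueError(
                f"{isomir} ~ {parameter_name}: too few donors "
                f"({len(keep)}) after influence removal"
            )
        design, response = design.loc[keep], response.loc[keep]
        _check_design(design)
        fit = _fit(response, design)
    focal_idx = list(design.columns).index(focal_name)
    t_value = float(fit.tvalues[focal_idx])
    df_resid = float(fit.df_resid)
    partial_r2 = t_value**2 / (t_value**2 + df_resid)
    return AssociationResult(
        isomir=isomir,
        parameter=parameter_name,
        coefficient=float(fit.params[focal_idx]),
        p_value=float(fit.pvalues[focal_idx]),
        partial_r2=float(partial_r2),
        n_used=int(fit.nobs),
        removed_donors=removed,
    )


def association_matrix(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    parameters: list[str],
    covariate_columns: list[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    adjust: str | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, list[AssociationResult]]:
    """Signed-effect matrix over (isomiR x clinical parameter) pairs.

    `expression` has isomiR rows and donor columns; `metadata` is indexed
    by donor and carries the covariates and parameters. Cells hold
    sign(coef) * sqrt(partial R^2) where the parameter's p value is below
    alpha and 0 otherwise; with adjust="bh", Benjamini-Hochberg-adjusted
    p values (across all fitted pairs) are compared to alpha instead.
    """
    covariates = metadata[covariate_columns]
    fits: list[AssociationResult] = []
    for isomir in expression.index:
        for parameter in parameters:
            fits.append(
                fit_adjusted_model(
                    expression.loc[isomir],
                    metadata[parameter].rename(parameter),
                    covariates,
                    isomir=str(isomir),
                    parameter_name=parameter,
                    **fit_kwargs,
                )
            )
    p_values = np.array([f.p_value for f in fits])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        significant = multipletests(p_values, alpha=alpha, method="fdr_bh")[0]
    elif adjust is None:
        significant = p_values < alpha
    else:
        raise ValueError("adjust must be None or 'bh'")
    matrix = pd.DataFrame(
        0.0, index=list(expression.index), columns=list(parameters)
    )
    for fit, ok in zip(fits, significant):
        if ok:
            matrix.loc[fit.isomir, fit.parameter] = fit.signed_effect
    return matrix, fits
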