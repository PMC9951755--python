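"""Mean/linear prediction-bias decomposition for UN prediction equations.

An equation is evaluated by regressing its residuals (observed minus
predicted UN) on the mean-centered predictions with a diet-type
interaction, in a weighted random-intercept mixed model.  After centering,
the intercept is the *mean bias* (average over/under-prediction, g/d) and
the slope is the *linear bias* (error that grows across the prediction
range); the interaction terms test whether either differs between TMR and
pasture diets.  RMSEP and the relative prediction error (RPE, RMSEP as a
percent of the observed mean) are computed per diet on the raw residuals,
outside the weighted regression.

Sign convention: residuals are observed - predicted everywhere, so a
*negative* mean bias means the equation over-predicts.  Report prose (see
``DietBias.direction``) translates accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import DietType, StudyTable
from .equations import EquationId, CoefficientSet, predict_un
from .lmm import WeightVector, build_weights, fit_weighted_lmm

__all__ = [
    "DietBias",
    "BiasReport",
    "ResidualRegressionRow",
    "residuals",
    "mean_center",
    "assess_bias",
    "residual_covariate_regression",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS: Mapping[str, str] = {
    "MUN": "mun_mgdl",
    "CP": "cp_pct",
    "DMI": "dmi_kg",
    "BW": "bw_kg",
}


@dataclass(frozen=True)
class DietBias:
    mean_bias: float
    mean_bias_se: float
    mean_bias_p: float
    linear_bias: float
    linear_bias_se: float
    linear_bias_p: float
    rmsep: float
    rpe: float

    @property
    def direction(self) -> str:
        return "over-predicted" if self.mean_bias < 0 else "under-predicted"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mean_bias", "mean_bias_se", "mean_bias_p",
            "linear_bias", "linear_bias_se", "linear_bias_p", "rmsep", "rpe")}


@dataclass
class BiasReport:
    equation: str
    per_diet: dict[DietType, DietBias]
    interaction_p_mean: float
    interaction_p_linear: float
    n_obs: int
    n_studies: int

    def to_dict(self) -> dict:
        return {
            "equation": self.equation,
            "per_diet": {d.value: b.to_dict() for d, b in self.per_diet.items()},
            "interaction_p_mean": self.interaction_p_mean,
            "interaction_p_linear": self.interaction_p_linear,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
        }

    def summary(self) -> str:
        lines = [f"Bias assessment for {self.equation}"]
        for d, b in self.per_diet.items():
            lines.append(
                f"  {d.value:<8} mean bias {b.mean_bias:+.2f} (SE {b.mean_bias_se:.2f}, "
                f"p={b.mean_bias_p:.3g}) [{b.direction} on average]; "
                f"linear bias {b.linear_bias:+.3f} (SE {b.linear_bias_se:.3f}, "
                f"p={b.linear_bias_p:.3g}); RMSEP {b.rmsep:.1f} g/d; RPE {b.rpe:.1f}%")
        lines.append(f"  diet interaction p: mean {self.interaction_p_mean:.3g}, "
                     f"linear {self.interaction_p_linear:.3g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ResidualRegressionRow:
    equation: str
    covariate: str
    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "equation", "covariate", "slope", "slope_se", "slope_p",
            "intercept", "intercept_se")}


def residuals(table: StudyTable, eq: EquationId | str | CoefficientSet) -> np.ndarray:
    """Observed minus predicted UN, g/d (negative = over-prediction)."""
    pred = predict_un(eq, table)
    return table.df["un_gd"].to_numpy(float) - pred


def mean_center(values) -> np.ndarray:
    """Subtract the grand mean over the full evaluation set (diets pooled)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot center an empty vector")
    return v - v.mean()


def _weights_for(table: StudyTable, use_weights: bool) -> WeightVector | None:
    if not use_weights:
        return None
    return build_weights(table.df["un_sem"].to_numpy(float))


def assess_bias(table: StudyTable, eq: EquationId | str | CoefficientSet,
                use_weights: bool = True) -> BiasReport:
    """Mean/linear bias of one equation, per diet, with diet-interaction tests.

    The residuals are regressed on diet, the grand-mean-centered
    predictions, and their interaction, with a random study intercept and
    SEm weights.  Two parameterizations of the same model are fitted:
    reference coding for the interaction p-values and cell means for the
    per-diet estimates and their standard errors.  With a single diet
    present the model degrades to intercept + slope with a warning.
    """
    eq_label = eq.value if isinstance(eq, EquationId) else (
        "fitted" if isinstance(eq, CoefficientSet) else str(eq))
    df = table.df
    pred = predict_un(eq, table)
    resid = df["un_gd"].to_numpy(float) - pred
    c = mean_center(pred)
    groups = df["study_id"].to_numpy()
    w = _weights_for(table, use_weights)
    diets = df["diet"].to_numpy()
    present = [d for d in DietType if (diets == d).any()]

    if len(present) == 2:
        past = (diets == DietType.PASTURE).astype(float)
        X_ref = pd.DataFrame({
            "intercept": np.ones(len(df)),
            "diet": past,
            "cpred": c,
            "cpred:diet": c * past,
        })
        fit_ref = fit_weighted_lmm(resid, X_ref, groups, w)
        interaction_p_mean = fit_ref.p_values["diet"]
        interaction_p_linear = fit_ref.p_values["cpred:diet"]

        tmr = 1.0 - past
        X_cm = pd.DataFrame({
            "intercept@TMR": tmr,
            "intercept@PASTURE": past,
            "cpred@TMR": c * tmr,
            "cpred@PASTURE": c * past,
        })
        fit_cm = fit_weighted_lmm(resid, X_cm, groups, w)

        def diet_stats(d: DietType) -> tuple[float, ...]:
            i, s = f"intercept@{d.value}", f"cpred@{d.value}"
            return (fit_cm.coefficients[i], fit_cm.coef_se[i], fit_cm.p_values[i],
                    fit_cm.coefficients[s], fit_cm.coef_se[s], fit_cm.p_values[s])
        stats_by_diet = {d: diet_stats(d) for d in present}
        n_studies = fit_ref.n_studies
    else:
        warnings.warn("single diet type present: fitting a no-interaction bias model",
                      stacklevel=2)
        X = pd.DataFrame({"intercept": np.ones(len(df)), "cpred": c})
        fit = fit_weighted_lmm(resid, X, groups, w)
        interaction_p_mean = interaction_p_linear = float("nan")
        stats_by_diet = {present[0]: (
            fit.coefficients["intercept"], fit.coef_se["intercept"], fit.p_values["intercept"],
            fit.coefficients["cpred"], fit.coef_se["cpred"], fit.p_values["cpred"])}
        n_studies = fit.n_studies

    per_diet = {}
    for d in present:
        mask = diets == d
        r = resid[mask]
        rmsep = float(np.sqrt(np.mean(r**2)))
        obs_mean = float(df.loc[mask, "un_gd"].mean())
        mb, mb_se, mb_p, lb, lb_se, lb_p = stats_by_diet[d]
        per_diet[d] = DietBias(mb, mb_se, mb_p, lb, lb_se, lb_p,
                               rmsep, 100.0 * rmsep / obs_mean)

    return BiasReport(equation=eq_label, per_diet=per_diet,
                      interaction_p_mean=interaction_p_mean,
                      interaction_p_linear=interaction_p_linear,
                      n_obs=len(df), n_studies=n_studies)


def residual_covariate_regression(table: StudyTable, eq: EquationId | str | CoefficientSet,
                                  covariate: str,
                                  use_weights: bool = True) -> ResidualRegressionRow:
    """Weighted random-intercept regression of residuals on one covariate.

    A significant slope means the equation leaves variation on the table
    that the covariate could explain (whether or not the equation already
    includes it with an inadequate coefficient).
    """
    key = covariate.strip().upper()
    if key not in COVARIATE_COLUMNS:
        raise ValueError(f"unknown covariate {covariate!r}; "
                         f"choose from {sorted(COVARIATE_COLUMNS)}")
    col = COVARIATE_COLUMNS[key]
    df = table.df
    if df[col].isna().any():
        raise ValueError(f"covariate {key} (column {col}) missing for some records")
    resid = residuals(table, eq)
    X = pd.DataFrame({"intercept": np.ones(len(df)), key: df[col].to_numpy(float)})
    fit = fit_weighted_lmm(resid, X, df["study_id"].to_numpy(),
                           _weights_for(table, use_weights))
    eq_label = eq.value if isinstance(eq, EquationId) else str(eq)
    return ResidualRegressionRow(
        equation=eq_label, covariate=key,
        slope=fit.coefficients[key], slope_se=fit.coef_se[key], slope_p=fit.p_values[key],
        intercept=fit.coefficients["intercept"], intercept_se=fit.coef_se["intercept"])
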