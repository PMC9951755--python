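"""Closed-form urinary-nitrogen prediction equations.

Seven equations are bundled: three previously published (EQ1-EQ3) and four
developed by this package's meta-regression workflow (EQ4-EQ7).  Equations
whose response is UN per kg of body weight (EQ2, EQ4, EQ7) are multiplied
through by BW so every prediction comes back in g/d.

The per-BW MUN slope of such equations has a physiological reading: with
MUN in mg/dL, multiplying the slope by 100 converts it into the volume of
plasma cleared of urea per kg of body weight per day (L/(kg BW * d)),
the renal clearance rate implied by the equation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import DietType, StudyTable, TreatmentRecord

__all__ = [
    "EquationId",
    "CoefficientSet",
    "PUBLISHED",
    "predict_un",
    "renal_clearance_per_bw",
    "coefficient_percent_difference",
    "MissingCovariateError",
    "NegativePredictionWarning",
]

#: Column in the canonical StudyTable frame backing each term name.
TERM_COLUMNS: Mapping[str, str] = {
    "mun": "mun_mgdl",
    "cp": "cp_pct",
    "dmi": "dmi_kg",
    "bw": "bw_kg",
}


class MissingCovariateError(ValueError):
    """A record lacks a covariate the equation requires."""


class NegativePredictionWarning(UserWarning):
    """An affine equation extrapolated below zero; value returned as-is."""


class EquationId(enum.Enum):
    EQ1 = "EQ1"
    EQ2 = "EQ2"
    EQ3 = "EQ3"
    EQ4 = "EQ4"
    EQ5 = "EQ5"
    EQ6 = "EQ6"
    EQ7 = "EQ7"

    @classmethod
    def parse(cls, value) -> "EquationId":
        if isinstance(value, EquationId):
            return value
        key = str(value).strip().upper()
        if not key.startswith("EQ"):
            key = "EQ" + key
        try:
            return cls(key)
        except ValueError as exc:
            raise ValueError(f"unknown equation id {value!r}") from exc


@dataclass(frozen=True)
class CoefficientSet:
    """Named coefficients of one UN prediction equation.

    ``terms`` hold coefficients shared across diets; ``diet_terms`` hold
    those that differ between the TMR and PASTURE strata.  ``response``
    is ``"un_gd"`` or ``"un_per_bw"``; for the latter the evaluated linear
    predictor is multiplied by BW.  Standard errors are carried for
    reporting only; no uncertainty is propagated into predictions.
    """

    response: str
    terms: Mapping[str, float] = field(default_factory=dict)
    diet_terms: Mapping[DietType, Mapping[str, float]] | None = None
    se: Mapping[str, float] | None = None
    diet_se: Mapping[DietType, Mapping[str, float]] | None = None
    description: str = ""

    def __post_init__(self):
        if self.response not in ("un_gd", "un_per_bw"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.diet_terms is not None:
            levels = set(self.diet_terms)
            if levels != set(DietType):
                raise ValueError("diet_terms must cover both diet types")

    @property
    def diet_specific(self) -> bool:
        return bool(self.diet_terms)

    def required_covariates(self) -> list[str]:
        names = set(self.terms) - {"intercept"}
        for m in (self.diet_terms or {}).values():
            names |= set(m) - {"intercept"}
        covs = [c for c in TERM_COLUMNS if c in names]
        if self.response == "un_per_bw" and "bw" not in covs:
            covs.append("bw")
        return covs

    def evaluate(self, df: pd.DataFrame, label: str = "equation") -> np.ndarray:
        """Evaluate the equation on canonical-column data, returning UN g/d."""
        n = len(df)
        for cov in self.required_covariates():
            col = TERM_COLUMNS[cov]
            if col not in df.columns or df[col].isna().any():
                raise MissingCovariateError(
                    f"{label} requires covariate {cov!r} (column {col!r}) for every record")
        if self.diet_specific and ("diet" not in df.columns or df["diet"].isna().any()):
            raise MissingCovariateError(f"{label} is diet-specific and requires a diet type")

        def linpred(terms: Mapping[str, float], idx: np.ndarray) -> np.ndarray:
            out = np.full(idx.sum(), float(terms.get("intercept", 0.0)))
            for name, coef in terms.items():
                if name == "intercept":
                    continue
                out = out + coef * df.loc[idx, TERM_COLUMNS[name]].to_numpy(float)
            return out

        pred = np.zeros(n)
        all_idx = np.ones(n, dtype=bool)
        pred += linpred(self.terms, all_idx)
        if self.diet_specific:
            diets = df["diet"].map(DietType.parse).to_numpy()
            for diet, terms in self.diet_terms.items():
                idx = diets == diet
                if idx.any():
                    pred[idx] += linpred(terms, idx)
        if self.response == "un_per_bw":
            pred = pred * df["bw_kg"].to_numpy(float)
        if np.any(pred < 0):
            warnings.warn(
                f"{label} produced {int((pred < 0).sum())} negative UN prediction(s); "
                "returned unclipped (out-of-domain extrapolation)",
                NegativePredictionWarning, stacklevel=2)
        return pred


def _load_published() -> dict[EquationId, CoefficientSet]:
    text = resources.files("munmeta").joinpath("data/published_equations.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for key, spec in raw.items():
        diet_terms = spec.get("diet_terms")
        if diet_terms is not None:
            diet_terms = {DietType.parse(k): dict(v) for k, v in diet_terms.items()}
        diet_se = spec.get("diet_se")
        if diet_se is not None:
            diet_se = {DietType.parse(k): dict(v) for k, v in diet_se.items()}
        out[EquationId.parse(key)] = CoefficientSet(
            response=spec["response"],
            terms=dict(spec.get("terms", {})),
            diet_terms=diet_terms,
            se=spec.get("se"),
            diet_se=diet_se,
            description=spec.get("description", ""),
        )
    return out


#: The published coefficient sets, loaded from the bundled config file.
PUBLISHED: dict[EquationId, CoefficientSet] = _load_published()


def _as_frame(record) -> pd.DataFrame:
    if isinstance(record, StudyTable):
        return record.df
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, TreatmentRecord):
        return pd.DataFrame([{
            "diet": record.diet,
            "mun_mgdl": record.mun_mgdl,
            "cp_pct": record.cp_pct,
            "dmi_kg": record.dmi_kg,
            "bw_kg": record.bw_kg,
        }])
    if isinstance(record, Mapping):
        return pd.DataFrame([record])
    raise TypeError(f"cannot evaluate an equation on {type(record).__name__}")


def predict_un(eq, record) -> float | np.ndarray:
    """Predict urinary nitrogen excretion (g/d).

    Parameters
    ----------
    eq : EquationId, str, or CoefficientSet
        One of the bundled equations, or any fitted coefficient set.
    record : TreatmentRecord, StudyTable, DataFrame, or mapping
        Scalar input returns a float; tabular input returns an ndarray
        aligned with the rows.

    Raises
    ------
    MissingCovariateError
        Naming the equation and the covariate that is absent.
    """
    if isinstance(eq, CoefficientSet):
        cs, label = eq, "fitted equation"
    else:
        eq = EquationId.parse(eq)
        cs, label = PUBLISHED[eq], eq.value
    df = _as_frame(record)
    pred = cs.evaluate(df, label=label)
    if not isinstance(record, (StudyTable, pd.DataFrame)):
        return float(pred[0])
    return pred


def renal_clearance_per_bw(coefficient: float) -> float:
    """Renal clearance rate, L/(kg BW * d), implied by a per-BW MUN slope.

    The slope has units (g UN/d)/(kg BW * mg MUN/dL); converting mg/dL to
    g/L makes the conversion factor exactly 100.
    """
    if not coefficient > 0:
        raise ValueError(f"per-BW MUN slope must be > 0, got {coefficient}")
    return coefficient * 100.0


def coefficient_percent_difference(a: float, b: float) -> float:
    """Percent change from slope ``a`` to slope ``b``: 100 * (b - a) / a."""
    if a == 0:
        raise ValueError("reference slope must be nonzero")
    if not a > 0:
        raise ValueError(f"reference slope must be > 0, got {a}")
    return 100.0 * (b - a) / a
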