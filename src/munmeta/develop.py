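"""Development of new UN prediction equations on the training set.

Four candidate model families are fitted as weighted random-intercept
mixed models, each starting from a full design of main effects, the diet
factor, and all covariate-by-diet interactions:

    M4: UN/BW ~ MUN x diet
    M5: UN    ~ (MUN + CP + DMI) x diet
    M6: UN    ~ (MUN + CP + DMI + BW) x diet
    M7: UN/BW ~ (MUN + CP + DMI) x diet

Non-significant terms are removed by backward elimination -- one term at a
time by default (largest p first, ties broken lexicographically), or all
removable terms at once in ``block`` mode.  Elimination respects the model
hierarchy: a main effect stays while any interaction containing it
survives, and the diet factor stays while any diet interaction survives.
The intercept is an ordinary removable term.  Surviving diet interactions
are re-expressed as per-diet (cell-means) coefficients when the final
equation is emitted, and per-BW responses are multiplied through by BW so
the finished equation predicts UN in g/d.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DietType, StudyTable
from .equations import CoefficientSet
from .lmm import FitResult, WeightVector, build_weights, fit_weighted_lmm

__all__ = [
    "CandidateFamily",
    "DevelopedModel",
    "DegenerateModelError",
    "backward_eliminate",
    "finalize_equation",
    "develop_all",
]


class DegenerateModelError(RuntimeError):
    """Backward elimination removed every term."""


class CandidateFamily(enum.Enum):
    """The four candidate model families (response, main covariates)."""

    M4 = ("un_per_bw", ("mun",))
    M5 = ("un_gd", ("mun", "cp", "dmi"))
    M6 = ("un_gd", ("mun", "cp", "dmi", "bw"))
    M7 = ("un_per_bw", ("mun", "cp", "dmi"))

    def __init__(self, response: str, mains: tuple[str, ...]):
        self.response = response
        self.mains = mains

    @classmethod
    def parse(cls, value) -> "CandidateFamily":
        if isinstance(value, CandidateFamily):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError as exc:
            raise ValueError(f"unknown model family {value!r}") from exc

    def initial_terms(self) -> list[str]:
        return (["intercept"] + list(self.mains) + ["diet"]
                + [f"{m}:diet" for m in self.mains])


_TERM_COLUMNS = {"mun": "mun_mgdl", "cp": "cp_pct", "dmi": "dmi_kg", "bw": "bw_kg"}


def _response_vector(df: pd.DataFrame, response: str) -> np.ndarray:
    y = df["un_gd"].to_numpy(float)
    if response == "un_per_bw":
        y = y / df["bw_kg"].to_numpy(float)
    return y


def _design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Reference-coded design: diet indicator is 1 for PASTURE (TMR reference)."""
    past = (df["diet"].to_numpy() == DietType.PASTURE).astype(float)
    cols = {}
    for t in terms:
        if t == "intercept":
            cols[t] = np.ones(len(df))
        elif t == "diet":
            cols[t] = past
        elif t.endswith(":diet"):
            main = t[:-5]
            cols[t] = df[_TERM_COLUMNS[main]].to_numpy(float) * past
        else:
            cols[t] = df[_TERM_COLUMNS[t]].to_numpy(float)
    return pd.DataFrame(cols)


def _cell_means_design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Per-diet columns for every term involved with diet; shared otherwise."""
    diets = df["diet"].to_numpy()
    ind = {d: (diets == d).astype(float) for d in DietType}
    interacting = {t[:-5] for t in terms if t.endswith(":diet")}
    diet_intercepts = "diet" in terms
    cols = {}
    for t in terms:
        if t == "diet" or t.endswith(":diet"):
            continue
        if t == "intercept":
            if diet_intercepts:
                for d in DietType:
                    cols[f"intercept@{d.value}"] = ind[d]
            else:
                cols[t] = np.ones(len(df))
        elif t in interacting:
            x = df[_TERM_COLUMNS[t]].to_numpy(float)
            for d in DietType:
                cols[f"{t}@{d.value}"] = x * ind[d]
        else:
            cols[t] = df[_TERM_COLUMNS[t]].to_numpy(float)
    if diet_intercepts and "intercept" not in terms:
        # a diet main effect with no overall intercept is a per-diet intercept
        for d in DietType:
            cols[f"intercept@{d.value}"] = ind[d]
    return pd.DataFrame(cols)


def _removable(term: str, terms: Sequence[str]) -> bool:
    if term.endswith(":diet") or term == "intercept":
        return True
    if term == "diet":
        return not any(t.endswith(":diet") for t in terms)
    return f"{term}:diet" not in terms


@dataclass
class DevelopedModel:
    """Result of backward elimination for one candidate family."""

    family: CandidateFamily
    final_terms: list[str]
    fit: FitResult
    eliminated: list[tuple[str, float]]
    cell_means_fit: FitResult | None = None

    @property
    def diet_involved(self) -> bool:
        return "diet" in self.final_terms or any(
            t.endswith(":diet") for t in self.final_terms)

    def to_dict(self) -> dict:
        return {
            "family": self.family.name,
            "response": self.family.response,
            "final_terms": self.final_terms,
            "eliminated": [{"term": t, "p_at_removal": p} for t, p in self.eliminated],
            "fit": self.fit.to_dict(),
            "cell_means_fit": self.cell_means_fit.to_dict() if self.cell_means_fit else None,
        }


def backward_eliminate(train: StudyTable, family: CandidateFamily | str,
                       alpha: float = 0.05, use_weights: bool = True,
                       mode: str = "sequential") -> DevelopedModel:
    """Fit a candidate family and backward-eliminate non-significant terms.

    Parameters
    ----------
    alpha : float in (0, 1)
        Removal threshold: a removable term with Wald p > alpha is dropped.
    mode : "sequential" (default) or "block"
        Sequential removes the single worst term per refit; block removes
        every removable non-significant term in one sweep per refit.

    The procedure is deterministic: record order and term declaration
    order do not affect the elimination path (ties on p are broken by
    term name).
    """
    family = CandidateFamily.parse(family)
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if mode not in ("sequential", "block"):
        raise ValueError(f"mode must be 'sequential' or 'block', got {mode!r}")
    df = train.canonical_sort().df
    y = _response_vector(df, family.response)
    groups = df["study_id"].to_numpy()
    w = build_weights(df["un_sem"].to_numpy(float)) if use_weights else None

    terms = family.initial_terms()
    eliminated: list[tuple[str, float]] = []
    while True:
        fit = fit_weighted_lmm(y, _design(df, terms), groups, w)
        candidates = sorted(
            ((t, fit.p_values[t]) for t in terms
             if _removable(t, terms) and fit.p_values[t] > alpha),
            key=lambda tp: (-tp[1], tp[0]))
        if not candidates:
            break
        victims = candidates if mode == "block" else candidates[:1]
        for t, p in victims:
            # in block mode hierarchy may forbid some removals mid-sweep
            if t in terms and _removable(t, terms):
                terms.remove(t)
                eliminated.append((t, float(p)))
        if not terms:
            raise DegenerateModelError(
                f"{family.name}: every term eliminated at alpha={alpha}")

    cm_fit = None
    model = DevelopedModel(family=family, final_terms=list(terms),
                           fit=fit, eliminated=eliminated)
    if model.diet_involved:
        cm_fit = fit_weighted_lmm(y, _cell_means_design(df, terms), groups, w)
        model.cell_means_fit = cm_fit
    return model


def finalize_equation(model: DevelopedModel) -> CoefficientSet:
    """Turn a developed model into a prediction-ready CoefficientSet.

    Surviving diet interactions become per-diet coefficients (from the
    cell-means refit, whose SEs are the per-diet slope SEs).  A per-BW
    response is kept as such in the CoefficientSet; prediction multiplies
    through by BW, so the emitted equation returns UN in g/d.
    """
    response = model.family.response
    if not model.diet_involved:
        return CoefficientSet(
            response=response,
            terms=dict(model.fit.coefficients),
            se=dict(model.fit.coef_se),
            description=f"developed {model.family.name} "
                        f"(terms: {', '.join(model.final_terms)})",
        )
    fit = model.cell_means_fit
    shared: dict[str, float] = {}
    shared_se: dict[str, float] = {}
    diet_terms: dict[DietType, dict[str, float]] = {d: {} for d in DietType}
    diet_se: dict[DietType, dict[str, float]] = {d: {} for d in DietType}
    for name, coef in fit.coefficients.items():
        if "@" in name:
            base, level = name.split("@", 1)
            d = DietType.parse(level)
            diet_terms[d][base] = coef
            diet_se[d][base] = fit.coef_se[name]
        else:
            shared[name] = coef
            shared_se[name] = fit.coef_se[name]
    return CoefficientSet(
        response=response,
        terms=shared,
        se=shared_se or None,
        diet_terms=diet_terms,
        diet_se=diet_se,
        description=f"developed {model.family.name} "
                    f"(terms: {', '.join(model.final_terms)})",
    )


def develop_all(train: StudyTable, alpha: float = 0.05, use_weights: bool = True,
                mode: str = "sequential",
                families: Sequence[CandidateFamily | str] | None = None,
                ) -> dict[CandidateFamily, DevelopedModel]:
    """Backward-eliminate every candidate family on one training table."""
    fams = [CandidateFamily.parse(f) for f in (families or list(CandidateFamily))]
    return {f: backward_eliminate(train, f, alpha=alpha, use_weights=use_weights,
                                  mode=mode) for f in fams}
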