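"""Synthetic treatment-mean tables with the structure the analysis assumes.

The generator emulates a literature-derived meta-analysis data frame:
studies belong to one of two diet strata, each study carries a random
intercept, treatment-mean covariates are drawn around study-level means
(treatment means within a study share animals and base diets, so most of
the covariate spread is between studies), and every record gets a
heterogeneous SEm whose inverse square drives the observation weights.
The response is

    UN_i = truth(covariates_i) + u_study + eps_i,
    u_study ~ N(0, var_study),  eps_i ~ N(0, var_resid / w_i),

with w the normalized inverse-squared-SEm weights -- exactly the error
law the weighted mixed model downstream assumes, so parameter-recovery
tests close the loop.  Default covariate profiles are the training-set
means/SDs of the two strata; the default truth is the published per-BW
equation (-0.253 + 0.00932 MUN + 0.0260 CP) x BW with variance components
matching its reported residual SD and variance partition.

Correlation defaults (BW-DMI +0.6, MUN-CP +0.5) and truncation bounds are
fixture conventions chosen for physiological plausibility, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CP_PER_N, DietType, StudyTable
from .equations import EquationId, CoefficientSet, PUBLISHED, predict_un

__all__ = ["CovariateProfile", "TruthSet", "SimulationConfig", "generate", "inject_bias"]

#: Covariate order used for the correlated draw.
_COVS = ("mun", "bw", "dmi", "cp", "ndf")
_COV_COLUMNS = {"mun": "mun_mgdl", "bw": "bw_kg", "dmi": "dmi_kg",
                "cp": "cp_pct", "ndf": "ndf_pct"}

#: Training-stratum covariate profiles: {covariate: (mean, sd)}.
TMR_PROFILE: Mapping[str, tuple[float, float]] = {
    "mun": (13.2, 3.17), "bw": (647.5, 64.74), "dmi": (22.1, 2.65),
    "cp": (16.7, 1.85), "ndf": (33.1, 5.80),
    "milk_yield": (34.4, 18.84), "dim": (125.7, 70.16),
}
PASTURE_PROFILE: Mapping[str, tuple[float, float]] = {
    "mun": (18.5, 2.46), "bw": (508.6, 63.60), "dmi": (17.0, 3.25),
    "cp": (19.5, 3.40), "ndf": (44.4, 6.74),
    "milk_yield": (20.3, 6.46), "dim": (115.3, 57.73),
}

#: Physiological truncation bounds applied to drawn covariates.
BOUNDS: Mapping[str, tuple[float, float]] = {
    "mun": (2.0, 40.0), "bw": (300.0, 900.0), "dmi": (5.0, 35.0),
    "cp": (8.0, 30.0), "ndf": (15.0, 70.0),
    "milk_yield": (4.0, 80.0), "dim": (5.0, 400.0),
}


@dataclass(frozen=True)
class CovariateProfile:
    """Per-diet covariate means/SDs (units as in the canonical schema)."""

    means: Mapping[str, float]
    sds: Mapping[str, float]

    @classmethod
    def from_table(cls, profile: Mapping[str, tuple[float, float]]) -> "CovariateProfile":
        return cls(means={k: v[0] for k, v in profile.items()},
                   sds={k: v[1] for k, v in profile.items()})


@dataclass(frozen=True)
class TruthSet:
    """The generating equation and variance components of a simulation.

    ``var_study`` and ``var_resid`` are on the UN g/d scale.  Defaults
    match the published per-BW development fit: residual SD ~0.019 g/d per
    kg BW (~11 g/d at typical BW) and a 82.9/17.1 study/residual variance
    split, giving a study SD near 24 g/d.
    """

    coefficients: CoefficientSet = field(
        default_factory=lambda: PUBLISHED[EquationId.EQ7])
    var_study: float = 24.0**2
    var_resid: float = 11.0**2

    def __post_init__(self):
        if self.var_study < 0 or not self.var_resid > 0:
            raise ValueError("need var_study >= 0 and var_resid > 0")

    def expected_un(self, df: pd.DataFrame) -> np.ndarray:
        return predict_un(self.coefficients, df)


def _default_correlations() -> np.ndarray:
    corr = np.eye(len(_COVS))
    idx = {c: i for i, c in enumerate(_COVS)}
    for a, b, rho in (("bw", "dmi", 0.6), ("mun", "cp", 0.5)):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that defines one synthetic data frame.

    Defaults mirror the training split of the source literature: 38 TMR
    and 7 pasture studies with 2-5 treatment means each (~153 means), the
    training covariate profiles, and gamma-distributed SEm (shape 16,
    scale 0.625 g/d: mean ~10 g/d with moderate spread so the resulting
    weight distribution exercises the normalization nontrivially).
    70% of each covariate's variance sits between studies and 30% within.
    """

    seed: int = 0
    n_studies: Mapping[DietType, int] = field(
        default_factory=lambda: {DietType.TMR: 38, DietType.PASTURE: 7})
    means_per_study: tuple[int, int] = (2, 5)
    profiles: Mapping[DietType, CovariateProfile] = field(
        default_factory=lambda: {
            DietType.TMR: CovariateProfile.from_table(TMR_PROFILE),
            DietType.PASTURE: CovariateProfile.from_table(PASTURE_PROFILE)})
    correlations: np.ndarray = field(default_factory=_default_correlations)
    between_var_frac: float = 0.7
    truth: TruthSet = field(default_factory=TruthSet)
    sem_shape: float = 16.0
    sem_scale: float = 0.625
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(BOUNDS))

    def __post_init__(self):
        corr = np.asarray(self.correlations, dtype=float)
        if corr.shape != (len(_COVS), len(_COVS)) or not np.allclose(corr, corr.T):
            raise ValueError(f"correlation matrix must be symmetric {len(_COVS)}x{len(_COVS)}")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        object.__setattr__(self, "correlations", corr)
        if not (0.0 <= self.between_var_frac <= 1.0):
            raise ValueError("between_var_frac must lie in [0, 1]")


def _chol(corr: np.ndarray) -> np.ndarray:
    # tolerate PSD matrices at the boundary
    evals, evecs = np.linalg.eigh(corr)
    return evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))


def generate(config: SimulationConfig) -> tuple[StudyTable, TruthSet]:
    """Draw one synthetic StudyTable; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    L = _chol(config.correlations)
    lo, hi = config.means_per_study
    rows = []
    study_effects = []
    counter = 0
    for diet in DietType:
        prof = config.profiles[diet]
        sd_vec = np.array([prof.sds[c] for c in _COVS])
        mean_vec = np.array([prof.means[c] for c in _COVS])
        between_sd = sd_vec * np.sqrt(config.between_var_frac)
        within_sd = sd_vec * np.sqrt(1.0 - config.between_var_frac)
        for _ in range(int(config.n_studies[diet])):
            counter += 1
            sid = f"10.9999/synthetic-{diet.value.lower()}-{counter:03d}"
            k = int(rng.integers(lo, hi + 1))
            study_mean = mean_vec + between_sd * (L @ rng.standard_normal(len(_COVS)))
            u = rng.normal(0.0, np.sqrt(config.truth.var_study))
            study_effects.append(u)
            for _ in range(k):
                dev = within_sd * (L @ rng.standard_normal(len(_COVS)))
                draw = study_mean + dev
                rec = {"study_id": sid, "diet": diet, "_u": u}
                for i, c in enumerate(_COVS):
                    b = config.bounds[c]
                    rec[_COV_COLUMNS[c]] = float(np.clip(draw[i], b[0], b[1]))
                my = rng.normal(prof.means["milk_yield"], prof.sds["milk_yield"])
                dim = rng.normal(prof.means["dim"], prof.sds["dim"])
                rec["milk_yield_kgd"] = float(np.clip(my, *config.bounds["milk_yield"]))
                rec["dim_d"] = float(np.clip(dim, *config.bounds["dim"]))
                rows.append(rec)
    df = pd.DataFrame(rows)
    df["n_intake_gd"] = df["cp_pct"] / 100.0 * df["dmi_kg"] * 1000.0 / CP_PER_N
    df["un_sem"] = rng.gamma(config.sem_shape, config.sem_scale, size=len(df))

    raw_w = 1.0 / df["un_sem"].to_numpy() ** 2
    w = raw_w / raw_w.mean()
    mu = config.truth.expected_un(df)
    eps = rng.normal(0.0, np.sqrt(config.truth.var_resid / w))
    un = mu + df["_u"].to_numpy() + eps
    df["un_gd"] = np.maximum(un, 1.0)  # physiological floor; never binds at defaults
    df = df.drop(columns="_u")

    table = StudyTable(df, provenance=f"synthetic (seed={config.seed})")
    return table.validate(require_sem=True), config.truth


def inject_bias(table: StudyTable, mean_shift: float = 0.0,
                linear_coef: float = 0.0, diet: DietType | None = None,
                eq: EquationId | str | CoefficientSet = EquationId.EQ1) -> StudyTable:
    """Return a copy with a known bias written into the observed UN.

    For the selected records (one diet, or all when ``diet`` is None):

        un <- un + mean_shift + linear_coef * (pred - grand mean pred)

    where predictions come from ``eq`` and centering uses the grand mean
    over the *whole* table, matching how the bias assessment centers.
    Useful as a known-truth fixture: the bias assessment should recover
    ``mean_shift`` as the mean bias and ``linear_coef`` as the linear
    bias for the targeted diet.
    """
    df = table.df.copy()
    pred = predict_un(eq, table)
    centered = pred - pred.mean()
    mask = np.ones(len(df), dtype=bool) if diet is None else (
        df["diet"].to_numpy() == diet)
    un = df["un_gd"].to_numpy(float)
    un[mask] = un[mask] + mean_shift + linear_coef * centered[mask]
    df["un_gd"] = un
    return StudyTable(df, provenance=table.provenance + " +injected bias")
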