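"""Weighted linear mixed models with one random intercept per study.

The model is

    y = X beta + u_study + eps,   u_study ~ N(0, var_study),
    Var(eps_i) = var_resid / w_i,

with w the St-Pierre weights: inverse squared SEm normalized to mean 1,
which keeps the variance components on the response scale (g UN/d).
Estimation is REML, profiled over the variance ratio
lambda = var_study / var_resid and optimized by bounded scalar search.
Because the random-effect design is one intercept per study, every matrix
with structure D + lambda * 1 1' is handled per study block in closed form
(Sherman-Morrison), so an objective evaluation costs O(n).

Degrees of freedom for Wald t tests use the between-within convention
n_obs - rank(X) - n_studies + 1 (falling back to n_obs - rank(X) when the
random intercept is unidentifiable because every study has one record).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

__all__ = [
    "WeightVector",
    "ModelSpec",
    "FitResult",
    "RankDeficientError",
    "ConvergenceError",
    "build_weights",
    "fit_weighted_lmm",
    "wald_p_values",
    "variance_partition",
]

LAMBDA_MAX = 1e6
LAMBDA_TOL = 1e-10


class RankDeficientError(ValueError):
    """The fixed-effect design matrix is rank deficient (aliased columns listed)."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(f"design matrix rank deficient; aliased column(s): {', '.join(self.aliased)}")


class ConvergenceError(RuntimeError):
    """The REML scalar search failed to converge."""


@dataclass(frozen=True)
class WeightVector:
    """Per-record weights normalized to mean 1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("weights must be finite and > 0")
        if abs(v.mean() - 1.0) > 1e-12:
            raise ValueError("weights must have mean 1 (use build_weights)")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def build_weights(sem) -> WeightVector:
    """St-Pierre weights from treatment-mean SEm values.

    w_i = (1/sem_i^2) / mean_j(1/sem_j^2).  If every SEm is absent the
    fallback is equal weights; a mixture of present and absent SEm is an
    error -- silent partial weighting would distort the fit.
    """
    arr = np.asarray([np.nan if s is None else float(s) for s in np.ravel(sem)], dtype=float)
    if arr.size == 0:
        raise ValueError("empty SEm vector")
    absent = np.isnan(arr)
    if absent.all():
        return WeightVector(np.ones(arr.size))
    if absent.any():
        raise ValueError(f"{int(absent.sum())} of {arr.size} SEm values are absent; "
                         "provide all or none")
    if np.any(arr <= 0):
        raise ValueError("SEm values must be > 0")
    raw = 1.0 / arr**2
    return WeightVector(raw / raw.mean())


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    response: str
    fixed_terms: tuple[str, ...]
    grouping: str = "study_id"
    use_weights: bool = True


@dataclass
class FitResult:
    """Fixed effects, Wald statistics, and variance components of one fit."""

    coefficients: dict[str, float]
    coef_se: dict[str, float]
    p_values: dict[str, float]
    t_values: dict[str, float]
    var_study: float
    var_resid: float
    rsd: float
    var_partition_study_pct: float
    var_partition_resid_pct: float
    loglik_reml: float
    n_obs: int
    n_studies: int
    df_resid: int
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "coef_se": self.coef_se,
            "p_values": self.p_values,
            "var_study": self.var_study,
            "var_resid": self.var_resid,
            "rsd": self.rsd,
            "var_partition_study_pct": self.var_partition_study_pct,
            "var_partition_resid_pct": self.var_partition_resid_pct,
            "loglik_reml": self.loglik_reml,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
            "df_resid": self.df_resid,
        }

    def summary(self) -> str:
        """Plain-text report: coefficient (SE), RSD, variance partition."""
        lines = ["term            estimate (SE)          p"]
        for t, b in self.coefficients.items():
            lines.append(f"{t:<15} {b:> .6g} ({self.coef_se[t]:.3g})   {self.p_values[t]:.3g}")
        lines.append(f"RSD = {self.rsd:.4g}; random-effect variance %: "
                     f"study {self.var_partition_study_pct:.1f}, "
                     f"residual {self.var_partition_resid_pct:.1f}; "
                     f"n = {self.n_obs} records / {self.n_studies} studies")
        return "\n".join(lines)


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> int:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        aliased = [columns[i] for i in sorted(piv[rank:])]
        raise RankDeficientError(aliased)
    return rank


class _Profile:
    """Profiled REML pieces for fixed lambda, exploiting block structure."""

    def __init__(self, y, X, w, group_slices):
        self.y, self.X, self.w = y, X, w
        self.slices = group_slices
        self.Sg = np.array([w[sl].sum() for sl in group_slices])
        self.n, self.p = X.shape

    def _apply_vinv(self, lam, M):
        """V0^{-1} M for V0 = diag(1/w) + lam * block-ones (per group)."""
        wM = self.w[:, None] * M
        out = wM.copy()
        if lam > 0:
            for g, sl in enumerate(self.slices):
                s = wM[sl].sum(axis=0)
                out[sl] -= (lam / (1.0 + lam * self.Sg[g])) * self.w[sl, None] * s[None, :]
        return out

    def pieces(self, lam):
        ViX = self._apply_vinv(lam, self.X)
        XtViX = self.X.T @ ViX
        XtViy = ViX.T @ self.y
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
        resid = self.y - self.X @ beta
        Vir = self._apply_vinv(lam, resid[:, None])[:, 0]
        rss = float(resid @ Vir)
        logdet_v0 = float(-np.log(self.w).sum() + np.log1p(lam * self.Sg).sum())
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        return beta, XtViX, rss, logdet_v0, logdet_xvx

    def objective(self, lam):
        _, _, rss, logdet_v0, logdet_xvx = self.pieces(lam)
        return logdet_v0 + logdet_xvx + (self.n - self.p) * math.log(max(rss, 1e-300))


def fit_weighted_lmm(y, X, groups, weights: WeightVector | None = None) -> FitResult:
    """REML fit of a weighted random-intercept model.

    Parameters
    ----------
    y : array-like, response (g UN/d or g UN/d per kg BW).
    X : DataFrame or 2-D array of the fixed-effect design (named columns).
    groups : array-like of study identifiers, one per record.
    weights : WeightVector, optional; equal weights when omitted.

    Notes
    -----
    With a single record per study the random intercept is confounded with
    the residual; the engine then reports ``var_study = 0`` with a warning
    rather than failing.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    g = np.asarray(groups)
    n, p = Xv.shape
    if len(yv) != n or len(g) != n:
        raise ValueError("y, X, and groups must have matching lengths")
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite values in design or response")

    rank = _check_rank(Xv, columns)
    w = weights.values if weights is not None else np.ones(n)
    if len(w) != n:
        raise ValueError("weights length mismatch")

    codes, uniques = pd.factorize(g)
    n_groups = len(uniques)
    if n_groups < 2:
        warnings.warn("fewer than 2 studies: var_study fixed at 0", stacklevel=2)
    order = np.argsort(codes, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(n)
    ys, Xs, ws, cs = yv[order], Xv[order], w[order], codes[order]
    bounds = np.flatnonzero(np.diff(cs)) + 1
    slices = [slice(a, b) for a, b in zip(np.r_[0, bounds], np.r_[bounds, n])]

    prof = _Profile(ys, Xs, ws, slices)

    degenerate = n_groups >= n or n_groups < 2
    if degenerate:
        if n_groups >= n and n_groups >= 2:
            warnings.warn("one record per study: var_study is confounded with the "
                          "residual and is reported as 0", stacklevel=2)
        lam = 0.0
        converged = True
    else:
        res = optimize.minimize_scalar(
            prof.objective, bounds=(0.0, LAMBDA_MAX), method="bounded",
            options={"xatol": LAMBDA_TOL, "maxiter": 500})
        if not res.success:  # pragma: no cover - bounded search essentially always succeeds
            raise ConvergenceError(f"REML scalar search failed: {res.message}")
        lam = float(res.x)
        # the boundary is a legitimate optimum the interior search can miss
        if prof.objective(0.0) <= res.fun:
            lam = 0.0
        converged = True

    beta, XtViX, rss, logdet_v0, logdet_xvx = prof.pieces(lam)
    dof = n - rank
    sigma2 = rss / dof
    var_resid = float(sigma2)
    var_study = float(lam * sigma2)
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))

    df_resid = n - rank - n_groups + 1 if n_groups < n else n - rank
    df_resid = max(int(df_resid), 1)
    with np.errstate(divide="ignore", invalid="ignore"):  # se=0 on perfect fits
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    if sigma2 > 0:
        loglik = -0.5 * (logdet_v0 + logdet_xvx + dof * (math.log(2.0 * math.pi * sigma2) + 1.0))
    else:  # degenerate perfect fit: the restricted likelihood is unbounded
        loglik = math.inf

    total = var_study + var_resid
    study_pct = 100.0 * var_study / total if total > 0 else float("nan")
    return FitResult(
        coefficients={c: float(b) for c, b in zip(columns, beta)},
        coef_se={c: float(s) for c, s in zip(columns, se)},
        p_values={c: float(pv) for c, pv in zip(columns, pvals)},
        t_values={c: float(tv) for c, tv in zip(columns, tvals)},
        var_study=var_study,
        var_resid=var_resid,
        rsd=float(math.sqrt(var_resid)),
        var_partition_study_pct=study_pct,
        var_partition_resid_pct=100.0 - study_pct if total > 0 else float("nan"),
        loglik_reml=float(loglik),
        n_obs=int(n),
        n_studies=int(n_groups),
        df_resid=df_resid,
        converged=converged,
    )


def wald_p_values(fit: FitResult) -> dict[str, float]:
    """Two-sided p-values from t = estimate/SE on the fit's residual df."""
    out = {}
    for term, b in fit.coefficients.items():
        se = fit.coef_se[term]
        if se == 0:
            raise ValueError(f"zero standard error for term {term!r}")
        out[term] = float(2.0 * stats.t.sf(abs(b / se), fit.df_resid))
    return out


def variance_partition(fit: FitResult) -> tuple[float, float]:
    """(study %, residual %) of the non-fixed variance; sums to 100."""
    total = fit.var_study + fit.var_resid
    if total == 0:
        raise ValueError("both variance components are zero")
    s = 100.0 * fit.var_study / total
    return s, 100.0 - s
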