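"""Agreement statistics between observed and predicted UN on a test set.

Lin's concordance correlation coefficient (CCC) measures how far the
observed-vs-predicted cloud sits from the 1:1 line.  It factors as

    CCC = r * Cb,   Cb = 2 / (v + 1/v + u^2),
    u = (mean_pred - mean_obs) / sqrt(sd_pred * sd_obs)   (location shift)
    v = sd_pred / sd_obs                                  (scale shift)

so r carries precision and Cb (in (0, 1]) carries accuracy: Cb = 1 exactly
when u = 0 and v = 1.  RMSEP = sqrt(mean squared prediction error) and
RPE = 100 * RMSEP / mean observed complete the evaluation.  Population
(n-denominator) moments are used inside the CCC components, which keeps
the covariance-form identity CCC = 2*cov / (var_o + var_p + (m_o - m_p)^2)
exact; descriptive summaries use the sample SD (n-1) as summary tables
conventionally do.  Both conventions are exposed via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import StudyTable
from .equations import EquationId, CoefficientSet, predict_un

__all__ = [
    "AgreementReport",
    "DescriptiveStats",
    "lin_ccc",
    "descriptive_stats",
    "evaluate_on_test",
    "plot_observed_vs_predicted",
]


@dataclass(frozen=True)
class AgreementReport:
    r: float
    u: float
    v: float
    cb: float
    ccc: float
    rmsep: float
    rpe: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("r", "u", "v", "cb", "ccc", "rmsep", "rpe", "n")}


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd: float
    cv_pct: float
    max: float
    min: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("mean", "sd", "cv_pct", "max", "min", "n")}


def _clean(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def lin_ccc(observed, predicted) -> AgreementReport:
    """Concordance of predictions with observations (see module docstring).

    Requires at least 3 paired values and non-constant vectors (the
    correlation is undefined otherwise).
    """
    obs = _clean(observed, "observed")
    pred = _clean(predicted, "predicted")
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must have equal length")
    n = len(obs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    sd_o = obs.std(ddof=0)
    sd_p = pred.std(ddof=0)
    if sd_o == 0 or sd_p == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(obs, pred)[0, 1])
    u = float((pred.mean() - obs.mean()) / np.sqrt(sd_p * sd_o))
    v = float(sd_p / sd_o)
    cb = float(2.0 / (v + 1.0 / v + u**2))
    rmsep = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return AgreementReport(r=r, u=u, v=v, cb=cb, ccc=r * cb,
                           rmsep=rmsep, rpe=100.0 * rmsep / obs.mean(), n=n)


def descriptive_stats(values, ddof: int = 1) -> DescriptiveStats:
    """Mean, SD, CV%, max, min of a UN vector (sample SD by default)."""
    v = _clean(values, "values")
    if v.size == 0:
        raise ValueError("empty vector")
    sd = float(v.std(ddof=ddof)) if v.size > ddof else 0.0
    mean = float(v.mean())
    return DescriptiveStats(mean=mean, sd=sd, cv_pct=100.0 * sd / mean,
                            max=float(v.max()), min=float(v.min()), n=v.size)


def evaluate_on_test(test: StudyTable,
                     eqs: Sequence[EquationId | str] | Mapping[str, CoefficientSet],
                     ) -> dict:
    """Agreement and descriptive statistics of each equation on a test table.

    Returns ``{"observed": DescriptiveStats, "equations": {label:
    {"agreement": AgreementReport, "descriptive": DescriptiveStats}}}``,
    one row per equation, in the shape of a published evaluation table.
    """
    obs = test.df["un_gd"].to_numpy(float)
    out: dict = {"observed": descriptive_stats(obs), "equations": {}}
    if isinstance(eqs, Mapping):
        items = list(eqs.items())
    else:
        items = [(EquationId.parse(e).value, EquationId.parse(e)) for e in eqs]
    for label, eq in items:
        pred = predict_un(eq, test)
        out["equations"][label] = {
            "agreement": lin_ccc(obs, pred),
            "descriptive": descriptive_stats(pred),
        }
    return out


def plot_observed_vs_predicted(test: StudyTable,
                               eqs: Sequence[EquationId | str] | Mapping[str, CoefficientSet],
                               path) -> None:
    """Convenience scatter of predicted vs observed UN with the 1:1 line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = test.df["un_gd"].to_numpy(float)
    if isinstance(eqs, Mapping):
        items = list(eqs.items())
    else:
        items = [(EquationId.parse(e).value, EquationId.parse(e)) for e in eqs]
    fig, ax = plt.subplots(figsize=(6, 6))
    for label, eq in items:
        ax.scatter(obs, predict_un(eq, test), label=label, alpha=0.7, s=25)
    lim = [0, max(1.0, obs.max()) * 1.15]
    ax.plot(lim, lim, "k--", lw=1, label="1:1")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel("Observed UN (g/d)")
    ax.set_ylabel("Predicted UN (g/d)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
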