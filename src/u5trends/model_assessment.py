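"""Model comparison and variance accounting for the space-time fits.

Implements the two fit criteria used to choose between the RW1 and RW2
temporal priors — the deviance information criterion (DIC, lower is
better) and the sum of log conditional predictive ordinates (LCPO, higher
is better) — plus a decomposition of the fitted surface's variation into
the five random-effect components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .spacetime_model import ObservedCells, PosteriorSamples

__all__ = [
    "DicResult",
    "AssessmentReport",
    "dic",
    "cpo_lcpo",
    "variance_decomposition",
    "compare_models",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def _log_densities(samples: PosteriorSamples, cells: ObservedCells) -> np.ndarray:
    """Per-draw, per-cell Gaussian log density: (S, n_obs)."""
    obs = ~np.isnan(cells.y)
    y = cells.y[obs]
    v = cells.v[obs]
    eta = samples.eta_draws()[:, obs]  # (S, n_obs)
    return -0.5 * (_LOG2PI + np.log(v) + (y - eta) ** 2 / v)


def dic(samples: PosteriorSamples, cells: ObservedCells) -> DicResult:
    """DIC = mean deviance + pD, with pD = Dbar - D(posterior-mean eta).

    The deviance is -2 times the Gaussian log likelihood of the observed
    cells given eta (variances known).  Negative pD is possible on poorly
    mixed chains and is left visible rather than clipped.
    """
    if samples.n_draws < 100:
        import warnings

        warnings.warn("fewer than 100 draws; DIC will be noisy")
    ld = _log_densities(samples, cells)
    dev = -2.0 * ld.sum(axis=1)  # (S,)
    mean_dev = float(dev.mean())

    obs = ~np.isnan(cells.y)
    eta_bar = samples.eta_draws().mean(axis=0)[obs]
    y, v = cells.y[obs], cells.v[obs]
    d_at_mean = float(np.sum(_LOG2PI + np.log(v) + (y - eta_bar) ** 2 / v))
    p_d = mean_dev - d_at_mean
    return DicResult(dic=mean_dev + p_d, p_d=p_d, mean_deviance=mean_dev)


def cpo_lcpo(
    samples: PosteriorSamples, cells: ObservedCells, aggregate: str = "sum"
) -> tuple[np.ndarray, float]:
    """Conditional predictive ordinates by the harmonic-mean identity.

    CPO_it = [ S^-1 sum_s 1 / p(y_it | eta_it^(s), v_it) ]^-1, evaluated in
    log space with log-sum-exp.  ``aggregate`` is ``"sum"`` (LCPO = sum of
    log CPO, higher = better) or ``"neg_mean"`` (mean of -log CPO).
    Returns (cpo vector over observed cells in row-major grid order, LCPO).
    """
    ld = _log_densities(samples, cells)  # (S, m)
    S = ld.shape[0]
    log_cpo = np.log(S) - logsumexp(-ld, axis=0)
    cpo = np.exp(log_cpo)
    if not np.all(np.isfinite(log_cpo)):
        bad = int(np.sum(~np.isfinite(log_cpo)))
        import warnings

        warnings.warn(f"{bad} cells have non-finite CPO (flagged, excluded from LCPO)")
    finite = np.isfinite(log_cpo)
    if aggregate == "sum":
        lcpo = float(log_cpo[finite].sum())
    elif aggregate == "neg_mean":
        lcpo = float(-log_cpo[finite].mean())
    else:
        raise ValueError("aggregate must be 'sum' or 'neg_mean'")
    return cpo, lcpo


_COMPONENT_LABELS = {
    "theta": "Space unstructured (independent space)",
    "phi": "Space structured (ICAR space)",
    "gamma": "Time structured (random-walk time)",
    "alpha": "Time unstructured (independent time)",
    "delta": "Space-time interaction (independent)",
}


def variance_decomposition(samples: PosteriorSamples) -> pd.DataFrame:
    """Share of surface variation attributed to each random-effect component.

    For each component the empirical variance of its posterior-median
    elements is computed (over regions for the spatial terms, years for
    the temporal terms, all cells for the interaction); shares are
    percentages of the total.  Empirical variance of the identified,
    constrained effects is used rather than the prior variance parameters,
    because the intrinsic (ICAR/RW) variances are defined only
    conditionally.
    """
    med = {
        "theta": np.median(samples.theta, axis=0),
        "phi": np.median(samples.phi, axis=0),
        "gamma": np.median(samples.gamma, axis=0),
        "alpha": np.median(samples.alpha, axis=0),
        "delta": np.median(samples.delta, axis=0).ravel(),
    }
    var = {k: float(np.var(v, ddof=1)) for k, v in med.items()}
    total = sum(var.values())
    if total <= 0:
        raise ValueError("all components degenerate; nothing to decompose")
    rows = [
        {
            "component": k,
            "interpretation": _COMPONENT_LABELS[k],
            "variance": var[k],
            "percentage": 100.0 * var[k] / total,
        }
        for k in ("theta", "phi", "gamma", "alpha", "delta")
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssessmentReport:
    """Side-by-side DIC/LCPO comparison of two candidate fits."""

    criteria: pd.DataFrame  # one row per model: label, dic, p_d, mean_deviance, lcpo
    variance_table: pd.DataFrame  # decomposition of the selected model
    selected_model: str
    rule: str
    criteria_disagree: bool
    tie: bool

    def to_json_dict(self) -> dict:
        return {
            "criteria": self.criteria.to_dict(orient="records"),
            "variance_components": self.variance_table.to_dict(orient="records"),
            "selected_model": self.selected_model,
            "rule": self.rule,
            "criteria_disagree": self.criteria_disagree,
            "tie": self.tie,
        }


def compare_models(
    fit_a: PosteriorSamples,
    fit_b: PosteriorSamples,
    cells: ObservedCells,
    labels: tuple[str, str] = ("RW1", "RW2"),
) -> AssessmentReport:
    """Compare two fits of the same cells; select the one with lower DIC.

    Reports both DIC and LCPO for both models and flags when the two
    criteria disagree about the ordering.  Identical criteria are a tie
    and the first model is retained.
    """
    if tuple(fit_a.regions) != tuple(fit_b.regions) or not np.array_equal(
        fit_a.years, fit_b.years
    ):
        raise ValueError("fits must be on identical cells")

    rows = []
    for lab, fit in zip(labels, (fit_a, fit_b)):
        d = dic(fit, cells)
        _, lcpo = cpo_lcpo(fit, cells)
        rows.append(
            {
                "model": lab,
                "dic": d.dic,
                "p_d": d.p_d,
                "mean_deviance": d.mean_deviance,
                "lcpo": lcpo,
            }
        )
    crit = pd.DataFrame(rows)
    tie = bool(np.isclose(crit.dic[0], crit.dic[1], rtol=0, atol=1e-12))
    selected = labels[0] if tie or crit.dic[0] < crit.dic[1] else labels[1]
    dic_order = bool(crit.dic[0] < crit.dic[1])
    lcpo_order = bool(crit.lcpo[0] > crit.lcpo[1])
    disagree = bool((not tie) and (dic_order != lcpo_order))
    var_tab = variance_decomposition(fit_a if selected == labels[0] else fit_b)
    return AssessmentReport(
        criteria=crit,
        variance_table=var_tab,
        selected_model=selected,
        rule="lower DIC (ties keep the first model); LCPO reported alongside",
        criteria_disagree=disagree,
        tie=tie,
    )
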