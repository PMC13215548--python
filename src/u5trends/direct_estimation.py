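"""Design-weighted direct estimation of U5MR from full birth histories.

The estimator is the standard synthetic-cohort life table on discrete
age-band hazards: within each region x calendar-year cell, each child
contributes weighted person-months at risk to the age bands it traverses
while alive and under observation, and a weighted death event to the band
and year containing its death month.  The band monthly hazard is the
ratio of weighted deaths to weighted person-months, and

    q5 = 1 - prod_a (1 - h_a)^{n_a},   n_a = (1, 11, 12, 12, 12, 12),

expressed per 1000 live births.  Uncertainty is design-based: a
delete-one-cluster jackknife on the logit of q5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_data import AGE_BAND_STARTS, AGE_BAND_WIDTHS, q5_from_hazards

__all__ = [
    "EstimationConfig",
    "band_exposure",
    "hazard_table",
    "u5mr_from_hazards",
    "logit_with_delta_variance",
    "jackknife_variance",
    "estimate_all",
    "pooled_estimate",
]

N_BANDS = 6


@dataclass(frozen=True)
class EstimationConfig:
    """Tuning knobs of the direct estimator.

    variance_floor
        lower bound for the jackknife variance of the logit estimate;
        cells where all clusters agree would otherwise report zero
        sampling variance, which the downstream smoother cannot accept.
    zero_correction
        if True, a cell with no observed deaths receives half the minimum
        positive weighted death mass seen anywhere in the dataset (spread
        over bands proportionally to exposure) so the logit stays finite;
        if False, such cells raise.
    """

    variance_floor: float = 1e-6
    zero_correction: bool = True


def _band_of_age(age: np.ndarray) -> np.ndarray:
    return np.searchsorted(AGE_BAND_STARTS, age, side="right") - 1


def _tabulate(records: pd.DataFrame, n_years: int, by: str = "region"):
    """Weighted deaths and person-month exposure per (group, cluster, year, band).

    Returns (group_labels, cluster_labels, cluster_group_codes, D, E) where
    D and E have shape (n_clusters, n_years, 6).  Months are 0-based from
    January of the first study year; ``year`` indices follow suit.
    """
    if len(records) == 0:
        return [], [], np.array([], dtype=int), np.zeros((0, n_years, N_BANDS)), np.zeros(
            (0, n_years, N_BANDS)
        )
    groups, group_labels = pd.factorize(records[by])
    clusters, cluster_labels = pd.factorize(records["cluster_id"])
    # every cluster must belong to exactly one group
    cg = np.full(len(cluster_labels), -1, dtype=int)
    cg[clusters] = groups
    w = records["weight"].to_numpy(dtype=float)
    birth = records["birth_month"].to_numpy(dtype=int)
    interview = records["interview_month"].to_numpy(dtype=int)
    death = records["death_age_months"].to_numpy(dtype=float)

    n = len(records)
    ages = np.arange(60)
    bands = _band_of_age(ages)
    cal = birth[:, None] + ages[None, :]
    end_obs = interview - birth  # last observable age in months
    at_risk = ages[None, :] <= np.minimum(
        np.where(np.isnan(death), np.inf, death), end_obs
    )[:, None]
    at_risk &= cal < 12 * n_years  # ignore months past the study window

    yidx = np.clip(cal // 12, 0, n_years - 1)
    flat = (clusters[:, None] * n_years + yidx) * N_BANDS + bands[None, :]
    E = np.zeros(len(cluster_labels) * n_years * N_BANDS)
    np.add.at(E, flat[at_risk], np.broadcast_to(w[:, None], (n, 60))[at_risk])
    E = E.reshape(len(cluster_labels), n_years, N_BANDS)

    D = np.zeros_like(E)
    dead = ~np.isnan(death)
    if dead.any():
        da = death[dead].astype(int)
        dy = np.clip((birth[dead] + da) // 12, 0, n_years - 1)
        np.add.at(D, (clusters[dead], dy, _band_of_age(da)), w[dead])
    return list(group_labels), list(cluster_labels), cg, D, E


def _cell_hazards(d: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Band hazards d/e with empty bands flagged as NaN (missing, not zero)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(e > 0, d / np.maximum(e, 1e-300), np.nan)
    return np.clip(h, 0.0, 1.0)


def band_exposure(
    records: pd.DataFrame, region: str, year: int, year_start: int, by: str = "region"
) -> pd.DataFrame:
    """Weighted deaths, exposure and hazard per age band for one region-year cell."""
    n_years = max(records["interview_month"].max() // 12 + 1, year - year_start + 1)
    labels, _, cg, D, E = _tabulate(records, int(n_years), by=by)
    if region not in labels:
        raise ValueError(f"no records for region {region!r}")
    g = labels.index(region)
    t = year - year_start
    d = D[cg == g, t].sum(axis=0)
    e = E[cg == g, t].sum(axis=0)
    return pd.DataFrame(
        {
            "region": region,
            "year": year,
            "age_band": np.arange(N_BANDS),
            "weighted_deaths": d,
            "weighted_exposure_months": e,
            "hazard": _cell_hazards(d, e),
        }
    )


def hazard_table(records: pd.DataFrame, year_start: int, n_years: int, by="region"):
    """All (group, year, band) hazards as a tidy DataFrame."""
    labels, _, cg, D, E = _tabulate(records, n_years, by=by)
    frames = []
    for g, lab in enumerate(labels):
        d = D[cg == g].sum(axis=0)
        e = E[cg == g].sum(axis=0)
        h = _cell_hazards(d, e)
        idx = pd.MultiIndex.from_product(
            [[lab], year_start + np.arange(n_years), range(N_BANDS)],
            names=["region", "year", "age_band"],
        )
        frames.append(
            pd.DataFrame(
                {
                    "weighted_deaths": d.ravel(),
                    "weighted_exposure_months": e.ravel(),
                    "hazard": h.ravel(),
                },
                index=idx,
            )
        )
    return pd.concat(frames).reset_index()


def u5mr_from_hazards(band_hazards) -> float:
    """U5MR per 1000 implied by six monthly band hazards."""
    return 1000.0 * q5_from_hazards(band_hazards)


def logit_with_delta_variance(
    q5_prob: float, var_q5: float, config: EstimationConfig | None = None
) -> tuple[float, float]:
    """Logit transform of q5 with delta-method variance var / (p(1-p))^2."""
    if not 0 < q5_prob < 1:
        raise ValueError(
            "q5 of 0 or 1 has no finite logit; enable the zero-death correction "
            "or pool periods/regions"
        )
    if var_q5 < 0:
        raise ValueError("variance must be nonnegative")
    p = q5_prob
    return float(np.log(p / (1 - p))), float(var_q5 / (p * (1 - p)) ** 2)


def _zero_correction_mass(D: np.ndarray, records: pd.DataFrame) -> float:
    """Half the smallest positive weighted death mass (fallback: half min weight)."""
    pos = D[D > 0]
    if pos.size:
        return 0.5 * float(pos.min())
    return 0.5 * float(records["weight"].min())


def _corrected_q5(d: np.ndarray, e: np.ndarray, mass: float, config) -> float:
    """q5 (0-1) for one cell, applying the zero-death continuity correction."""
    if np.any(e <= 0):
        return np.nan
    if d.sum() == 0:
        if not config.zero_correction:
            raise ValueError("cell has no deaths and zero-correction is disabled")
        # spread the correction mass over bands proportionally to exposure:
        # a uniform monthly-hazard bump, invariant to rescaling all weights
        d = d + mass * e / e.sum()
    h = np.clip(d / e, 0.0, 1.0)
    return q5_from_hazards(h)


def _jackknife_logit_variance(Dc, Ec, mass, config):
    """Delete-one-cluster jackknife variance of logit q5 for one cell.

    Dc, Ec: (n_clusters, 6) weighted deaths / exposure of the clusters
    contributing to the cell.  Returns (variance, n_contributing).
    """
    contrib = Ec.sum(axis=1) > 0
    Dc, Ec = Dc[contrib], Ec[contrib]
    G = Dc.shape[0]
    if G < 2:
        raise ValueError(
            "jackknife needs >= 2 contributing clusters; pool periods or regions"
        )
    d_tot, e_tot = Dc.sum(axis=0), Ec.sum(axis=0)
    loo = []
    for g in range(G):
        d, e = d_tot - Dc[g], e_tot - Ec[g]
        if np.any(e <= 0):
            continue  # removing this cluster empties a band
        q = _corrected_q5(d, e, mass, config)
        loo.append(np.log(q / (1 - q)))
    loo = np.asarray(loo)
    m = len(loo)
    if m < 2:
        return config.variance_floor, G
    var = (m - 1) / m * np.sum((loo - loo.mean()) ** 2)
    return max(float(var), config.variance_floor), G


def jackknife_variance(
    records: pd.DataFrame,
    region: str,
    year: int,
    year_start: int,
    config: EstimationConfig | None = None,
    by: str = "region",
) -> float:
    """Delete-one-cluster jackknife variance of the logit-scale estimate."""
    config = config or EstimationConfig()
    n_years = max(records["interview_month"].max() // 12 + 1, year - year_start + 1)
    labels, _, cg, D, E = _tabulate(records, int(n_years), by=by)
    g = labels.index(region)
    t = year - year_start
    mass = _zero_correction_mass(D, records)
    var, _ = _jackknife_logit_variance(D[cg == g, t], E[cg == g, t], mass, config)
    return var


def estimate_all(
    records: pd.DataFrame,
    years,
    regions=None,
    by: str = "region",
    config: EstimationConfig | None = None,
) -> pd.DataFrame:
    """Direct region x year U5MR estimates with design-based logit variances.

    ``years`` is the full study window (calendar years); month indices in
    ``records`` are 0-based from January of ``years[0]``.  Cells that
    cannot be estimated (empty band exposure, or a single contributing
    cluster) appear with NaN values and are listed in
    ``result.attrs["missing_cells"]``.  Regions requested but absent from
    the records are listed in ``result.attrs["regions_without_data"]``.
    """
    config = config or EstimationConfig()
    years = list(years)
    n_years = len(years)
    labels, _, cg, D, E = _tabulate(records, n_years, by=by)
    if regions is None:
        regions = labels
    rows, missing, absent = [], [], []
    mass = _zero_correction_mass(D, records) if len(records) else 0.0
    for r in regions:
        if r not in labels:
            absent.append(r)
            rows.extend(
                dict(region=r, year=y, u5mr_per_1000=np.nan, logit_mean=np.nan,
                     logit_variance=np.nan, n_clusters_contributing=0)
                for y in years
            )
            continue
        g = labels.index(r)
        Dg, Eg = D[cg == g], E[cg == g]
        d_tot, e_tot = Dg.sum(axis=0), Eg.sum(axis=0)
        for t, y in enumerate(years):
            try:
                q = _corrected_q5(d_tot[t], e_tot[t], mass, config)
                if np.isnan(q):
                    raise ValueError("empty band exposure")
                lm = float(np.log(q / (1 - q)))
                var, ncl = _jackknife_logit_variance(Dg[:, t], Eg[:, t], mass, config)
            except ValueError as exc:
                missing.append((r, y, str(exc)))
                rows.append(
                    dict(region=r, year=y, u5mr_per_1000=np.nan, logit_mean=np.nan,
                         logit_variance=np.nan, n_clusters_contributing=0)
                )
                continue
            rows.append(
                dict(
                    region=r,
                    year=y,
                    u5mr_per_1000=1000.0 * float(expit(lm)),
                    logit_mean=lm,
                    logit_variance=var,
                    n_clusters_contributing=ncl,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "region", "year", "u5mr_per_1000", "logit_mean",
            "logit_variance", "n_clusters_contributing",
        ],
    )
    out.attrs["missing_cells"] = missing
    out.attrs["regions_without_data"] = absent
    return out


def pooled_estimate(
    records: pd.DataFrame, config: EstimationConfig | None = None
) -> dict:
    """Single U5MR estimate pooling all regions and calendar years.

    Useful for validation against an analytic target and as the fallback
    the jackknife error message points to when cells are too sparse.
    """
    config = config or EstimationConfig()
    n_years = int(records["interview_month"].max() // 12 + 1)
    pooled = records.assign(_all="all")
    _, _, _, D, E = _tabulate(pooled, n_years, by="_all")
    Dc, Ec = D.sum(axis=1), E.sum(axis=1)  # collapse years: (clusters, bands)
    mass = _zero_correction_mass(D, records)
    q = _corrected_q5(Dc.sum(axis=0), Ec.sum(axis=0), mass, config)
    lm = float(np.log(q / (1 - q)))
    var, ncl = _jackknife_logit_variance(Dc, Ec, mass, config)
    return {
        "u5mr_per_1000": 1000.0 * q,
        "logit_mean": lm,
        "logit_variance": var,
        "n_clusters": ncl,
    }
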