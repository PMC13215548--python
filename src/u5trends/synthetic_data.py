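"""Synthetic mortality surfaces and DHS-style survey birth histories.

This module generates ground truth and survey data with the statistical
structure the downstream estimators assume: a logit-scale space-time
surface built from ICAR spatial, random-walk temporal, iid and interaction
components; and a two-stage stratified cluster sample of full birth
histories (one row per child) whose deaths are driven by that surface
through age-band hazards.

Months are integer indices counted from January of the first study year
(CMC-style, 0-based).  Age bands follow the standard DHS convention:
0, 1-11, 12-23, 24-35, 36-47 and 48-59 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "AGE_BAND_WIDTHS",
    "AGE_BAND_STARTS",
    "DEFAULT_HAZARD_SHAPE",
    "AdjacencyGraph",
    "TruthSpec",
    "TruthSurface",
    "SurveyDesign",
    "load_adjacency",
    "default_adjacency",
    "sample_icar",
    "sample_rw",
    "simulate_truth",
    "hazards_from_q5",
    "simulate_birth_histories",
    "BIRTH_HISTORY_COLUMNS",
]

#: widths (months) of the six age bands used throughout the package
AGE_BAND_WIDTHS = np.array([1, 11, 12, 12, 12, 12], dtype=int)
#: first month of age of each band
AGE_BAND_STARTS = np.array([0, 1, 12, 24, 36, 48], dtype=int)

#: relative monthly hazards across the six bands.  The first month of life
#: carries by far the highest risk; risk declines through infancy and
#: childhood.  With these multipliers roughly 43% of under-five deaths are
#: neonatal, 31% post-neonatal infant and 26% at ages 1-4, a typical
#: split for high-mortality settings.
DEFAULT_HAZARD_SHAPE = np.array([60.0, 4.0, 1.2, 0.8, 0.6, 0.5])

BIRTH_HISTORY_COLUMNS = [
    "child_id",
    "cluster_id",
    "stratum_id",
    "region",
    "weight",
    "birth_month",
    "death_age_months",
    "interview_month",
]

_COMPONENTS = ("alpha", "gamma", "theta", "phi", "delta")


def _band_of_age(age_months: np.ndarray) -> np.ndarray:
    """Age band index (0-5) for each age in months (0-59)."""
    return np.searchsorted(AGE_BAND_STARTS, age_months, side="right") - 1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected region neighbourhood graph.

    Edges are stored as unordered pairs of region labels, so the relation
    is symmetric by construction; self-loops and unknown labels are
    rejected at validation time.
    """

    region_names: tuple[str, ...]
    edges: frozenset[frozenset]

    def __post_init__(self):
        names = self.region_names
        if len(names) < 2:
            raise ValueError(
                "adjacency graph needs at least 2 regions (ICAR undefined otherwise)"
            )
        if len(set(names)) != len(names):
            raise ValueError("duplicate region labels")
        known = set(names)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {sorted(e)}")
            for lab in pair:
                if lab not in known:
                    raise ValueError(f"edge references unknown region {lab!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def neighbors(self, label: str) -> set[str]:
        return {
            other
            for e in self.edges
            for other in e
            if label in e and other != label
        }

    def index(self, label: str) -> int:
        return self.region_names.index(label)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_names)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix W in region_names order."""
        n = self.n_regions
        idx = {r: i for i, r in enumerate(self.region_names)}
        w = np.zeros((n, n))
        for e in self.edges:
            a, b = tuple(e)
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
        return w


def _edges_from_config(cfg: dict, regions: Sequence[str]) -> frozenset:
    """Accept either a list of pairs or a neighbours mapping (checked for symmetry)."""
    raw = cfg["edges"]
    pairs: set[frozenset] = set()
    if isinstance(raw, Mapping):
        for a, neighbours in raw.items():
            for b in neighbours:
                pairs.add(frozenset((a, b)))
        # a mapping must be symmetric: b must list a whenever a lists b
        for a, neighbours in raw.items():
            for b in neighbours:
                if a not in raw.get(b, []):
                    raise ValueError(
                        f"asymmetric edge list: {a!r} lists {b!r} but not vice versa"
                    )
    else:
        for item in raw:
            a, b = item
            pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def load_adjacency(config_path) -> AdjacencyGraph:
    """Load and validate a region adjacency graph from a YAML config.

    The config has a ``regions`` list and an ``edges`` entry, either a
    list of ``[a, b]`` pairs or a mapping ``region -> [neighbours]``
    (which must be symmetric).
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    regions = tuple(cfg["regions"])
    edges = _edges_from_config(cfg, regions)
    return AdjacencyGraph(region_names=regions, edges=edges)


def default_adjacency() -> AdjacencyGraph:
    """The bundled 8-division Bangladesh fixture (editable YAML in package data)."""
    return load_adjacency(Path(__file__).parent / "data" / "bangladesh_divisions.yaml")


# ---------------------------------------------------------------------------
# latent component samplers
# ---------------------------------------------------------------------------


def icar_structure(graph: AdjacencyGraph) -> np.ndarray:
    """ICAR structure matrix Q = D - W (degree minus adjacency)."""
    w = graph.adjacency_matrix()
    return np.diag(w.sum(axis=1)) - w


def sample_icar(graph: AdjacencyGraph, precision: float, seed) -> np.ndarray:
    """Draw from the intrinsic CAR prior with structure Q = D - W.

    The draw lives in the space orthogonal to the constant vector (the
    null space of Q for a connected graph), i.e. it sums to zero, and has
    covariance pinv(Q)/precision there.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    if not graph.is_connected:
        raise ValueError("ICAR sampling requires a connected graph")
    rng = _as_rng(seed)
    q = icar_structure(graph)
    lam, vec = np.linalg.eigh(q)
    # connected graph: exactly one (numerically) zero eigenvalue
    keep = lam > 1e-10 * lam.max()
    z = rng.standard_normal(keep.sum())
    x = vec[:, keep] @ (z / np.sqrt(precision * lam[keep]))
    return x - x.mean()  # exact sum-to-zero despite rounding


def _rw_projection(T: int, order: int) -> np.ndarray:
    """Projector removing the RW null space (constant; plus linear for order 2)."""
    cols = [np.ones(T)]
    if order == 2:
        t = np.arange(T, dtype=float)
        cols.append(t - t.mean())
    x = np.column_stack(cols)
    return np.eye(T) - x @ np.linalg.solve(x.T @ x, x.T)


def sample_rw(T: int, order: int, precision: float, seed) -> np.ndarray:
    """Draw a random-walk path of the given order and innovation precision.

    Innovations are iid Normal(0, 1/precision); the cumulative (order-fold)
    sum is then projected to sum to zero (order 1) and additionally to be
    orthogonal to a linear trend (order 2), so the draw is identifiable
    against a grand mean and a global slope.  The projection leaves the
    order-th differences untouched.
    """
    if order not in (1, 2):
        raise ValueError("random-walk order must be 1 or 2")
    if T < order + 1:
        raise ValueError(f"need T >= {order + 1} for a RW{order}")
    if precision <= 0:
        raise ValueError("precision must be positive")
    rng = _as_rng(seed)
    innov = rng.standard_normal(T - order) / np.sqrt(precision)
    x = np.zeros(T)
    if order == 1:
        x[1:] = np.cumsum(innov)
    else:
        for t in range(2, T):
            x[t] = 2 * x[t - 1] - x[t - 2] + innov[t - 2]
    return _rw_projection(T, order) @ x


# ---------------------------------------------------------------------------
# truth surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthSpec:
    """Generating parameters of the logit-scale space-time surface.

    ``variances`` holds the marginal/innovation variances of the five
    components: ``alpha`` (iid time), ``gamma`` (structured time, RW of
    ``temporal_order``), ``theta`` (iid space), ``phi`` (ICAR space) and
    ``delta`` (iid space-time interaction).
    """

    mu: float
    variances: Mapping[str, float]
    graph: AdjacencyGraph
    year_start: int = 1990
    year_end: int = 2022
    temporal_order: int = 2
    seed: int = 0

    def __post_init__(self):
        missing = set(_COMPONENTS) - set(self.variances)
        if missing:
            raise ValueError(f"variances missing components: {sorted(missing)}")
        for k, v in self.variances.items():
            if v < 0:
                raise ValueError(f"variance for {k!r} must be >= 0")
        if self.temporal_order not in (1, 2):
            raise ValueError("temporal_order must be 1 or 2")
        if self.n_years < self.temporal_order + 1:
            raise ValueError("too few years for the requested random-walk order")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass(frozen=True)
class TruthSurface:
    """Ground-truth surface: eta (logit scale) and its generating components."""

    regions: tuple[str, ...]
    years: np.ndarray
    eta: np.ndarray  # (n_regions, n_years)
    components: dict = field(repr=False)
    mu: float = 0.0

    @property
    def q5(self) -> np.ndarray:
        """True five-year death probability per 1000 live births."""
        return 1000.0 * expit(self.eta)

    def to_frame(self) -> pd.DataFrame:
        n, T = self.eta.shape
        return pd.DataFrame(
            {
                "region": np.repeat(self.regions, T),
                "year": np.tile(self.years, n),
                "eta": self.eta.ravel(),
                "q5_per_1000": self.q5.ravel(),
            }
        )


def simulate_truth(spec: TruthSpec) -> TruthSurface:
    """Draw a truth surface eta[i,t] = mu + alpha_t + gamma_t + theta_i + phi_i + delta_it.

    Components with zero variance are identically zero, so a TruthSpec with
    all variances zero yields the constant surface eta = mu.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.graph.n_regions, spec.n_years
    v = spec.variances

    alpha = (
        rng.standard_normal(T) * np.sqrt(v["alpha"]) if v["alpha"] > 0 else np.zeros(T)
    )
    theta = (
        rng.standard_normal(n) * np.sqrt(v["theta"]) if v["theta"] > 0 else np.zeros(n)
    )
    gamma = (
        sample_rw(T, spec.temporal_order, 1.0 / v["gamma"], rng)
        if v["gamma"] > 0
        else np.zeros(T)
    )
    phi = (
        sample_icar(spec.graph, 1.0 / v["phi"], rng) if v["phi"] > 0 else np.zeros(n)
    )
    delta = (
        rng.standard_normal((n, T)) * np.sqrt(v["delta"])
        if v["delta"] > 0
        else np.zeros((n, T))
    )

    eta = spec.mu + alpha[None, :] + gamma[None, :] + theta[:, None] + phi[:, None] + delta
    components = {
        "alpha": alpha,
        "gamma": gamma,
        "theta": theta,
        "phi": phi,
        "delta": delta,
    }
    return TruthSurface(
        regions=spec.graph.region_names,
        years=spec.years,
        eta=eta,
        components=components,
        mu=spec.mu,
    )


# ---------------------------------------------------------------------------
# hazards
# ---------------------------------------------------------------------------


def hazards_from_q5(q5_prob: float, shape: np.ndarray | None = None) -> np.ndarray:
    """Monthly age-band hazards h = c * shape reproducing a target q5.

    Solves for the scalar c such that 1 - prod_a (1 - c*shape_a)^{n_a}
    equals ``q5_prob``, with n_a the band widths in months.
    """
    if shape is None:
        shape = DEFAULT_HAZARD_SHAPE
    shape = np.asarray(shape, dtype=float)
    if shape.shape != (6,) or np.any(shape <= 0):
        raise ValueError("shape must be six positive relative hazards")
    if not 0 <= q5_prob < 1:
        raise ValueError("q5_prob must lie in [0, 1)")
    if q5_prob == 0:
        return np.zeros(6)

    c_max = (1.0 - 1e-12) / shape.max()

    def gap(c):
        return 1.0 - np.prod((1.0 - c * shape) ** AGE_BAND_WIDTHS) - q5_prob

    c = brentq(gap, 0.0, c_max, xtol=1e-15, rtol=1e-14)
    return np.clip(c * shape, 0.0, 1.0 - 1e-15)


def q5_from_hazards(hazards: np.ndarray) -> float:
    """Five-year death probability (0-1 scale) implied by six band hazards."""
    h = np.asarray(hazards, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hazards must lie in [0, 1]")
    return float(1.0 - np.prod((1.0 - h) ** AGE_BAND_WIDTHS))


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDesign:
    """Two-stage stratified cluster design: region x urban/rural strata.

    Within each stratum a fixed number of clusters is drawn, each with a
    fixed number of interviewed women; births per woman are Poisson.
    Sampling weights are the inverse stratum sampling fractions,
    normalised to mean 1 over the realised sample.  Defaults emulate a
    national DHS-scale survey: 16 strata x 42 clusters x 45 women at 2.13
    births per woman gives roughly 64,000 child records.
    """

    clusters_per_stratum: int = 42
    women_per_cluster: int = 45
    births_per_woman_mean: float = 2.13
    interview_month: int | None = None  # default: December of the last study year
    weight_scheme: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 0.010, "rural": 0.004}
    )

    def __post_init__(self):
        if self.clusters_per_stratum <= 0 or self.women_per_cluster <= 0:
            raise ValueError("cluster and woman counts must be positive")
        if self.births_per_woman_mean <= 0:
            raise ValueError("births_per_woman_mean must be positive")
        for k, f in self.weight_scheme.items():
            if f <= 0:
                raise ValueError(f"sampling fraction for {k!r} must be positive")


def simulate_birth_histories(
    surface: TruthSurface,
    design: SurveyDesign,
    seed,
    hazard_shape: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate a full-birth-history survey table driven by a truth surface.

    Each child is placed uniformly over the calendar months of the study
    window and followed month by month to age 59; in each month of age it
    experiences the hazard of the age band it currently occupies and the
    calendar year it currently occupies (period hazards).  Follow-up stops
    at the interview month, so deaths that would occur afterwards are
    unobserved and the child appears alive (right censoring).

    Returns a DataFrame with exactly the columns of
    ``BIRTH_HISTORY_COLUMNS``; ``death_age_months`` is NaN for children
    alive or censored.
    """
    rng = _as_rng(seed)
    regions = surface.regions
    n_regions, n_years = surface.eta.shape
    last_month = 12 * n_years - 1
    interview = (
        design.interview_month if design.interview_month is not None else last_month
    )
    if interview < 0:
        raise ValueError("interview_month before study start")
    if interview > last_month:
        raise ValueError("interview_month beyond the truth surface's last year")

    # per region x year band hazards implied by the surface
    q5 = surface.q5 / 1000.0
    hmat = np.empty((n_regions, n_years, 6))
    for i in range(n_regions):
        for t in range(n_years):
            hmat[i, t] = hazards_from_q5(q5[i, t], hazard_shape)

    strata = list(design.weight_scheme)  # e.g. ["urban", "rural"]
    rows_region, rows_stratum, rows_cluster = [], [], []
    for r in regions:
        for s in strata:
            for c in range(design.clusters_per_stratum):
                n_births = rng.poisson(
                    design.births_per_woman_mean, size=design.women_per_cluster
                ).sum()
                rows_region.append((r, s, f"{r}_{s}_{c:03d}", n_births))
    region_arr, stratum_arr, cluster_arr = [], [], []
    for r, s, cid, nb in rows_region:
        region_arr.extend([r] * nb)
        stratum_arr.extend([f"{r}_{s}"] * nb)
        cluster_arr.extend([cid] * nb)
    n_children = len(region_arr)

    region_idx = np.array([regions.index(r) for r in region_arr])
    birth = rng.integers(0, interview + 1, size=n_children)

    # month-by-month survival, vectorised over children x 60 months of age
    ages = np.arange(60)
    bands = _band_of_age(ages)
    cal_month = birth[:, None] + ages[None, :]
    observed = cal_month <= interview
    year_idx = np.minimum(cal_month // 12, n_years - 1)
    haz = hmat[region_idx[:, None], year_idx, bands[None, :]]
    haz = np.where(observed, haz, 0.0)  # cannot observe a death past interview
    u = rng.random((n_children, 60))
    died = u < haz
    death_age = np.where(died.any(axis=1), died.argmax(axis=1), -1)

    # weights: inverse stratum sampling fraction, normalised to mean 1
    frac = np.array([design.weight_scheme[s.rsplit("_", 1)[1]] for s in stratum_arr])
    weight = 1.0 / frac
    weight = weight / weight.mean()

    df = pd.DataFrame(
        {
            "child_id": [f"c{k:07d}" for k in range(n_children)],
            "cluster_id": cluster_arr,
            "stratum_id": stratum_arr,
            "region": region_arr,
            "weight": weight,
            "birth_month": birth,
            "death_age_months": np.where(death_age >= 0, death_age, np.nan),
            "interview_month": interview,
        }
    )
    return df[BIRTH_HISTORY_COLUMNS]


def default_truth_spec(seed: int = 0, graph: AdjacencyGraph | None = None) -> TruthSpec:
    """Study-condition defaults for the synthetic truth surface.

    The grand mean logit(0.06) puts the typical five-year death
    probability near 60 per 1000 — the right order of magnitude for a
    1990-2022 high-mortality-transition setting.  The component variances
    make structured space the dominant source of between-cell variation,
    with modest iid space, a smooth structured time trend (small RW2
    innovation variance integrates to visible swings), and small iid time
    and interaction terms.
    """
    if graph is None:
        graph = default_adjacency()
    return TruthSpec(
        mu=float(logit(0.06)),
        variances={
            "phi": 0.15,
            "theta": 0.02,
            "gamma": 1e-4,
            "alpha": 0.005,
            "delta": 0.005,
        },
        graph=graph,
        year_start=1990,
        year_end=2022,
        temporal_order=2,
        seed=seed,
    )
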