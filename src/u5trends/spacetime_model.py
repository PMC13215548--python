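"""Bayesian hierarchical space-time smoothing of logit-scale U5MR estimates.

The observation model treats each direct estimate as a Gaussian
pseudo-likelihood with known design-based variance:

    y_it ~ Normal(eta_it, v_it),
    eta_it = mu + alpha_t + gamma_t + theta_i + phi_i + delta_it,

with alpha iid time, gamma a random walk of order 1 or 2 (structured
time), theta iid space, phi ICAR (structured space) and delta iid
space-time interaction.  Every precision gets a Gamma(a, b) prior
(shape/RATE parametrisation).  All full conditionals are conjugate —
Gaussian for mu and each effect block, Gamma for the precisions — and the
model is fitted by Gibbs sampling.  Identifiability is enforced exactly:
alpha, theta and phi are constrained to sum to zero, gamma to sum to zero
(and, for order 2, to be orthogonal to a linear trend), and delta is
double-centred by rows and columns.

Because the structured and unstructured terms of each domain (theta/phi in
space, alpha/gamma in time) enter the likelihood only through their sum,
single-block updates of their precisions mix catastrophically badly: the
chain gets trapped with one term holding the whole pattern.  The default
sampler therefore updates these four precisions by slice sampling from
their marginal posteriors with the paired effect blocks integrated out
(a partially collapsed Gibbs step), and then redraws each pair jointly as
one constrained Gaussian block.  The plain conjugate scheme remains
available (``ModelSpec.precision_sampler = "conjugate"``) and is used to
validate the full conditionals against closed forms on reduced models.

Forecasts extend only the structured temporal term through the random-walk
recursion; the iid terms carry no autoregressive structure and are not
projected forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_data import AdjacencyGraph, icar_structure

__all__ = [
    "ModelSpec",
    "ObservedCells",
    "PosteriorSamples",
    "ForecastResult",
    "build_icar_precision",
    "build_rw_precision",
    "cells_from_estimates",
    "gibbs_fit",
    "posterior_summaries",
    "forecast",
    "effective_sample_size",
]

_EFFECTS = ("alpha", "gamma", "theta", "phi", "delta")


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and prior settings.

    ``hyper_a``/``hyper_b`` are the shape and RATE of the Gamma priors on
    all five precisions (mean a/b = 500 at the defaults — a diffuse prior
    letting the data govern the degree of smoothing).  ``temporal_order``
    selects the structured-time prior: 1 for a first-order random walk,
    2 for a second-order one.
    """

    temporal_order: int = 2
    hyper_a: float = 0.5
    hyper_b: float = 0.001
    n_iter: int = 20_000
    n_burn: int = 5_000
    thin: int = 5
    seed: int = 0
    mu_prior_variance: float = 1e6
    precision_sampler: str = "collapsed"

    def __post_init__(self):
        if self.temporal_order not in (1, 2):
            raise ValueError("temporal_order must be 1 or 2")
        if self.precision_sampler not in ("collapsed", "conjugate"):
            raise ValueError("precision_sampler must be 'collapsed' or 'conjugate'")
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("hyperprior parameters must be positive")


def build_icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """ICAR structure matrix Q = D - W; symmetric, zero row sums, rank n-1."""
    if not graph.is_connected:
        raise ValueError("ICAR requires a connected adjacency graph")
    return icar_structure(graph)


def build_rw_precision(T: int, order: int) -> np.ndarray:
    """Random-walk structure matrix R = D'D for the order-th difference operator."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if T < order + 1:
        raise ValueError(f"need T >= {order + 1}")
    d = np.diff(np.eye(T), n=order, axis=0)
    return d.T @ d


@dataclass(frozen=True)
class ObservedCells:
    """Logit-scale observations on the region x year grid (NaN = missing)."""

    regions: tuple[str, ...]
    years: np.ndarray
    y: np.ndarray  # (n, T), NaN where unobserved
    v: np.ndarray  # (n, T), known variances, NaN where unobserved

    def __post_init__(self):
        obs = ~np.isnan(self.y)
        if np.any(self.v[obs] <= 0):
            raise ValueError("observed cells must have positive variance")

    @property
    def weight(self) -> np.ndarray:
        """Observation precision 1/v, zero where missing."""
        w = np.zeros_like(self.y)
        obs = ~np.isnan(self.y)
        w[obs] = 1.0 / self.v[obs]
        return w


def cells_from_estimates(
    estimates: pd.DataFrame, regions, years
) -> ObservedCells:
    """Arrange a direct-estimates table onto the (region, year) grid.

    Rows with NaN logit mean/variance become missing cells.  Estimates
    referencing a region or year outside the grid raise.
    """
    regions = tuple(regions)
    years = np.asarray(list(years))
    n, T = len(regions), len(years)
    y = np.full((n, T), np.nan)
    v = np.full((n, T), np.nan)
    ridx = {r: i for i, r in enumerate(regions)}
    tidx = {int(t): j for j, t in enumerate(years)}
    for row in estimates.itertuples():
        if row.region not in ridx:
            raise ValueError(f"estimate references unknown region {row.region!r}")
        if int(row.year) not in tidx:
            raise ValueError(f"estimate references year {row.year} outside the grid")
        if np.isnan(row.logit_mean) or np.isnan(row.logit_variance):
            continue
        y[ridx[row.region], tidx[int(row.year)]] = row.logit_mean
        v[ridx[row.region], tidx[int(row.year)]] = row.logit_variance
    return ObservedCells(regions=regions, years=years, y=y, v=v)


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws of all effects and precisions."""

    regions: tuple[str, ...]
    years: np.ndarray
    spec: ModelSpec
    mu: np.ndarray  # (S,)
    alpha: np.ndarray  # (S, T)
    gamma: np.ndarray  # (S, T)
    theta: np.ndarray  # (S, n)
    phi: np.ndarray  # (S, n)
    delta: np.ndarray  # (S, n, T)
    tau: dict = field(default_factory=dict)  # effect -> (S,)
    constrained: bool = True
    # structure-matrix rescaling applied to the random walk during fitting;
    # the innovation precision of gamma is tau_gamma * gamma_scale
    gamma_scale: float = 1.0

    @property
    def n_draws(self) -> int:
        return len(self.mu)

    def eta_draws(self) -> np.ndarray:
        """Linear predictor per draw: (S, n, T)."""
        return (
            self.mu[:, None, None]
            + self.alpha[:, None, :]
            + self.gamma[:, None, :]
            + self.theta[:, :, None]
            + self.phi[:, :, None]
            + self.delta
        )


def _sample_gaussian(prec: np.ndarray, b: np.ndarray, rng, constraints=None) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1), optionally conditioned on Ax = 0.

    Hard constraints are imposed exactly by conditioning-by-kriging:
    x* = x - prec^-1 A' (A prec^-1 A')^-1 A x.
    """
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, b)
    z = rng.standard_normal(len(b))
    x = mean + np.linalg.solve(L.T, z)
    if constraints is not None:
        A = constraints
        CA = np.linalg.solve(prec, A.T)
        x = x - CA @ np.linalg.solve(A @ CA, A @ x)
    return x


_LOG_TAU_LO, _LOG_TAU_HI = np.log(1e-6), np.log(1e14)


def _slice_sample(logpost, x0: float, rng, w: float = 2.0, max_steps: int = 30) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    f0 = logpost(x0)
    logy = f0 + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if lo <= _LOG_TAU_LO or logpost(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if hi >= _LOG_TAU_HI or logpost(hi) < logy:
            break
        hi += w
    lo, hi = max(lo, _LOG_TAU_LO), min(hi, _LOG_TAU_HI)
    for _ in range(100):
        x1 = lo + rng.random() * (hi - lo)
        if logpost(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _sum_zero_basis(T: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace (T x T-1)."""
    lam, vec = np.linalg.eigh(np.eye(T) - np.ones((T, T)) / T)
    return vec[:, lam > 0.5]


def _scale_structure(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale an intrinsic structure matrix to unit typical marginal variance.

    Returns (s*K, s) with s the geometric mean of the marginal variances
    diag(K^+).  After scaling, a precision tau means the same thing for
    every component — the typical effect variance is 1/tau — so one
    Gamma(a, b) prior is comparable across iid, ICAR and random-walk
    terms.  Without this, the prior systematically favours whichever
    component needs the larger precision for a given field size.
    """
    lam, vec = np.linalg.eigh(K)
    keep = lam > 1e-9 * lam.max()
    pinv_diag = ((vec[:, keep] ** 2) / lam[keep]).sum(axis=1)
    s = float(np.exp(np.mean(np.log(pinv_diag))))
    return s * K, s


class _PairCollapse:
    """Marginal posterior machinery for a (iid, structured) effect pair.

    The two effects enter the likelihood only through their sum s = x + g,
    observed via precision-weighted residual means z with known noise
    precisions omega.  In an orthonormal basis U of the identified
    subspace the marginal covariance of U'z is

        N + tau_iid^-1 I + tau_struct^-1 G,

    with N = U' diag(1/omega) U and G = U' K^+ U for structure matrix K.
    This lets the two precisions be slice-sampled with the pair integrated
    out, which is what makes the split between the confounded effects mix.
    """

    def __init__(self, K: np.ndarray, omega: np.ndarray, a: float, b: float):
        m = len(omega)
        lam, vec = np.linalg.eigh(K)
        keep = lam > 1e-9 * lam.max()
        K_pinv = (vec[:, keep] / lam[keep]) @ vec[:, keep].T
        self.U = _sum_zero_basis(m)
        omega_adj = np.maximum(omega, 1e-8)
        self.N = self.U.T @ (self.U / omega_adj[:, None])
        self.G = self.U.T @ K_pinv @ self.U
        self.I = np.eye(m - 1)
        self.omega_adj = omega_adj
        self.a, self.b = a, b

    def _nll(self, zu, inv_tau_iid, inv_tau_struct):
        M = self.N + inv_tau_iid * self.I + inv_tau_struct * self.G
        L = np.linalg.cholesky(M)
        half = np.linalg.solve(L, zu)
        return np.log(np.diag(L)).sum() + 0.5 * half @ half

    def sample_precisions(self, s, tau_iid, tau_struct, rng):
        """Slice-update both precisions given summed weighted residuals s."""
        zu = self.U.T @ (s / self.omega_adj)
        a, b = self.a, self.b

        def post_iid(u):
            return a * u - b * np.exp(u) - self._nll(zu, np.exp(-u), 1.0 / tau_struct)

        tau_iid = np.exp(_slice_sample(post_iid, np.log(tau_iid), rng))

        def post_struct(u):
            return a * u - b * np.exp(u) - self._nll(zu, 1.0 / tau_iid, np.exp(-u))

        tau_struct = np.exp(_slice_sample(post_struct, np.log(tau_struct), rng))
        return tau_iid, tau_struct


def gibbs_fit(
    cells: ObservedCells,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    include=None,
    fixed_precisions=None,
) -> PosteriorSamples:
    """Fit the space-time model by Gibbs sampling.

    ``include`` restricts the model to a subset of
    {"mu", "alpha", "gamma", "theta", "phi", "delta"} (defaults to all);
    excluded effects are pinned at zero.  ``fixed_precisions`` maps effect
    names to fixed precision values, bypassing their Gamma updates — both
    hooks exist so reduced single-block models can be checked against
    closed-form conjugate posteriors.  Identifiability projections are
    applied only when ``mu`` is in the model (they exist to separate the
    effects from the grand mean and from each other).

    Deterministic given ``spec.seed``.
    """
    if tuple(cells.regions) != tuple(graph.region_names):
        raise ValueError("cells and graph must use the same regions in the same order")
    include = set(include) if include is not None else {"mu", *_EFFECTS}
    fixed_precisions = dict(fixed_precisions or {})
    constrain = "mu" in include

    n, T = cells.y.shape
    w = cells.weight
    y0 = np.nan_to_num(cells.y)
    wy = w * y0
    a, b = spec.hyper_a, spec.hyper_b
    rng = np.random.default_rng(spec.seed)

    # structure matrices, rescaled to unit typical marginal variance so the
    # shared Gamma(a, b) prior treats all components comparably
    Q, _ = _scale_structure(build_icar_precision(graph))
    R, sR = _scale_structure(build_rw_precision(T, spec.temporal_order))
    jitter_T = 1e-10 * np.eye(T)
    jitter_n = 1e-10 * np.eye(n)

    # identifiability projections
    proj_T = np.eye(T) - 1.0 / T
    if spec.temporal_order == 2:
        t = np.arange(T, dtype=float)
        t = t - t.mean()
        proj_gamma = proj_T - np.outer(t, t) / (t @ t)
    else:
        proj_gamma = proj_T

    # effective ranks of the constrained effects (full ranks when unconstrained)
    rank = {
        "alpha": T - 1 if constrain else T,
        "gamma": T - spec.temporal_order,
        "theta": n - 1 if constrain else n,
        "phi": n - 1,
        "delta": (n - 1) * (T - 1) if constrain else n * T,
    }

    mu = 0.0
    alpha = np.zeros(T)
    gamma = np.zeros(T)
    theta = np.zeros(n)
    phi = np.zeros(n)
    delta = np.zeros((n, T))
    tau = {k: fixed_precisions.get(k, 10.0) for k in _EFFECTS}

    n_keep = (spec.n_iter - spec.n_burn + spec.thin - 1) // spec.thin
    out = {
        "mu": np.empty(n_keep),
        "alpha": np.empty((n_keep, T)),
        "gamma": np.empty((n_keep, T)),
        "theta": np.empty((n_keep, n)),
        "phi": np.empty((n_keep, n)),
        "delta": np.empty((n_keep, n, T)),
        "tau": {k: np.empty(n_keep) for k in _EFFECTS},
    }

    w_col = w.sum(axis=0)  # per-year data precision
    w_row = w.sum(axis=1)  # per-region data precision
    w_tot = w.sum()
    keep = 0

    use_collapsed = (
        spec.precision_sampler == "collapsed"
        and include == {"mu", *_EFFECTS}
        and not fixed_precisions
    )
    if use_collapsed:
        pair_t = _PairCollapse(R, w_col, a, b)
        pair_s = _PairCollapse(Q, w_row, a, b)
        A_s = np.zeros((2, 2 * n))
        A_s[0, :n] = 1.0
        A_s[1, n:] = 1.0
        A_t = np.zeros((3 if spec.temporal_order == 2 else 2, 2 * T))
        A_t[0, :T] = 1.0
        A_t[1, T:] = 1.0
        if spec.temporal_order == 2:
            A_t[2, T:] = np.arange(T) - (T - 1) / 2.0
        Dt, Ds = np.diag(w_col), np.diag(w_row)
        eye_T, eye_n = np.eye(T), np.eye(n)
        jit_2T, jit_2n = 1e-10 * np.eye(2 * T), 1e-10 * np.eye(2 * n)

    def resid(exclude):
        eta = mu + alpha[None, :] + gamma[None, :] + theta[:, None] + phi[:, None] + delta
        return wy - w * (eta - exclude)

    for it in range(spec.n_iter):
        if "mu" in include:
            prec = w_tot + 1.0 / spec.mu_prior_variance
            r = resid(mu).sum()
            mu = r / prec + rng.standard_normal() / np.sqrt(prec)

        if use_collapsed:
            # temporal pair: collapsed precision updates, then a joint
            # constrained draw of (alpha, gamma)
            s_t = resid(alpha[None, :] + gamma[None, :]).sum(axis=0)
            tau["alpha"], tau["gamma"] = pair_t.sample_precisions(
                s_t, tau["alpha"], tau["gamma"], rng
            )
            C = np.block(
                [[tau["alpha"] * eye_T + Dt, Dt], [Dt, tau["gamma"] * R + Dt]]
            ) + jit_2T
            x = _sample_gaussian(C, np.concatenate([s_t, s_t]), rng, constraints=A_t)
            alpha, gamma = x[:T], x[T:]

            # spatial pair: same treatment for (theta, phi)
            s_r = resid(theta[:, None] + phi[:, None]).sum(axis=1)
            tau["theta"], tau["phi"] = pair_s.sample_precisions(
                s_r, tau["theta"], tau["phi"], rng
            )
            C = np.block(
                [[tau["theta"] * eye_n + Ds, Ds], [Ds, tau["phi"] * Q + Ds]]
            ) + jit_2n
            x = _sample_gaussian(C, np.concatenate([s_r, s_r]), rng, constraints=A_s)
            theta, phi = x[:n], x[n:]

            # interaction: conjugate update, double-centred, conjugate Gamma
            prec = tau["delta"] + w
            r = resid(delta)
            delta = r / prec + rng.standard_normal((n, T)) / np.sqrt(prec)
            delta = delta - delta.mean(axis=1, keepdims=True)
            delta = delta - delta.mean(axis=0, keepdims=True)
            tau["delta"] = rng.gamma(
                a + rank["delta"] / 2.0, 1.0 / (b + (delta * delta).sum() / 2.0)
            )

            if it >= spec.n_burn and (it - spec.n_burn) % spec.thin == 0:
                out["mu"][keep] = mu
                out["alpha"][keep] = alpha
                out["gamma"][keep] = gamma
                out["theta"][keep] = theta
                out["phi"][keep] = phi
                out["delta"][keep] = delta
                for k in _EFFECTS:
                    out["tau"][k][keep] = tau[k]
                keep += 1
            continue

        if "alpha" in include:
            prec = tau["alpha"] + w_col
            r = resid(alpha[None, :]).sum(axis=0)
            alpha = r / prec + rng.standard_normal(T) / np.sqrt(prec)
            if constrain:
                alpha = alpha - alpha.mean()

        if "gamma" in include:
            C = tau["gamma"] * R + np.diag(w_col) + jitter_T
            r = resid(gamma[None, :]).sum(axis=0)
            gamma = _sample_gaussian(C, r, rng)
            if constrain:
                gamma = proj_gamma @ gamma

        if "theta" in include:
            prec = tau["theta"] + w_row
            r = resid(theta[:, None]).sum(axis=1)
            theta = r / prec + rng.standard_normal(n) / np.sqrt(prec)
            if constrain:
                theta = theta - theta.mean()

        if "phi" in include:
            C = tau["phi"] * Q + np.diag(w_row) + jitter_n
            r = resid(phi[:, None]).sum(axis=1)
            phi = _sample_gaussian(C, r, rng)
            if constrain:
                phi = phi - phi.mean()
            else:
                phi = phi - phi.mean()  # ICAR is intrinsic: always sum-zero

        if "delta" in include:
            prec = tau["delta"] + w
            r = resid(delta)
            delta = r / prec + rng.standard_normal((n, T)) / np.sqrt(prec)
            if constrain:
                delta = delta - delta.mean(axis=1, keepdims=True)
                delta = delta - delta.mean(axis=0, keepdims=True)

        quad = {
            "alpha": alpha @ alpha,
            "gamma": gamma @ R @ gamma,
            "theta": theta @ theta,
            "phi": phi @ Q @ phi,
            "delta": float((delta * delta).sum()),
        }
        for k in _EFFECTS:
            if k in include and k not in fixed_precisions:
                tau[k] = rng.gamma(a + rank[k] / 2.0, 1.0 / (b + quad[k] / 2.0))

        if it >= spec.n_burn and (it - spec.n_burn) % spec.thin == 0:
            out["mu"][keep] = mu
            out["alpha"][keep] = alpha
            out["gamma"][keep] = gamma
            out["theta"][keep] = theta
            out["phi"][keep] = phi
            out["delta"][keep] = delta
            for k in _EFFECTS:
                out["tau"][k][keep] = tau[k]
            keep += 1

    return PosteriorSamples(
        regions=cells.regions,
        years=cells.years,
        spec=spec,
        mu=out["mu"][:keep],
        alpha=out["alpha"][:keep],
        gamma=out["gamma"][:keep],
        theta=out["theta"][:keep],
        phi=out["phi"][:keep],
        delta=out["delta"][:keep],
        tau={k: v[:keep] for k, v in out["tau"].items()},
        gamma_scale=sR,
        constrained=constrain,
    )


def _interval(draws: np.ndarray, level: float):
    lo = (1 - level) / 2
    return (
        np.median(draws, axis=0),
        np.quantile(draws, lo, axis=0),
        np.quantile(draws, 1 - lo, axis=0),
    )


def posterior_summaries(samples: PosteriorSamples, level: float = 0.95) -> dict:
    """Elementwise posterior medians and central credible intervals.

    Returns a dict of tidy DataFrames per effect, plus ``eta`` (logit
    scale) and ``u5mr`` (back-transformed to deaths per 1000).
    """
    if samples.n_draws < 100:
        import warnings

        warnings.warn("fewer than 100 retained draws; summaries will be noisy")
    out = {}
    med, lo, hi = _interval(samples.mu, level)
    out["mu"] = pd.DataFrame({"median": [med], "lower": [lo], "upper": [hi]})
    for name, draws, index in [
        ("alpha", samples.alpha, samples.years),
        ("gamma", samples.gamma, samples.years),
        ("theta", samples.theta, samples.regions),
        ("phi", samples.phi, samples.regions),
    ]:
        med, lo, hi = _interval(draws, level)
        out[name] = pd.DataFrame(
            {"index": list(index), "median": med, "lower": lo, "upper": hi}
        )
    eta = samples.eta_draws()
    med, lo, hi = _interval(eta, level)
    n, T = med.shape
    grid = pd.DataFrame(
        {
            "region": np.repeat(samples.regions, T),
            "year": np.tile(samples.years, n),
            "median": med.ravel(),
            "lower": lo.ravel(),
            "upper": hi.ravel(),
        }
    )
    out["eta"] = grid
    u5 = grid.copy()
    for c in ("median", "lower", "upper"):
        u5[c] = 1000.0 * expit(u5[c])
    out["u5mr"] = u5
    med, lo, hi = _interval(samples.delta, level)
    out["delta"] = pd.DataFrame(
        {
            "region": np.repeat(samples.regions, T),
            "year": np.tile(samples.years, n),
            "median": med.ravel(),
            "lower": lo.ravel(),
            "upper": hi.ravel(),
        }
    )
    return out


@dataclass(frozen=True)
class ForecastResult:
    """Posterior median and credible band of U5MR for future years."""

    table: pd.DataFrame  # region, year, median, lower, upper (per 1000)
    horizon: int
    level: float


def forecast(samples: PosteriorSamples, H: int, seed: int = 0, level: float = 0.95) -> ForecastResult:
    """Project U5MR H years past the data through the random-walk recursion.

    Per retained draw, the structured temporal term is simulated forward
    (order 2: gamma_{T+h} = 2 gamma_{T+h-1} - gamma_{T+h-2} + innovation,
    innovation variance 1/tau_gamma of that draw); the future linear
    predictor is mu + gamma_{T+h} + theta_i + phi_i.  The iid temporal and
    interaction terms are not projected forward.
    """
    if H < 0:
        raise ValueError("H must be >= 0")
    cols = ["region", "year", "median", "lower", "upper"]
    if H == 0:
        return ForecastResult(pd.DataFrame(columns=cols), horizon=0, level=level)
    rng = np.random.default_rng(seed)
    S, T = samples.gamma.shape
    order = samples.spec.temporal_order
    sd = 1.0 / np.sqrt(samples.tau["gamma"] * samples.gamma_scale)  # (S,)
    g = np.empty((S, H))
    prev1 = samples.gamma[:, -1]
    prev2 = samples.gamma[:, -2] if T >= 2 else np.zeros(S)
    for h in range(H):
        innov = rng.standard_normal(S) * sd
        if order == 2:
            new = 2 * prev1 - prev2 + innov
        else:
            new = prev1 + innov
        g[:, h] = new
        prev2, prev1 = prev1, new

    base = samples.mu[:, None] + samples.theta + samples.phi  # (S, n)
    eta_f = base[:, :, None] + g[:, None, :]  # (S, n, H)
    med, lo_q, hi_q = _interval(1000.0 * expit(eta_f), level)
    n = len(samples.regions)
    years_f = samples.years[-1] + 1 + np.arange(H)
    table = pd.DataFrame(
        {
            "region": np.repeat(samples.regions, H),
            "year": np.tile(years_f, n),
            "median": med.ravel(),
            "lower": lo_q.ravel(),
            "upper": hi_q.ravel(),
        }
    )
    return ForecastResult(table=table, horizon=H, level=level)


def effective_sample_size(samples: PosteriorSamples) -> pd.DataFrame:
    """ESS of the grand mean and the five precision chains (mixing diagnostic)."""

    def ess(x):
        return float(az.ess(az.convert_to_dataset(x[None, :]))["x"].values)

    rows = [("mu", ess(samples.mu))]
    rows += [(f"tau_{k}", ess(draws)) for k, draws in samples.tau.items()]
    return pd.DataFrame(rows, columns=["parameter", "ess"])
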