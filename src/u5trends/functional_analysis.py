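"""Functional representation of mortality trajectories and one-way FANOVA.

Each region's (or stratum's) annual U5MR series is represented as a smooth
function on a B-spline basis, fitted by penalised least squares with an
integrated-squared-second-derivative roughness penalty (lambda chosen by
GCV if not given).  One-way functional ANOVA regresses the curves on group
indicators pointwise, and inference uses a permutation null distribution
of the pointwise F statistic: per-point 95th percentiles give the
pointwise critical curve, and the 95th percentile of the maximum over
points gives the global (max-statistic) threshold and p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

__all__ = [
    "BasisSystem",
    "FunctionalCurve",
    "FanovaFit",
    "FanovaResult",
    "build_basis",
    "smooth_curve",
    "mean_curve_ci",
    "fit_fanova",
    "pointwise_F",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasisSystem:
    """B-spline basis on a closed interval.

    ``order`` follows the spline-order convention (degree + 1, so 4 means
    cubic); interior knots are strictly inside the domain, and the number
    of basis functions is ``len(interior_knots) + order``.
    """

    domain: tuple[float, float]
    interior_knots: tuple[float, ...]
    order: int = 4
    penalty_order: int = 2

    def __post_init__(self):
        a, b = self.domain
        if not b > a:
            raise ValueError("degenerate domain")
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if any(not a < k < b for k in self.interior_knots):
            raise ValueError("interior knots must lie strictly inside the domain")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be sorted")

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        a, b = self.domain
        return np.concatenate(
            [[a] * self.order, list(self.interior_knots), [b] * self.order]
        )

    def design_matrix(self, x, deriv: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at points x."""
        x = np.asarray(x, dtype=float)
        t = self.knot_vector
        k = self.order - 1
        cols = np.empty((x.size, self.n_basis))
        for j in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[j] = 1.0
            spl = BSpline(t, c, k, extrapolate=True)
            if deriv:
                spl = spl.derivative(deriv)
            cols[:, j] = spl(x)
        return cols

    def penalty_matrix(self) -> np.ndarray:
        """Gram matrix of penalty_order-th derivatives, by exact Gauss-Legendre.

        The integrand is piecewise polynomial of degree
        2*(order - 1 - penalty_order), so ``order`` nodes per inter-knot
        interval integrate it exactly.
        """
        breaks = np.unique(self.knot_vector)
        nodes, weights = np.polynomial.legendre.leggauss(max(self.order, 3))
        P = np.zeros((self.n_basis, self.n_basis))
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            half = (hi - lo) / 2.0
            x = lo + half * (nodes + 1.0)
            B2 = self.design_matrix(x, deriv=self.penalty_order)
            P += half * (B2 * weights[:, None]).T @ B2
        return P


def build_basis(
    domain: tuple[float, float], n_interior_knots: int, order: int = 4
) -> BasisSystem:
    """Basis with equally spaced interior knots; size = n_interior_knots + order."""
    a, b = domain
    interior = tuple(np.linspace(a, b, n_interior_knots + 2)[1:-1])
    return BasisSystem(domain=(float(a), float(b)), interior_knots=interior, order=order)


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionalCurve:
    """A function expressed as coefficients on a shared B-spline basis."""

    basis: BasisSystem
    coefficients: np.ndarray
    label: str | None = None
    smoothing_lambda: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.coefficients) != self.basis.n_basis:
            raise ValueError("coefficient length must equal basis size")

    def __call__(self, x) -> np.ndarray:
        return self.basis.design_matrix(x) @ np.asarray(self.coefficients)


def smooth_curve(series, basis: BasisSystem, lam="gcv", label=None) -> FunctionalCurve:
    """Penalised least-squares smooth of an annual series onto the basis.

    ``series`` maps years to values (dict or pandas Series).  ``lam`` is
    the roughness penalty weight, or ``"gcv"`` to minimise generalised
    cross-validation over a log-spaced grid.  Large lambda shrinks the fit
    to the penalty null space (a straight line for the default
    second-derivative penalty).
    """
    if isinstance(series, pd.Series):
        x = series.index.to_numpy(dtype=float)
        y = series.to_numpy(dtype=float)
    else:
        items = sorted(series.items())
        x = np.array([k for k, _ in items], dtype=float)
        y = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    B = basis.design_matrix(x)
    P = basis.penalty_matrix()
    BtB, Bty = B.T @ B, B.T @ y

    def fit(l):
        return np.linalg.solve(BtB + l * P + 1e-12 * np.eye(basis.n_basis), Bty)

    if isinstance(lam, str):
        if lam != "gcv":
            raise ValueError("lam must be a number or 'gcv'")
        n = len(y)
        best = (np.inf, 0.0)
        for l in np.logspace(-8, 8, 49):
            c = fit(l)
            resid = y - B @ c
            H_trace = np.trace(
                np.linalg.solve(BtB + l * P + 1e-12 * np.eye(basis.n_basis), BtB)
            )
            denom = max(n - H_trace, 1e-8)
            g = n * float(resid @ resid) / denom**2
            if g < best[0]:
                best = (g, l)
        lam = best[1]
    else:
        if len(y) < basis.n_basis and lam == 0:
            raise ValueError("unpenalised fit needs at least basis-size observations")
    coef = fit(float(lam))
    return FunctionalCurve(basis, coef, label=label, smoothing_lambda=float(lam))


def mean_curve_ci(curves, level: float = 0.95, grid=None) -> pd.DataFrame:
    """Cross-sectional mean curve with pointwise normal intervals.

    Returns a DataFrame (grid, mean, lower, upper); interval is
    mean +/- z * sd / sqrt(n) at each grid point.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    basis = curves[0].basis
    if any(c.basis != basis for c in curves):
        raise ValueError("curves must share a basis")
    if grid is None:
        a, b = basis.domain
        grid = np.arange(np.ceil(a), np.floor(b) + 1)
    grid = np.asarray(grid, dtype=float)
    B = basis.design_matrix(grid)
    Y = np.stack([c.coefficients for c in curves]) @ B.T
    m = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    z = norm.ppf(0.5 + level / 2)
    half = z * sd / np.sqrt(len(curves))
    return pd.DataFrame({"grid": grid, "mean": m, "lower": m - half, "upper": m + half})


# ---------------------------------------------------------------------------
# FANOVA
# ---------------------------------------------------------------------------


@dataclass
class FanovaFit:
    """Pointwise one-way ANOVA decomposition of a set of curves."""

    grid: np.ndarray
    labels: list
    groups: list  # unique group labels, in first-appearance order
    codes: np.ndarray  # group code per curve
    values: np.ndarray  # (N, P) curve values on the grid
    mu: np.ndarray  # (P,) grand mean
    beta: np.ndarray  # (G, P) group effects, weighted sum-to-zero
    residuals: np.ndarray  # (N, P)
    basis: BasisSystem | None = None

    def mu_curve(self) -> FunctionalCurve:
        return _project(self.mu, self.grid, self.basis)

    def beta_curves(self) -> list[FunctionalCurve]:
        return [
            _project(self.beta[g], self.grid, self.basis, label=str(lab))
            for g, lab in enumerate(self.groups)
        ]


def _project(values, grid, basis, label=None) -> FunctionalCurve:
    """Least-squares projection of grid values back onto the basis."""
    if basis is None:
        raise ValueError("fit has no basis attached")
    B = basis.design_matrix(grid)
    coef, *_ = np.linalg.lstsq(B, values, rcond=None)
    return FunctionalCurve(basis, coef, label=label)


def fit_fanova(curves, labels, grid=None) -> FanovaFit:
    """Pointwise least squares of curve values on group indicators.

    Under the weighted sum-to-zero constraint sum_g n_g beta_g(t) = 0 the
    solution is the overall mean mu(t) and group deviations
    beta_g(t) = ybar_g(t) - mu(t).  Requires more curves than groups so
    residual degrees of freedom are positive.
    """
    curves = list(curves)
    labels = list(labels)
    if len(curves) != len(labels):
        raise ValueError("one label per curve required")
    basis = curves[0].basis
    if any(c.basis != basis for c in curves):
        raise ValueError("curves must share a basis")
    if grid is None:
        a, b = basis.domain
        grid = np.arange(np.ceil(a), np.floor(b) + 1)
    grid = np.asarray(grid, dtype=float)

    groups = list(dict.fromkeys(labels))
    codes = np.array([groups.index(l) for l in labels])
    N, G = len(curves), len(groups)
    if N <= G:
        raise ValueError(
            "FANOVA needs more curves than groups (replicate curves per group); "
            "with one curve per group there are no residual degrees of freedom"
        )
    B = basis.design_matrix(grid)
    Y = np.stack([c.coefficients for c in curves]) @ B.T
    mu = Y.mean(axis=0)
    beta = np.stack([Y[codes == g].mean(axis=0) - mu for g in range(G)])
    resid = Y - mu - beta[codes]
    return FanovaFit(
        grid=grid, labels=labels, groups=groups, codes=codes, values=Y,
        mu=mu, beta=beta, residuals=resid, basis=basis,
    )


def _f_statistic(Y: np.ndarray, codes: np.ndarray, G: int) -> np.ndarray:
    """Pointwise one-way ANOVA F over the columns of Y (rows = curves)."""
    N = Y.shape[0]
    ybar = Y.mean(axis=0)
    ssb = np.zeros(Y.shape[1])
    ssw = np.zeros(Y.shape[1])
    for g in range(G):
        block = Y[codes == g]
        mg = block.mean(axis=0)
        ssb += block.shape[0] * (mg - ybar) ** 2
        ssw += ((block - mg) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (G - 1)) / (ssw / (N - G))
    # ssw == 0 with real between-group signal is +inf; ssb at rounding-noise
    # level (identical curves) is 0
    tol = 1e-12 * N * (np.abs(Y).max() ** 2 + 1e-300)
    return np.where(ssw == 0, np.where(ssb > tol, np.inf, 0.0), f)


def _f_statistic_perms(Y, perm_codes, G):
    """F(t) for many label permutations at once: perm_codes is (n_perm, N)."""
    n_perm, N = perm_codes.shape
    P = Y.shape[1]
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)  # label-invariant
    ybar = Y.mean(axis=0)
    ssb = np.zeros((n_perm, P))
    for g in range(G):
        mask = (perm_codes == g).astype(float)  # (n_perm, N)
        ng = mask.sum(axis=1)[:, None]
        mg = (mask @ Y) / ng
        ssb += ng * (mg - ybar) ** 2
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (G - 1)) / (ssw / (N - G))
    return np.where(ssw <= 0, np.where(ssb <= 0, 0.0, np.inf), f)


def pointwise_F(fit: FanovaFit) -> np.ndarray:
    """Observed F(t) = [SSB(t)/(G-1)] / [SSW(t)/(N-G)] on the fit's grid."""
    return _f_statistic(fit.values, fit.codes, len(fit.groups))


@dataclass(frozen=True)
class FanovaResult:
    """Observed F curve with permutation critical values and global p-value."""

    grid: np.ndarray
    F_observed: np.ndarray
    pointwise_crit: np.ndarray
    max_crit: float
    p_global: float
    n_perm: int
    seed: int
    groups: list
    mu: np.ndarray
    beta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "F_observed": self.F_observed,
                "pointwise_crit": self.pointwise_crit,
                "max_crit": self.max_crit,
            }
        )


def permutation_test(
    curves, labels, n_perm: int = 1000, seed: int = 0, grid=None, level: float = 0.95
) -> FanovaResult:
    """Permutation FANOVA: pointwise and max-statistic critical values.

    Group labels are reshuffled ``n_perm`` times; the pointwise critical
    curve is the per-point ``level`` quantile of the permuted F values,
    the global threshold is the same quantile of max_t F, and
    p_global = (1 + #{perm max F >= observed max F}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable tail percentiles")
    fit = fit_fanova(curves, labels, grid=grid)
    G = len(fit.groups)
    f_obs = pointwise_F(fit)

    rng = np.random.default_rng(seed)
    perm_codes = np.stack([rng.permutation(fit.codes) for _ in range(n_perm)])
    f_perm = _f_statistic_perms(fit.values, perm_codes, G)

    pointwise_crit = np.quantile(f_perm, level, axis=0)
    max_perm = f_perm.max(axis=1)
    max_obs = f_obs.max()
    max_crit = float(np.quantile(max_perm, level))
    p_global = (1.0 + np.sum(max_perm >= max_obs)) / (n_perm + 1.0)
    return FanovaResult(
        grid=fit.grid,
        F_observed=f_obs,
        pointwise_crit=pointwise_crit,
        max_crit=max_crit,
        p_global=float(p_global),
        n_perm=n_perm,
        seed=seed,
        groups=fit.groups,
        mu=fit.mu,
        beta=fit.beta,
    )
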