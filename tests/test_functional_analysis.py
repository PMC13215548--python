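import numpy as np
import pytest
from scipy.stats import f_oneway

from u5trends import functional_analysis as fa


def deboor(x, t, k, j):
    """Independent Cox-de Boor recursion for basis function j of degree k."""
    if k == 0:
        # half-open intervals, closed at the right boundary
        if t[j] <= x < t[j + 1]:
            return 1.0
        if x == t[-1] and t[j] < t[j + 1] <= t[-1] and t[j + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[j + k] > t[j]:
        left = (x - t[j]) / (t[j + k] - t[j]) * deboor(x, t, k - 1, j)
    right = 0.0
    if t[j + k + 1] > t[j + 1]:
        right = (t[j + k + 1] - x) / (t[j + k + 1] - t[j + 1]) * deboor(x, t, k - 1, j + 1)
    return left + right


@pytest.fixture(scope="module")
def basis():
    return fa.build_basis((0.0, 10.0), n_interior_knots=5, order=4)


class TestBasis:
    def test_size_is_knots_plus_order(self):
        b = fa.build_basis((1990, 2022), 10, order=4)
        assert b.n_basis == 14

    def test_partition_of_unity(self, basis):
        x = np.linspace(0, 10, 101)
        assert np.allclose(basis.design_matrix(x).sum(axis=1), 1.0, atol=1e-10)

    def test_matches_de_boor_recursion(self, basis):
        x = np.array([0.3, 2.5, 5.0, 7.9, 9.6])
        B = basis.design_matrix(x)
        t = basis.knot_vector
        for i, xi in enumerate(x):
            for j in range(basis.n_basis):
                assert B[i, j] == pytest.approx(deboor(xi, t, 3, j), abs=1e-12)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            fa.BasisSystem(domain=(1.0, 1.0), interior_knots=())

    def test_penalty_annihilates_lines(self, basis):
        """A straight line has zero roughness: coefficients of a linear fit
        lie in the penalty null space."""
        x = np.linspace(0, 10, 50)
        coef, *_ = np.linalg.lstsq(basis.design_matrix(x), 2.0 + 0.5 * x, rcond=None)
        P = basis.penalty_matrix()
        assert coef @ P @ coef == pytest.approx(0.0, abs=1e-8)


class TestSmoothing:
    def test_interpolation_at_zero_lambda(self, basis):
        x = np.linspace(0.2, 9.8, basis.n_basis)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(len(x))
        curve = fa.smooth_curve(dict(zip(x, y)), basis, lam=0.0)
        assert np.allclose(curve(x), y, atol=1e-6)

    def test_huge_lambda_gives_straight_line(self, basis):
        x = np.linspace(0, 10, 30)
        rng = np.random.default_rng(1)
        y = np.sin(x) + rng.standard_normal(30) * 0.1
        curve = fa.smooth_curve(dict(zip(x, y)), basis, lam=1e12)
        fitted = curve(x)
        slope, intercept = np.polyfit(x, fitted, 1)
        assert np.allclose(fitted, intercept + slope * x, atol=1e-4)
        # and it is the least-squares line of the data
        s2, i2 = np.polyfit(x, y, 1)
        assert slope == pytest.approx(s2, abs=1e-4)

    def test_gcv_beats_raw_noise(self, basis):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 40)
        truth = np.sin(x)
        y = truth + rng.standard_normal(40) * 0.4
        curve = fa.smooth_curve(dict(zip(x, y)), basis, lam="gcv")
        rmse_smooth = np.sqrt(np.mean((curve(x) - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((y - truth) ** 2))
        assert rmse_smooth < rmse_raw

    def test_linear_in_data(self, basis):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 25)
        y = rng.standard_normal(25)
        c1 = fa.smooth_curve(dict(zip(x, y)), basis, lam=2.5)
        c3 = fa.smooth_curve(dict(zip(x, 3 * y)), basis, lam=2.5)
        assert np.allclose(3 * c1.coefficients, c3.coefficients, atol=1e-9)

    def test_nonfinite_rejected(self, basis):
        with pytest.raises(ValueError, match="finite"):
            fa.smooth_curve({0.0: 1.0, 5.0: np.nan, 10.0: 2.0}, basis, lam=1.0)


class TestMeanCurve:
    def _curves(self, basis, coefs):
        return [fa.FunctionalCurve(basis, np.asarray(c, dtype=float)) for c in coefs]

    def test_identical_curves_zero_width(self, basis):
        c = np.arange(basis.n_basis, dtype=float)
        df = fa.mean_curve_ci(self._curves(basis, [c, c, c]), grid=np.linspace(0, 10, 11))
        assert np.allclose(df.upper - df.lower, 0.0, atol=1e-12)

    def test_two_curves_mean_is_average(self, basis):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, basis.n_basis))
        grid = np.linspace(0, 10, 7)
        df = fa.mean_curve_ci(self._curves(basis, [a, b]), grid=grid)
        expected = (self._curves(basis, [a])[0](grid) + self._curves(basis, [b])[0](grid)) / 2
        assert np.allclose(df["mean"], expected)

    def test_hand_computed_interval(self, basis):
        """Three constant curves 1, 2, 3: sd = 1, CI = 2 +/- 1.96/sqrt(3)."""
        ones = np.ones(basis.n_basis)
        curves = self._curves(basis, [ones, 2 * ones, 3 * ones])
        df = fa.mean_curve_ci(curves, level=0.95, grid=np.array([5.0]))
        from scipy.stats import norm

        half = norm.ppf(0.975) / np.sqrt(3)
        assert df["mean"][0] == pytest.approx(2.0)
        assert df.upper[0] - df["mean"][0] == pytest.approx(half, rel=1e-9)

    def test_mismatched_bases_rejected(self, basis):
        other = fa.build_basis((0.0, 10.0), 3)
        with pytest.raises(ValueError, match="share a basis"):
            fa.mean_curve_ci(
                [fa.FunctionalCurve(basis, np.zeros(basis.n_basis)),
                 fa.FunctionalCurve(other, np.zeros(other.n_basis))]
            )


@pytest.fixture(scope="module")
def toy_curves(basis):
    """Six curves in two groups with a known group contrast."""
    rng = np.random.default_rng(5)
    curves, labels = [], []
    for g, shift in enumerate((0.0, 1.5)):
        for _ in range(3):
            coef = rng.standard_normal(basis.n_basis) + shift
            curves.append(fa.FunctionalCurve(basis, coef))
            labels.append(f"g{g}")
    return curves, labels


class TestFanova:
    def test_identical_curves_zero_effects(self, basis):
        c = np.linspace(0, 1, basis.n_basis)
        curves = [fa.FunctionalCurve(basis, c) for _ in range(6)]
        fit = fa.fit_fanova(curves, ["a", "a", "b", "b", "c", "c"])
        assert np.allclose(fit.beta, 0.0, atol=1e-12)
        assert np.allclose(fa.pointwise_F(fit), 0.0, atol=1e-12)

    def test_weighted_sum_to_zero_constraint(self, toy_curves):
        curves, labels = toy_curves
        fit = fa.fit_fanova(curves, labels)
        n_g = np.array([(fit.codes == g).sum() for g in range(len(fit.groups))])
        assert np.allclose(n_g @ fit.beta, 0.0, atol=1e-9)

    def test_constant_shift_oracle(self, basis):
        """Adding c to one of G equal groups moves its effect by c(G-1)/G."""
        rng = np.random.default_rng(6)
        coefs = rng.standard_normal((9, basis.n_basis))
        curves = [fa.FunctionalCurve(basis, c) for c in coefs]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        base = fa.fit_fanova(curves, labels)
        shift = 2.0
        shifted = [
            fa.FunctionalCurve(basis, c + (shift if l == "b" else 0.0))
            for c, l in zip(coefs, labels)
        ]
        fit = fa.fit_fanova(shifted, labels)
        G = 3
        assert np.allclose(fit.beta[1] - base.beta[1], shift * (G - 1) / G, atol=1e-9)
        assert np.allclose(fit.beta[0] - base.beta[0], -shift / G, atol=1e-9)

    def test_no_replication_rejected(self, basis):
        curves = [fa.FunctionalCurve(basis, np.zeros(basis.n_basis)) for _ in range(3)]
        with pytest.raises(ValueError, match="replicate"):
            fa.fit_fanova(curves, ["a", "b", "c"])

    def test_pointwise_f_equals_scalar_anova(self, toy_curves):
        curves, labels = toy_curves
        fit = fa.fit_fanova(curves, labels)
        F = fa.pointwise_F(fit)
        for j in range(len(fit.grid)):
            samples = [fit.values[fit.codes == g, j] for g in range(len(fit.groups))]
            assert F[j] == pytest.approx(f_oneway(*samples).statistic, abs=1e-10)

    def test_invariant_to_common_function(self, toy_curves, basis):
        curves, labels = toy_curves
        common = np.linspace(-4, 7, basis.n_basis)
        shifted = [fa.FunctionalCurve(basis, c.coefficients + common) for c in curves]
        f1 = fa.pointwise_F(fa.fit_fanova(curves, labels))
        f2 = fa.pointwise_F(fa.fit_fanova(shifted, labels))
        assert np.allclose(f1, f2, atol=1e-8)


class TestPermutationTest:
    def test_deterministic_given_seed(self, toy_curves):
        curves, labels = toy_curves
        a = fa.permutation_test(curves, labels, n_perm=200, seed=9)
        b = fa.permutation_test(curves, labels, n_perm=200, seed=9)
        assert a.p_global == b.p_global
        assert np.array_equal(a.pointwise_crit, b.pointwise_crit)

    def test_p_value_bounds_and_crit_ordering(self, toy_curves):
        curves, labels = toy_curves
        res = fa.permutation_test(curves, labels, n_perm=200, seed=10)
        assert 1 / 201 <= res.p_global <= 1.0
        assert np.all(res.pointwise_crit <= res.max_crit + 1e-12)

    def test_too_few_permutations_rejected(self, toy_curves):
        curves, labels = toy_curves
        with pytest.raises(ValueError, match="n_perm"):
            fa.permutation_test(curves, labels, n_perm=50, seed=0)

    def test_detects_localised_effect(self, basis):
        """A strong group effect confined to part of the domain: F exceeds the
        pointwise threshold there and the global test rejects."""
        rng = np.random.default_rng(11)
        grid = np.linspace(0, 10, 33)
        bump_region = (grid >= 2) & (grid <= 4)
        B = basis.design_matrix(grid)
        curves, labels = [], []
        for g in range(2):
            for _ in range(4):
                y = rng.standard_normal(33) * 0.3
                if g == 1:
                    y = y + np.where(bump_region, 4.0, 0.0)
                coef, *_ = np.linalg.lstsq(B, y, rcond=None)
                curves.append(fa.FunctionalCurve(basis, coef))
                labels.append(f"g{g}")
        res = fa.permutation_test(curves, labels, n_perm=500, seed=12, grid=grid)
        assert res.p_global < 0.05
        assert np.any(res.F_observed[bump_region] > res.pointwise_crit[bump_region])
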