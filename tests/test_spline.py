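"""Parametric spline curve: ordering, fitting, coefficients, diagnostics."""

import numpy as np
import pytest

from marcex import (
    SplineCurveModel,
    evaluate_curve,
    export_coefficients,
    fit_parametric_spline,
    knot_residuals,
    order_points,
)
from marcex.spline import (
    KnotSequence,
    PiecewiseCurve,
    PolynomialPiece,
    import_coefficients,
    max_relative_residual,
)


# ---------------------------------------------------------------------------
# independent oracle: natural cubic spline via the second-derivative
# tridiagonal system, assembled and solved with plain numpy
# ---------------------------------------------------------------------------

def natural_spline_oracle(x, y):
    """Return f(s) evaluating the natural cubic interpolant of (x, y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0  # natural: zero second derivative at the ends
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, b)  # second derivatives at knots

    def f(s):
        i = min(max(int(np.searchsorted(x, s, side="right")) - 1, 0), n - 2)
        u, hi = s - x[i], h[i]
        return (
            M[i] * (x[i + 1] - s) ** 3 / (6 * hi)
            + M[i + 1] * u**3 / (6 * hi)
            + (y[i] / hi - M[i] * hi / 6) * (x[i + 1] - s)
            + (y[i + 1] / hi - M[i + 1] * hi / 6) * u
        )

    return f


class TestOrdering:
    def test_lexicographic_endpoints(self, table1):
        pts = order_points(table1, "TPC", "lexicographic")
        assert pts.shape == (15, 3)
        assert tuple(pts[0]) == (30, 0, 3.41)
        assert tuple(pts[-1]) == (65, 96, 2.39)

    def test_serpentine_reverses_middle_block(self, table1):
        pts = order_points(table1, "TPC", "serpentine")
        # the second temperature block (45 °C) starts at the high-ethanol end
        assert tuple(pts[5][:2]) == (45, 96)
        assert tuple(pts[9][:2]) == (45, 0)
        # same point set either way
        lex = order_points(table1, "TPC", "lexicographic")
        assert {tuple(p) for p in pts} == {tuple(p) for p in lex}

    def test_single_temperature_schemes_coincide(self, table1):
        from marcex import Condition, ExtractionDataset, ResponseValue

        conds = [Condition(30, c) for c in (0, 40, 60, 80, 96)]
        ds = ExtractionDataset(
            conditions=conds,
            responses={"R": [ResponseValue(v) for v in (1, 2, 5, 3, 1)]},
        )
        np.testing.assert_array_equal(
            order_points(ds, "R", "lexicographic"), order_points(ds, "R", "serpentine")
        )

    def test_unknown_scheme(self, table1):
        with pytest.raises(ValueError, match="scheme"):
            order_points(table1, "TPC", "spiral")


class TestCoefficientAccounting:
    def test_cubic_fit_of_factorial_grid_has_168_coefficients(self, table1):
        res = SplineCurveModel(table1, "TPC").fit()
        assert res.curve.n_coefficients == (15 - 1) * 3 * 4 == 168
        assert len(res.coefficients) == 168

    def test_linear_fit_halves_the_count(self, table1):
        res = SplineCurveModel(table1, "TPC", k=1).fit()
        assert res.curve.n_coefficients == (15 - 1) * 3 * 2 == 84

    def test_two_point_degenerate_curve_exports_12_rows(self):
        # a single cubic piece per direction, built directly
        pieces = {
            d: [PolynomialPiece(0, 0.0, (0.0, 0.0, 1.0, float(i)))]
            for i, d in enumerate(("t", "C", "response"))
        }
        curve = PiecewiseCurve(KnotSequence((0.0, 1.0)), 3, pieces)
        assert len(export_coefficients(curve)) == 1 * 3 * 4 == 12

    @pytest.mark.parametrize("n, k", [(4, 3), (5, 3), (6, 1), (15, 3)])
    def test_count_formula(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        pts = np.column_stack(
            [np.arange(n), rng.uniform(0, 96, n), rng.uniform(0, 12, n)]
        )
        curve = fit_parametric_spline(pts, k=k)
        assert curve.n_coefficients == (n - 1) * 3 * (k + 1)


class TestInterpolation:
    @pytest.mark.parametrize("response", ["TPC", "TFC", "TC", "TAC"])
    @pytest.mark.parametrize("scheme", ["lexicographic", "serpentine"])
    def test_curve_threads_every_experimental_point(self, table1, response, scheme):
        res = SplineCurveModel(table1, response, scheme=scheme).fit()
        assert res.max_relative_residual_ <= 1e-9

    @pytest.mark.parametrize("parameterization", ["index", "chord"])
    def test_parameterizations_both_interpolate(self, table1, parameterization):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts, parameterization=parameterization)
        assert max_relative_residual(curve, pts) <= 1e-9

    def test_linear_fit_also_interpolates_at_knots(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts, k=1)
        assert max_relative_residual(curve, pts) <= 1e-9

    def test_knot_evaluation_recovers_peak_yield_point(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts)
        # (65 °C, 60 %) is the 13th point of the lexicographic walk
        i = next(i for i, p in enumerate(pts) if tuple(p[:2]) == (65, 60))
        t, c, y = evaluate_curve(curve, curve.knots[i])
        assert (t, c) == pytest.approx((65, 60), abs=1e-9)
        assert y == pytest.approx(11.02, abs=1e-9)

    def test_first_knot_is_first_point(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts)
        assert evaluate_curve(curve, curve.knots[0]) == pytest.approx(tuple(pts[0]))

    def test_collinear_points_need_no_curvature(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        curve = fit_parametric_spline(pts, boundary="natural")
        for d in ("t", "C", "response"):
            for p in curve.pieces[d]:
                assert abs(p.coefficients[0]) <= 1e-9  # cubic term
                assert abs(p.coefficients[1]) <= 1e-9  # quadratic term


class TestEvaluation:
    def test_midpoint_lies_within_piece_extrema(self, table1):
        res = SplineCurveModel(table1, "TPC").fit()
        curve = res.curve
        for i in range(curve.n_points - 1):
            a, b = curve.knots[i], curve.knots[i + 1]
            # brute-force oracle: dense sampling of this cubic piece
            dense = [curve(s)[2] for s in np.linspace(a, b, 2001)]
            mid = curve((a + b) / 2)[2]
            assert min(dense) - 1e-12 <= mid <= max(dense) + 1e-12

    def test_continuity_across_interior_knots(self, table1):
        res = SplineCurveModel(table1, "TPC").fit()
        curve = res.curve
        for i in range(1, curve.n_points - 1):
            xi = curve.knots[i]
            left, right = curve.pieces["response"][i - 1], curve.pieces["response"][i]
            assert left(xi) == pytest.approx(right(xi), abs=1e-9)

    def test_c2_continuity_of_cubic_fit(self, table1):
        # analytic first/second derivatives of adjacent pieces at each
        # interior knot must match for a C² cubic spline
        res = SplineCurveModel(table1, "TPC").fit()
        curve = res.curve
        for d in ("t", "C", "response"):
            for i in range(1, curve.n_points - 1):
                xi = curve.knots[i]
                left, right = curve.pieces[d][i - 1], curve.pieces[d][i]

                def d1(p, s):
                    c1, c2, c3, _ = p.coefficients
                    u = s - p.origin
                    return 3 * c1 * u**2 + 2 * c2 * u + c3

                def d2(p, s):
                    c1, c2, _, _ = p.coefficients
                    u = s - p.origin
                    return 6 * c1 * u + 2 * c2

                assert d1(left, xi) == pytest.approx(d1(right, xi), abs=1e-8)
                assert d2(left, xi) == pytest.approx(d2(right, xi), abs=1e-8)

    def test_out_of_range_refused_unless_extrapolating(self, table1):
        curve = SplineCurveModel(table1, "TPC").fit().curve
        with pytest.raises(ValueError, match="extrapolation"):
            evaluate_curve(curve, -0.5)
        with pytest.raises(ValueError, match="extrapolation"):
            evaluate_curve(curve, 14.5)
        assert np.isfinite(evaluate_curve(curve, -0.5, extrapolate=True)).all()

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_independent_tridiagonal_solution(self, n):
        rng = np.random.default_rng(n)
        pts = np.column_stack(
            [rng.uniform(30, 65, n), rng.uniform(0, 96, n), rng.uniform(0, 12, n)]
        )
        curve = fit_parametric_spline(pts, boundary="natural")
        s = np.arange(n, dtype=float)
        for dim, d in enumerate(("t", "C", "response")):
            oracle = natural_spline_oracle(s, pts[:, dim])
            for sv in np.linspace(0, n - 1, 40):
                i = curve.interval_of(sv)
                assert curve.pieces[d][i](sv) == pytest.approx(oracle(sv), abs=1e-9)


class TestExportImport:
    def test_round_trip_reproduces_knots(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts)
        table = export_coefficients(curve)
        rebuilt = import_coefficients(table, curve.knots, curve.order)
        assert max_relative_residual(rebuilt, pts) <= 1e-9

    def test_perturbed_coefficient_is_flagged(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts)
        table = export_coefficients(curve)
        row = table[(table.direction == "response") & (table.j == 4)].index[3]
        table.loc[row, "coefficient"] += 0.5
        rebuilt = import_coefficients(table, curve.knots, curve.order)
        assert max_relative_residual(rebuilt, pts) > 1e-6

    def test_residual_length_mismatch(self, table1):
        pts = order_points(table1, "TPC")
        curve = fit_parametric_spline(pts)
        with pytest.raises(ValueError, match="knots"):
            knot_residuals(curve, pts[:10])


class TestValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit_parametric_spline(np.zeros((3, 3)) + np.arange(3)[:, None], k=3)

    def test_unsupported_order(self):
        pts = np.column_stack([np.arange(5)] * 3)
        with pytest.raises(ValueError, match="order"):
            fit_parametric_spline(pts, k=2)

    def test_duplicate_points_break_chord_parameterization(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        with pytest.raises(ValueError, match="chord"):
            fit_parametric_spline(pts, parameterization="chord")

    def test_summary_mentions_accounting(self, table1):
        s = SplineCurveModel(table1, "TPC").fit().summary()
        assert "168" in s and "natural" in s
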