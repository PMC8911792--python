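"""Parametric piecewise-polynomial (spline) curve through a factorial grid.

The extraction experiment measures a response y on a 2-factor grid
(temperature t, ethanol concentration C).  Rather than fitting a response
surface, the model threads a single parametric space curve through all n
experimental points: the points are put in a definite order, a strictly
increasing parameter ξ₁ < … < ξₙ is assigned (knot index by default, chord
length optionally), and one interpolating spline per coordinate direction —
t(s), C(s), y(s) — is fitted.  Each direction contributes n−1 polynomial
pieces

    P_i(s) = Σ_{j=1}^{k+1} c_ji (s − ξ_i)^{k+1−j},      ξ_i ≤ s ≤ ξ_{i+1},

so a cubic fit (k = 3) of a 15-point experiment carries
(15−1) × 3 directions × 4 coefficients = 168 coefficients.  The spline
interpolates: the curve reproduces every experimental point at its knot to
numerical precision ("virtually zero modeling error"), which is the model's
defining property and is enforced by :func:`knot_residuals`.

The fitted object is exposed statsmodels-style: :class:`SplineCurveModel`
holds the data and fit options, ``fit()`` returns a
:class:`SplineCurveResults` carrying the :class:`PiecewiseCurve`, residual
diagnostics, the coefficient table and export/evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .dataset import Condition, ExtractionDataset

__all__ = [
    "KnotSequence",
    "PolynomialPiece",
    "PiecewiseCurve",
    "SplineCurveModel",
    "SplineCurveResults",
    "order_points",
    "fit_parametric_spline",
    "evaluate_curve",
    "export_coefficients",
    "import_coefficients",
    "knot_residuals",
    "max_relative_residual",
]

DIRECTIONS = ("t", "C", "response")

_BOUNDARY_MAP = {"natural": "natural", "not_a_knot": "not-a-knot"}


@dataclass(frozen=True)
class KnotSequence:
    """Strictly increasing parameter values ξ_1 … ξ_n."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least 2 knots")
        arr = np.asarray(self.values)
        if not np.all(np.diff(arr) > 0):
            raise ValueError("knots must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass(frozen=True)
class PolynomialPiece:
    """Local polynomial on [ξ_i, ξ_{i+1}]: Σ_j c_j (s − ξ_i)^{k+1−j}, j = 1…k+1."""

    interval: int  # 0-based interval index i
    origin: float  # ξ_i
    coefficients: tuple[float, ...]  # c_1 (highest power) … c_{k+1} (constant)

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, s: float | np.ndarray) -> float | np.ndarray:
        # Horner evaluation in the local variable (s − ξ_i)
        u = np.asarray(s, dtype=float) - self.origin
        acc = np.zeros_like(u)
        for c in self.coefficients:
            acc = acc * u + c
        return float(acc) if acc.ndim == 0 else acc


@dataclass
class PiecewiseCurve:
    """Fitted parametric curve: one piece list per direction (t, C, response)."""

    knots: KnotSequence
    order: int
    pieces: dict[str, list[PolynomialPiece]]
    boundary: str = "natural"
    parameterization: str = "index"
    ordering: str = "lexicographic"

    def __post_init__(self) -> None:
        n = len(self.knots)
        for d, plist in self.pieces.items():
            if len(plist) != n - 1:
                raise ValueError(f"direction {d!r}: {len(plist)} pieces for {n} knots")
            for p in plist:
                if p.order != self.order:
                    raise ValueError(
                        f"direction {d!r} interval {p.interval}: "
                        f"{len(p.coefficients)} coefficients for order {self.order}"
                    )

    @property
    def n_points(self) -> int:
        return len(self.knots)

    @property
    def n_coefficients(self) -> int:
        """(n−1) × 3 × (k+1)."""
        return (self.n_points - 1) * len(self.pieces) * (self.order + 1)

    def interval_of(self, s: float) -> int:
        """Right-open interval lookup; the last interval is closed."""
        xi = self.knots.array
        if s < xi[0] or s > xi[-1]:
            raise ValueError(
                f"parameter {s} outside [{xi[0]}, {xi[-1]}]; "
                "extrapolation must be requested explicitly"
            )
        i = int(np.searchsorted(xi, s, side="right")) - 1
        return min(max(i, 0), len(xi) - 2)

    def __call__(self, s: float, extrapolate: bool = False) -> tuple[float, float, float]:
        xi = self.knots.array
        if extrapolate:
            i = 0 if s < xi[0] else min(
                int(np.searchsorted(xi, s, side="right")) - 1, len(xi) - 2
            )
            i = max(i, 0)
        else:
            i = self.interval_of(s)
        return tuple(float(self.pieces[d][i](s)) for d in DIRECTIONS)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# point ordering
# ---------------------------------------------------------------------------

def order_points(
    ds: ExtractionDataset,
    response: str,
    scheme: Literal["lexicographic", "serpentine"] = "lexicographic",
) -> np.ndarray:
    """Arrange the factorial cells as an (n, 3) array of (t, C, response) triples.

    ``lexicographic`` walks temperature blocks in ascending temperature with
    concentration ascending inside each block; ``serpentine`` alternates the
    concentration direction between consecutive temperature blocks (the
    boustrophedon path one would draw threading a grid without long jumps).
    """
    if response not in ds.responses:
        raise KeyError(f"response {response!r} not in dataset")
    if scheme not in ("lexicographic", "serpentine"):
        raise ValueError(f"unknown ordering scheme {scheme!r}")

    by_cond = {c: v.mean for c, v in zip(ds.conditions, ds.responses[response])}
    rows = []
    for bi, t in enumerate(ds.temperature_levels):
        concs = ds.concentration_levels
        if scheme == "serpentine" and bi % 2 == 1:
            concs = concs[::-1]
        for c in concs:
            rows.append((t, c, by_cond[Condition(t, c)]))
    return np.array(rows, dtype=float)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _parameter_values(points: np.ndarray, parameterization: str) -> np.ndarray:
    if parameterization == "index":
        return np.arange(len(points), dtype=float)
    if parameterization == "chord":
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("duplicate consecutive points give zero chord length")
        return np.concatenate([[0.0], np.cumsum(seg)])
    raise ValueError(f"unknown parameterization {parameterization!r}")


def _linear_pieces(s: np.ndarray, vals: np.ndarray) -> list[PolynomialPiece]:
    slopes = np.diff(vals) / np.diff(s)
    return [
        PolynomialPiece(i, float(s[i]), (float(slopes[i]), float(vals[i])))
        for i in range(len(s) - 1)
    ]


def fit_parametric_spline(
    points: np.ndarray | Sequence[Sequence[float]],
    k: int = 3,
    parameterization: Literal["index", "chord"] = "index",
    boundary: Literal["natural", "not_a_knot"] = "natural",
    ordering: str = "lexicographic",
) -> PiecewiseCurve:
    """Fit interpolating splines t(s), C(s), y(s) through ordered triples.

    Parameters
    ----------
    points
        (n, 3) ordered triples (t, C, response); n ≥ k + 1.
    k
        Spline order: 3 (cubic, default) or 1 (piecewise linear).
    parameterization
        ``index`` assigns ξ_i = 0 … n−1 (equally spaced, reproducible);
        ``chord`` uses cumulative Euclidean chord length.
    boundary
        End condition for the cubic: ``natural`` (zero second derivative,
        default) or ``not_a_knot``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    if k not in (1, 3):
        raise ValueError(f"spline order k must be 1 or 3, got {k}")
    n = len(pts)
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} points, got {n}")
    if boundary not in _BOUNDARY_MAP:
        raise ValueError(f"unknown boundary condition {boundary!r}")

    s = _parameter_values(pts, parameterization)
    pieces: dict[str, list[PolynomialPiece]] = {}
    for dim, name in enumerate(DIRECTIONS):
        vals = pts[:, dim]
        if k == 1:
            pieces[name] = _linear_pieces(s, vals)
        else:
            cs = CubicSpline(s, vals, bc_type=_BOUNDARY_MAP[boundary])
            # cs.c[m, i] multiplies (s − ξ_i)^(3−m): row 0 is c_1 (cubic term)
            pieces[name] = [
                PolynomialPiece(i, float(s[i]), tuple(float(c) for c in cs.c[:, i]))
                for i in range(n - 1)
            ]
    return PiecewiseCurve(
        knots=KnotSequence(tuple(float(v) for v in s)),
        order=k,
        pieces=pieces,
        boundary=boundary,
        parameterization=parameterization,
        ordering=ordering,
    )


def evaluate_curve(
    curve: PiecewiseCurve, s: float, extrapolate: bool = False
) -> tuple[float, float, float]:
    """Evaluate the (t, C, response) triple at parameter ``s``.

    Out-of-range ``s`` raises unless ``extrapolate=True``.
    """
    return curve(s, extrapolate=extrapolate)


# ---------------------------------------------------------------------------
# coefficient export / import
# ---------------------------------------------------------------------------

def export_coefficients(curve: PiecewiseCurve) -> pd.DataFrame:
    """Long-format coefficient table: (direction, interval, j, coefficient).

    ``interval`` is 1-based (i = 1 … n−1) and ``j`` runs 1 … k+1 with j = 1
    the highest-power coefficient, matching the local form
    Σ_j c_ji (s − ξ_i)^{k+1−j}.  Row count is (n−1) × 3 × (k+1).
    """
    rows = []
    for d in DIRECTIONS:
        for p in curve.pieces[d]:
            for j, c in enumerate(p.coefficients, start=1):
                rows.append(
                    {
                        "direction": d,
                        "interval": p.interval + 1,
                        "j": j,
                        "origin": p.origin,
                        "coefficient": c,
                    }
                )
    return pd.DataFrame(rows)


def import_coefficients(
    table: pd.DataFrame,
    knots: KnotSequence,
    order: int,
    **tags,
) -> PiecewiseCurve:
    """Rebuild a :class:`PiecewiseCurve` from an exported coefficient table."""
    pieces: dict[str, list[PolynomialPiece]] = {}
    for d, grp in table.groupby("direction", sort=False):
        plist = []
        for i, sub in grp.groupby("interval", sort=True):
            sub = sub.sort_values("j")
            plist.append(
                PolynomialPiece(
                    int(i) - 1,
                    float(sub["origin"].iloc[0]),
                    tuple(float(c) for c in sub["coefficient"]),
                )
            )
        pieces[str(d)] = plist
    return PiecewiseCurve(knots=knots, order=order, pieces=pieces, **tags)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _relative(err: np.ndarray, ref: np.ndarray) -> np.ndarray:
    # relative to the point magnitude, floored at 1 to stay meaningful near 0
    return np.abs(err) / np.maximum(np.abs(ref), 1.0)


def knot_residuals(curve: PiecewiseCurve, points: np.ndarray) -> np.ndarray:
    """(n, 3) signed residuals curve(ξ_i) − point_i across all directions."""
    pts = np.asarray(points, dtype=float)
    if len(pts) != curve.n_points:
        raise ValueError(
            f"curve has {curve.n_points} knots but {len(pts)} points supplied"
        )
    evals = np.array([curve(xi) for xi in curve.knots.values])
    return evals - pts


def max_relative_residual(curve: PiecewiseCurve, points: np.ndarray) -> float:
    """Max relative knot residual; ≤ 1e−9 for a correct interpolating fit."""
    pts = np.asarray(points, dtype=float)
    return float(_relative(knot_residuals(curve, pts), pts).max())


# ---------------------------------------------------------------------------
# model / results front-end
# ---------------------------------------------------------------------------

class SplineCurveModel:
    """Interpolating parametric curve model for one response of a dataset.

    Examples
    --------
    >>> from marcex import load_fixture, SplineCurveModel
    >>> res = SplineCurveModel(load_fixture("table1"), "TPC").fit()
    >>> res.curve.n_coefficients
    168
    """

    def __init__(
        self,
        dataset: ExtractionDataset,
        response: str,
        scheme: Literal["lexicographic", "serpentine"] = "lexicographic",
        k: int = 3,
        parameterization: Literal["index", "chord"] = "index",
        boundary: Literal["natural", "not_a_knot"] = "natural",
    ):
        self.dataset = dataset
        self.response = response
        self.scheme = scheme
        self.k = k
        self.parameterization = parameterization
        self.boundary = boundary
        self.points = order_points(dataset, response, scheme)

    def fit(self) -> "SplineCurveResults":
        curve = fit_parametric_spline(
            self.points,
            k=self.k,
            parameterization=self.parameterization,
            boundary=self.boundary,
            ordering=self.scheme,
        )
        return SplineCurveResults(self, curve)


@dataclass
class SplineCurveResults:
    """Fitted curve plus diagnostics and exports."""

    model: SplineCurveModel
    curve: PiecewiseCurve
    _coef: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> pd.DataFrame:
        if self._coef is None:
            self._coef = export_coefficients(self.curve)
        return self._coef

    @property
    def knot_residuals_(self) -> np.ndarray:
        return knot_residuals(self.curve, self.model.points)

    @property
    def max_relative_residual_(self) -> float:
        return max_relative_residual(self.curve, self.model.points)

    def predict(self, s: float | Sequence[float], extrapolate: bool = False) -> np.ndarray:
        svals = np.atleast_1d(np.asarray(s, dtype=float))
        return np.array([self.curve(v, extrapolate=extrapolate) for v in svals])

    def sample(self, points_per_interval: int = 100) -> pd.DataFrame:
        """Dense curve sampling (s, t, C, response) for plotting/refinement."""
        xi = self.curve.knots.array
        ss = np.unique(
            np.concatenate(
                [
                    np.linspace(xi[i], xi[i + 1], points_per_interval, endpoint=False)
                    for i in range(len(xi) - 1)
                ]
                + [xi[-1:]]
            )
        )
        vals = self.predict(ss)
        return pd.DataFrame(
            {"s": ss, "t": vals[:, 0], "C": vals[:, 1], "response": vals[:, 2]}
        )

    def summary(self) -> str:
        c = self.curve
        lines = [
            "Parametric spline curve fit",
            "===========================",
            f"response:          {self.model.response}",
            f"points (n):        {c.n_points}",
            f"order (k):         {c.order}",
            f"ordering:          {c.ordering}",
            f"parameterization:  {c.parameterization}",
            f"boundary:          {c.boundary}",
            f"intervals:         {c.n_points - 1}",
            f"coefficients:      {c.n_coefficients}  "
            f"((n-1) x 3 x (k+1) = {c.n_points - 1} x 3 x {c.order + 1})",
            f"max knot residual: {self.max_relative_residual_:.3e} (relative)",
        ]
        return "\n".join(lines)
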