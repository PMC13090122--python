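"""Non-deep age predictors: mean baseline, linear ASI model, spline GAM.

The mean baseline is the floor any informative model must beat: it predicts
the training-set mean age for every subject, so its fold-wise MAE measures
the raw dispersion of age in the cohort.  The two ASI-only models quantify
how much age signal a single explicitly defined vascular feature carries —
a univariate ordinary-least-squares line and a penalized cubic B-spline
smoother (GAM) whose roughness penalty is chosen by generalized
cross-validation on the training fold alone.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .base import AgeModel, AgeModelResults, FitError

__all__ = ["MeanAgeModel", "LinearAsiModel", "SplineGamModel"]


# ---------------------------------------------------------------------------
# Mean baseline
# ---------------------------------------------------------------------------

class MeanResults(AgeModelResults):
    kind = "mean"

    def predict(self, exog=None) -> np.ndarray:
        n = 1 if exog is None else np.asarray(exog).shape[0]
        return np.full(n, self.params["mean_age"])


class MeanAgeModel(AgeModel):
    """Predicts the training mean age for every subject."""

    input_kind = "none"

    def __init__(self, endog):
        super().__init__(endog, exog=None)

    def fit(self) -> MeanResults:
        return MeanResults(self, {"mean_age": float(np.mean(self.endog)),
                                  "n_train": self.endog.size})


# ---------------------------------------------------------------------------
# Univariate linear model
# ---------------------------------------------------------------------------

class LinearResults(AgeModelResults):
    kind = "linear"

    def predict(self, exog=None) -> np.ndarray:
        x = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return self.params["intercept"] + self.params["slope"] * x


class LinearAsiModel(AgeModel):
    """Ordinary least squares of age (years) on ASI (m/s)."""

    input_kind = "asi"

    def __init__(self, endog, asi):
        super().__init__(endog, exog=asi)
        if self.exog.shape != self.endog.shape:
            raise FitError("age and ASI arrays must align")
        if np.unique(self.exog).size < 2:
            raise FitError("ASI is constant: degenerate design")

    def fit(self) -> LinearResults:
        res = sm.OLS(self.endog, sm.add_constant(self.exog)).fit()
        return LinearResults(self, {
            "intercept": float(res.params[0]),
            "slope": float(res.params[1]),
            "intercept_se": float(res.bse[0]),
            "slope_se": float(res.bse[1]),
            "r_squared": float(res.rsquared),
            "n_train": self.endog.size,
        })


# ---------------------------------------------------------------------------
# Penalized B-spline GAM
# ---------------------------------------------------------------------------

def _bspline_knots(x: np.ndarray, n_knots: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector with interior knots at data quantiles."""
    interior = np.unique(np.quantile(x, np.linspace(0, 1, n_knots)[1:-1]))
    lo, hi = float(x.min()), float(x.max())
    interior = interior[(interior > lo) & (interior < hi)]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def _curvature_penalty(knots: np.ndarray, degree: int = 3,
                       n_grid: int = 201) -> np.ndarray:
    """Square-root factor D of the curvature penalty integral ∫ s''(x)² dx.

    D is the second-derivative design matrix on a fine grid, scaled by the
    quadrature weight; its null space is exactly the splines with zero second
    derivative, i.e. straight lines — so an infinite penalty reproduces the
    OLS fit regardless of knot placement.
    """
    lo, hi = knots[degree], knots[-degree - 1]
    grid = np.linspace(lo, hi, n_grid)
    n_coef = knots.size - degree - 1
    basis = BSpline.design_matrix(grid, knots, degree, extrapolate=False).toarray()
    # second derivative of each basis function via BSpline objects
    d2 = np.empty_like(basis)
    eye = np.eye(n_coef)
    for j in range(n_coef):
        d2[:, j] = BSpline(knots, eye[j], degree).derivative(2)(grid)
    h = (hi - lo) / (n_grid - 1)
    return d2 * np.sqrt(h)


class GamResults(AgeModelResults):
    kind = "gam"

    def predict(self, exog=None) -> np.ndarray:
        x = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        knots = self.params["knots"]
        degree = self.params["degree"]
        # constant extrapolation outside the training range
        xc = np.clip(x, knots[degree], knots[-degree - 1])
        B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
        return B @ self.params["coef"]


class SplineGamModel(AgeModel):
    """Penalized cubic B-spline regression of age on ASI.

    20 knots at training quantiles, a curvature (integrated squared second
    derivative) penalty, and GCV selection of the smoothing parameter over a
    log-spaced grid.  Inputs outside the training range are clamped, i.e. the
    fit extrapolates as a constant.
    """

    input_kind = "asi"

    def __init__(self, endog, asi, n_knots: int = 20, degree: int = 3):
        super().__init__(endog, exog=asi)
        if self.exog.shape != self.endog.shape:
            raise FitError("age and ASI arrays must align")
        if self.endog.size < 10 or np.unique(self.exog).size < 4:
            raise FitError("need >= 10 points spanning >= 4 distinct ASI values")
        self.n_knots = n_knots
        self.degree = degree

    def _design(self):
        knots = _bspline_knots(self.exog, self.n_knots, self.degree)
        B = BSpline.design_matrix(self.exog, knots, self.degree,
                                  extrapolate=False).toarray()
        D = _curvature_penalty(knots, self.degree)
        return knots, B, D

    @staticmethod
    def _solve(B, D, y, lam):
        n_coef = B.shape[1]
        A = np.vstack([B, np.sqrt(lam) * D])
        rhs = np.r_[y, np.zeros(D.shape[0])]
        coef, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        return coef

    @staticmethod
    def _gcv(B, D, y, lam):
        """Generalized cross-validation score n·RSS / (n − tr H)²."""
        n = y.size
        BtB = B.T @ B
        M = BtB + lam * (D.T @ D)
        coef = np.linalg.solve(M, B.T @ y)
        fitted = B @ coef
        # tr(B M^-1 B') == tr(M^-1 B'B): stay in coefficient space
        edf = float(np.trace(np.linalg.solve(M, BtB)))
        rss = float(np.sum((y - fitted) ** 2))
        denom = max(n - edf, 1e-8)
        return n * rss / denom ** 2, edf

    def fit(self, smoothing="gcv", lam_grid=None) -> GamResults:
        """Fit the smoother.

        ``smoothing`` is either "gcv" (default) or a fixed non-negative
        penalty weight.
        """
        knots, B, D = self._design()
        y = self.endog
        if smoothing == "gcv":
            if lam_grid is None:
                lam_grid = np.logspace(-3, 8, 23)
            scores = [self._gcv(B, D, y, lam)[0] for lam in lam_grid]
            lam = float(lam_grid[int(np.argmin(scores))])
        else:
            lam = float(smoothing)
            if lam < 0:
                raise FitError("smoothing penalty must be >= 0")
        coef = self._solve(B, D, y, lam)
        _, edf = self._gcv(B, D, y, lam)
        return GamResults(self, {
            "coef": coef, "knots": knots, "degree": self.degree,
            "lambda": lam, "edf": edf, "n_train": y.size,
        })
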