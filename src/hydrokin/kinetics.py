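"""Arrhenius and deformed (super-)Arrhenius fitting of temperature-indexed series.

The temperature dependence of a rate constant k or a self-diffusion
coefficient D is modelled on the log scale as a polynomial in x = 1/(RT):

    ln v(T) = ln_pre + B*x + C*x**2

With C = 0 this is the classical Arrhenius law (constant activation energy
Ea = -B).  A nonzero quadratic coefficient C makes the activation energy
temperature dependent,

    Ea(T) = -d ln v / dx = -B - 2*C/(R*T),

so C < 0 gives an Ea that decreases with increasing temperature
(super-Arrhenius: the trapped population diffuses over progressively
smaller effective barriers as thermal energy grows), while C > 0 gives
the sub-Arrhenius case.  Fits are unweighted ordinary least squares on
the ln scale; energies are J/mol internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import R_GAS
from .errors import DomainError, InsufficientDataError, SingularDesignError

__all__ = [
    "RateSeries",
    "SuperArrheniusFit",
    "ModelComparison",
    "fit_arrhenius",
    "fit_super_arrhenius",
    "activation_energy",
    "classify_arrhenius",
    "predict",
    "compare_models",
]


@dataclass(frozen=True)
class RateSeries:
    """Temperature-indexed positive rate constants or diffusion coefficients.

    Temperatures are absolute (K) and canonicalized to strictly ascending
    order on construction; exact duplicate temperatures are rejected.
    Values must be strictly positive (the models live on the ln scale).
    """

    temperatures: np.ndarray
    values: np.ndarray
    value_kind: str = "rate"  # "rate" | "diffusion"
    label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if T.ndim != 1 or v.ndim != 1 or T.size != v.size:
            raise DomainError("temperatures and values must be 1-D and equal length")
        if T.size < 2:
            raise InsufficientDataError(
                f"need at least 2 points, got {T.size}"
            )
        if np.any(T <= 0):
            raise DomainError("temperatures must be strictly positive (K)")
        order = np.argsort(T, kind="stable")
        T, v = T[order], v[order]
        if np.any(np.diff(T) == 0):
            dup = T[np.flatnonzero(np.diff(T) == 0)[0]]
            raise DomainError(f"duplicate temperature {dup} K")
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise DomainError(
                f"non-positive value at T = {T[bad[0]]} K (logarithm undefined)"
            )
        if self.value_kind not in ("rate", "diffusion"):
            raise DomainError(f"unknown value_kind {self.value_kind!r}")
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.temperatures.size)


@dataclass(frozen=True)
class SuperArrheniusFit:
    """Result of fitting ln v = ln_pre + B/(RT) + C/(RT)^2.

    ``ln_pre`` is dimensionless (ln A or ln D0), ``B`` is J/mol and ``C``
    J^2/mol^2.  ``covariance`` is the 3x3 OLS parameter covariance in the
    (ln_pre, B, C) ordering; an Arrhenius fit carries exact zeros in the
    C row/column.  ``r_squared`` is computed on the ln scale.
    """

    ln_pre: float
    B: float
    C: float
    r_squared: float
    covariance: np.ndarray = field(repr=False)
    value_kind: str = "rate"
    n_points: int = 0
    rss: float = 0.0

    @property
    def stderr(self) -> np.ndarray:
        """Standard errors of (ln_pre, B, C)."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def stderr_C(self) -> float:
        return float(self.stderr[2])


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side Arrhenius vs deformed-Arrhenius fit of one series."""

    arrhenius: SuperArrheniusFit
    super_arrhenius: SuperArrheniusFit
    rss_arrhenius: float
    rss_super: float
    preferred: str  # "arrhenius" | "super_arrhenius"


def _ln_design(series: RateSeries, degree: int) -> tuple[np.ndarray, np.ndarray]:
    x = 1.0 / (R_GAS * series.temperatures)
    X = np.vander(x, degree + 1, increasing=True)
    return X, np.log(series.values)


def _ols(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Column-scaled (optionally weighted) least squares.

    Returns (coef, covariance, r_squared, rss).  Covariance is
    s^2 (X'X)^-1 with s^2 = RSS/(n-p); for a saturated fit (n == p) it
    is identically zero and r_squared is 1.  Weights, when given, are
    per-point and applied on the ln scale (rows scaled by sqrt(w)).
    """
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w <= 0):
            raise DomainError("weights must be positive, one per point")
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
    n, p = X.shape
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    if np.linalg.matrix_rank(Xs) < p:
        raise SingularDesignError("design matrix is rank deficient")
    coef_s, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
    coef = coef_s / scale
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if n > p:
        s2 = rss / (n - p)
        cov = s2 * np.linalg.inv(Xs.T @ Xs) / np.outer(scale, scale)
    else:
        cov = np.zeros((p, p))
    if tss > 0:
        r2 = float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    else:
        r2 = 1.0  # constant data perfectly reproduced by the intercept
    return coef, cov, r2, rss


def fit_arrhenius(
    series: RateSeries, weights: np.ndarray | None = None
) -> SuperArrheniusFit:
    """Ordinary least squares of ln(value) on 1/(RT); returns C = 0 exactly.

    -B is the (constant) activation energy in J/mol.  The fit is
    unweighted unless per-point ``weights`` are passed explicitly.
    """
    if len(series) < 2:
        raise InsufficientDataError("Arrhenius fit needs >= 2 points")
    X, y = _ln_design(series, 1)
    coef, cov, r2, rss = _ols(X, y, weights)
    cov3 = np.zeros((3, 3))
    cov3[:2, :2] = cov
    return SuperArrheniusFit(
        ln_pre=float(coef[0]), B=float(coef[1]), C=0.0,
        r_squared=r2, covariance=cov3, value_kind=series.value_kind,
        n_points=len(series), rss=rss,
    )


def fit_super_arrhenius(
    series: RateSeries, weights: np.ndarray | None = None
) -> SuperArrheniusFit:
    """OLS of ln(value) on {1, 1/RT, 1/(RT)^2}; unweighted by default.

    With exactly 3 distinct temperatures the quadratic interpolates the
    points (r_squared = 1, zero covariance).
    """
    if len(series) < 3:
        raise InsufficientDataError("deformed-Arrhenius fit needs >= 3 points")
    X, y = _ln_design(series, 2)
    coef, cov, r2, rss = _ols(X, y, weights)
    return SuperArrheniusFit(
        ln_pre=float(coef[0]), B=float(coef[1]), C=float(coef[2]),
        r_squared=r2, covariance=cov, value_kind=series.value_kind,
        n_points=len(series), rss=rss,
    )


def activation_energy(fit: SuperArrheniusFit, T: float) -> float:
    """Temperature-dependent activation energy Ea(T) = -B - 2C/(RT), J/mol.

    Divide by 1000 at the presentation layer for kJ/mol.
    """
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T}")
    return -fit.B - 2.0 * fit.C / (R_GAS * T)


def classify_arrhenius(fit: SuperArrheniusFit, tolerance: float | None = None) -> str:
    """Classify the curvature sign: 'super', 'sub' or 'arrhenius'.

    C < -tolerance means super-Arrhenius (Ea decreasing with T); C >
    +tolerance sub-Arrhenius; otherwise plain Arrhenius.  The default
    tolerance is the fitted standard error of C, so curvature smaller
    than its own uncertainty is not over-interpreted.
    """
    if tolerance is None:
        tolerance = fit.stderr_C
    if tolerance < 0:
        raise DomainError("tolerance must be non-negative")
    if fit.C < -tolerance:
        return "super"
    if fit.C > tolerance:
        return "sub"
    return "arrhenius"


def predict(fit: SuperArrheniusFit, T) -> np.ndarray | float:
    """Evaluate the fitted law: exp(ln_pre + B/(RT) + C/(RT)^2)."""
    Ta = np.asarray(T, dtype=float)
    if np.any(Ta <= 0):
        raise DomainError("temperature must be positive")
    x = 1.0 / (R_GAS * Ta)
    out = np.exp(fit.ln_pre + fit.B * x + fit.C * x * x)
    return float(out) if np.isscalar(T) else out


def compare_models(series: RateSeries) -> ModelComparison:
    """Fit both laws and prefer by adjusted R^2 on the ln scale.

    Requires >= 4 points so the quadratic model is not saturated.  Ties
    (including both models exact) resolve to the simpler Arrhenius law.
    """
    if len(series) < 4:
        raise InsufficientDataError("model comparison needs >= 4 points")
    lin = fit_arrhenius(series)
    quad = fit_super_arrhenius(series)
    n = len(series)

    def adj_r2(fit: SuperArrheniusFit, p: int) -> float:
        return 1.0 - (1.0 - fit.r_squared) * (n - 1) / (n - p)

    prefer_quad = adj_r2(quad, 3) > adj_r2(lin, 2) + 1e-12
    return ModelComparison(
        arrhenius=lin, super_arrhenius=quad,
        rss_arrhenius=lin.rss, rss_super=quad.rss,
        preferred="super_arrhenius" if prefer_quad else "arrhenius",
    )


def constrain_to_arrhenius(fit: SuperArrheniusFit) -> SuperArrheniusFit:
    """Drop the quadratic term, keeping metadata (used by reports)."""
    return replace(fit, C=0.0)
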