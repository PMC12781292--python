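"""Restricted-cubic-spline dose-response regression and sample-size tools.

Moral distress (MD) is regressed on a 4-knot restricted cubic spline of
compassion fatigue (CF), optionally adjusting for dummy-coded categorical
covariates (Model 2).  With k knots the spline contributes k-1 regressors:
the raw predictor plus k-2 truncated-power terms that are constrained to be
linear beyond the boundary knots.  Nonlinearity is judged by a joint F-test
of the nonlinear coefficients; the overall effect is summarised by the
interquartile contrast of predicted MD with a Wald (z) confidence interval.

Also implemented here: the a-priori power machinery — the noncentral-F
minimum sample size for a multiple regression F-test, and the
participants-per-node heuristic with attrition inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

# Harrell's default knot quantiles by knot count.
DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def default_knots(x, k: int = 4) -> np.ndarray:
    """Knot locations at the default quantiles of the predictor sample."""
    x = np.asarray(x, dtype=float)
    if k not in DEFAULT_KNOT_QUANTILES:
        raise ValueError(f"supported knot counts: {sorted(DEFAULT_KNOT_QUANTILES)}")
    if np.unique(x).size < max(k, 4):
        raise ValueError(f"need at least {max(k, 4)} distinct predictor values")
    knots = np.quantile(x, DEFAULT_KNOT_QUANTILES[k])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "ties collapse the default quantile knots; supply knots manually"
        )
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form).

    Returns an n x (k-1) array: column 0 is x itself, columns 1..k-2 are the
    nonlinear terms, each scaled by (t_k - t_1)^2 so coefficients are on a
    comparable scale.  The nonlinear terms vanish for x <= t_1 and the
    function is linear beyond t_k.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("predictor values must be finite")
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("knots must be >= 3 strictly increasing values")
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.where(u > 0, u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class SplineModelFit:
    """A fitted RCS regression with everything needed for reporting."""

    results: sm.regression.linear_model.RegressionResultsWrapper
    knots: np.ndarray
    exposure: str
    outcome: str
    spline_names: list[str]
    covariate_names: list[str] = field(default_factory=list)
    x: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        return self.results.params

    @property
    def bse(self) -> pd.Series:
        return self.results.bse

    @property
    def rsquared(self) -> float:
        return float(self.results.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self.results.rsquared_adj)

    def summary_dict(self) -> dict:
        nl = nonlinearity_test(self)
        eff = total_effect(self)
        return {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "knots": self.knots.tolist(),
            "coefficients": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "r_squared": self.rsquared,
            "adj_r_squared": self.rsquared_adj,
            "nonlinearity_F": nl[0],
            "nonlinearity_p": nl[1],
            "total_effect": {"estimate": eff[0], "se": eff[1], "ci": list(eff[2])},
        }


def _spline_design(x, knots, exposure) -> pd.DataFrame:
    basis = rcs_basis(x, knots)
    names = [exposure] + [f"{exposure}_nl{j + 1}" for j in range(basis.shape[1] - 1)]
    return pd.DataFrame(basis, columns=names)


def fit_rcs_model(
    md,
    cf,
    covariates: pd.DataFrame | None = None,
    knots=None,
    exposure: str = "cf_total",
    outcome: str = "md_total",
) -> SplineModelFit:
    """OLS of the outcome on the RCS basis of the exposure (+ covariates).

    Categorical covariates are dummy-coded with the first category as
    reference (Model 2); pass ``covariates=None`` for the unadjusted Model 1.
    """
    md = np.asarray(md, dtype=float)
    cf = np.asarray(cf, dtype=float)
    knots = default_knots(cf) if knots is None else np.asarray(knots, dtype=float)
    design = _spline_design(cf, knots, exposure)
    cov_names: list[str] = []
    if covariates is not None and len(covariates.columns):
        dummies = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True, dtype=float)
        cov_names = list(dummies.columns)
        design = pd.concat([design, dummies], axis=1)
    X = sm.add_constant(design, has_constant="add")
    if len(md) <= X.shape[1]:
        raise ValueError(f"need more observations ({len(md)}) than parameters ({X.shape[1]})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X.to_numpy())
        dep = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")
    results = sm.OLS(md, X).fit()
    return SplineModelFit(
        results=results,
        knots=knots,
        exposure=exposure,
        outcome=outcome,
        spline_names=list(design.columns[: knots.size - 1]),
        covariate_names=cov_names,
        x=cf,
    )


def nonlinearity_test(fit: SplineModelFit) -> tuple[float, float]:
    """Joint F-test that all nonlinear spline coefficients are zero."""
    nl_names = fit.spline_names[1:]
    if not nl_names:
        raise ValueError("fit has no nonlinear spline terms to test")
    R = np.zeros((len(nl_names), len(fit.params)))
    cols = list(fit.params.index)
    for r, name in enumerate(nl_names):
        R[r, cols.index(name)] = 1.0
    test = fit.results.f_test(R)
    return float(test.fvalue), float(test.pvalue)


def wald_ci(estimate: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-quantile Wald interval: estimate +/- z * SE."""
    return estimate - z * se, estimate + z * se


def total_effect(
    fit: SplineModelFit, q_low: float = 0.25, q_high: float = 0.75, z: float = 1.96
) -> tuple[float, float, tuple[float, float]]:
    """Predicted-MD contrast between the q_high and q_low exposure quantiles.

    Covariates are held at reference (all dummies zero), so they cancel in
    the difference; the SE follows from the coefficient covariance by the
    delta method, and the CI is estimate +/- z * SE.
    """
    if q_low > q_high:
        raise ValueError("q_low must not exceed q_high")
    if fit.x is None:
        raise ValueError("fit does not retain the exposure sample")
    lo, hi = np.quantile(fit.x, [q_low, q_high])
    b_lo = rcs_basis(np.array([lo]), fit.knots)[0]
    b_hi = rcs_basis(np.array([hi]), fit.knots)[0]
    contrast = np.zeros(len(fit.params))
    cols = list(fit.params.index)
    for j, name in enumerate(fit.spline_names):
        contrast[cols.index(name)] = b_hi[j] - b_lo[j]
    est = float(contrast @ fit.params.to_numpy())
    se = float(np.sqrt(contrast @ fit.results.cov_params().to_numpy() @ contrast))
    return est, se, wald_ci(est, se, z)


def standardized_fit(md, cf, knots=None) -> SplineModelFit:
    """Model 1 on z-scored outcome and exposure (standardised coefficients)."""
    md = np.asarray(md, dtype=float)
    cf = np.asarray(cf, dtype=float)
    if md.std(ddof=1) == 0 or cf.std(ddof=1) == 0:
        raise ValueError("zero-variance input cannot be standardised")
    md_z = (md - md.mean()) / md.std(ddof=1)
    cf_z = (cf - cf.mean()) / cf.std(ddof=1)
    return fit_rcs_model(md_z, cf_z, knots=knots, exposure="cf_z", outcome="md_z")


def predict_curve(fit: SplineModelFit, grid, z: float = 1.96) -> pd.DataFrame:
    """Fitted mean MD and pointwise Wald band over an exposure grid.

    Covariates (if any) are held at the reference category.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    basis = rcs_basis(grid, fit.knots)
    X = np.zeros((grid.size, len(fit.params)))
    cols = list(fit.params.index)
    X[:, cols.index("const")] = 1.0
    for j, name in enumerate(fit.spline_names):
        X[:, cols.index(name)] = basis[:, j]
    mean = X @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.results.cov_params().to_numpy(), X))
    return pd.DataFrame(
        {
            fit.exposure: grid,
            "fit": mean,
            "se": se,
            "ci_low": mean - z * se,
            "ci_high": mean + z * se,
        }
    )


@dataclass
class PowerSpec:
    """A-priori power settings for the overall regression F-test."""

    f2: float = 0.10
    alpha: float = 0.05
    power: float = 0.95
    n_predictors: int = 10

    def __post_init__(self):
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")


def regression_power(n: int, spec: PowerSpec) -> float:
    """Power of the overall F-test at sample size n (lambda = f2 * n)."""
    p = spec.n_predictors
    df2 = n - p - 1
    if df2 < 1:
        return 0.0
    fcrit = stats.f.ppf(1 - spec.alpha, p, df2)
    return float(stats.ncf.sf(fcrit, p, df2, spec.f2 * n))


def required_sample_size_f2(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n whose noncentral-F power reaches the target."""
    n = spec.n_predictors + 2
    while n <= n_max:
        if regression_power(n, spec) >= spec.power:
            return n
        n += 1
    raise ValueError(f"target power not attainable below n = {n_max}")


def heuristic_network_n(
    n_nodes: int, per_node: int = 10, attrition: float = 0.10
) -> tuple[int, int]:
    """Participants-per-node heuristic with attrition inflation.

    Returns (minimum, target): minimum = nodes x per-node; target inflates
    the minimum so that after the anticipated attrition fraction the minimum
    is still met.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= attrition < 1:
        raise ValueError("attrition must be in [0, 1)")
    minimum = n_nodes * per_node
    target = math.ceil(minimum / (1 - attrition))
    return minimum, target


def describe_continuous(x, name: str = "value") -> dict:
    """Median/IQR/range plus a Shapiro-Wilk normality check (reporting only)."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    w, p = stats.shapiro(x) if 3 <= x.size <= 5000 else stats.shapiro(x[:5000])
    return {
        "variable": name,
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(x.min()),
        "max": float(x.max()),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
    }
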