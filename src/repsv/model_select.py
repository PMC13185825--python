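"""Curve fitting over a fixed family of nine candidate models with AIC/BIC selection.

Seven models are linear in their parameters and are solved by ordinary least
squares on transformed regressors; Exponential (``y = a·e^{bx}``) and Power
(``y = a·x^b``) are fitted by Levenberg–Marquardt least squares
(:func:`scipy.optimize.curve_fit`) started from a log-linearisation of the
data.  All models are scored on the same residual-sum-of-squares
approximations so they are comparable:

    R²  = 1 − SS_res/SS_tot
    AIC = n·ln(SS_res/n) + 2k
    BIC = n·ln(SS_res/n) + k·ln n

The model with the smallest AIC wins; ties fall back to BIC, then to fewer
parameters, then to the model name.  ``ConstantAndLogarithmic`` and
``InverseAndConstant`` are retained for fidelity to the candidate list even
though they are re-parameterisations of ``Logarithmic`` and ``Inverse``;
:func:`equivalent_models` exposes the resulting equivalence classes.

95% confidence bands use the delta method: ``se(x)² = J(x)ᵀ Cov J(x)`` with
``J`` the gradient of the model in its parameters, and t quantiles at
``n − k`` degrees of freedom.  Bands are restricted to the observed x-range;
no extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class ModelSpec:
    name: str
    param_names: tuple
    linear: bool
    positive_x: bool  # requires x > 0
    func: callable        # func(x, *params) -> y
    design: callable      # design(x) -> (n, k) regressor matrix incl. constant column
    jac: callable         # jac(x, params) -> (n, k) d f / d params

    @property
    def k(self) -> int:
        return len(self.param_names)


def _spec(name, params, positive_x, func, design, jac=None, linear=True):
    if jac is None:
        jac = lambda x, p, d=design: d(np.asarray(x, float))
    return ModelSpec(name, tuple(params), linear, positive_x, func, design, jac)


def _col(*cols):
    return np.column_stack(cols)


def _ones(x):
    return np.ones_like(np.asarray(x, float))


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _spec("Linear", "ab", False,
              lambda x, a, b: a + b * x,
              lambda x: _col(_ones(x), x)),
        _spec("Inverse", "ab", True,
              lambda x, a, b: a + b / x,
              lambda x: _col(_ones(x), 1.0 / x)),
        _spec("Logarithmic", "ab", True,
              lambda x, a, b: a + b * np.log(x),
              lambda x: _col(_ones(x), np.log(x))),
        _spec("Quadratic", "abc", False,
              lambda x, a, b, c: a + b * x + c * x**2,
              lambda x: _col(_ones(x), x, x**2)),
        _spec("InverseAndLinear", "abc", True,
              lambda x, a, b, c: a + b / x + c * x,
              lambda x: _col(_ones(x), 1.0 / x, x)),
        _spec("ConstantAndLogarithmic", "ab", True,
              lambda x, a, b: a + b * np.log(x),
              lambda x: _col(_ones(x), np.log(x))),
        _spec("InverseAndConstant", "ab", True,
              lambda x, a, b: a + b / x,
              lambda x: _col(_ones(x), 1.0 / x)),
        ModelSpec("Exponential", ("a", "b"), False, False,
                  lambda x, a, b: a * np.exp(b * x),
                  lambda x: None,
                  lambda x, p: _col(np.exp(p[1] * x), p[0] * x * np.exp(p[1] * x))),
        ModelSpec("Power", ("a", "b"), False, True,
                  lambda x, a, b: a * np.power(x, b),
                  lambda x: None,
                  lambda x, p: _col(np.power(x, p[1]),
                                    p[0] * np.power(x, p[1]) * np.log(x))),
    ]
}

#: models that re-parameterise the same curve family
_ALIASES = [
    {"Inverse", "InverseAndConstant"},
    {"Logarithmic", "ConstantAndLogarithmic"},
]


def equivalent_models(name: str) -> frozenset:
    for group in _ALIASES:
        if name in group:
            return frozenset(group)
    return frozenset([name])


def nesting_models(name: str) -> frozenset:
    """Candidate models able to represent ``name``'s curve family exactly."""
    nests = {
        "Linear": {"Linear", "Quadratic", "InverseAndLinear"},
        "Inverse": {"Inverse", "InverseAndConstant", "InverseAndLinear"},
        "InverseAndConstant": {"Inverse", "InverseAndConstant", "InverseAndLinear"},
        "Logarithmic": {"Logarithmic", "ConstantAndLogarithmic"},
        "ConstantAndLogarithmic": {"Logarithmic", "ConstantAndLogarithmic"},
    }
    return frozenset(nests.get(name, {name}))


def transform_data(x, model: str | ModelSpec) -> np.ndarray:
    """Design columns (including the constant column) for a linear-in-parameters model."""
    spec = MODELS[model] if isinstance(model, str) else model
    x = np.asarray(x, dtype=float)
    if spec.positive_x:
        bad = np.flatnonzero(~(x > 0))
        if bad.size:
            raise ValueError(
                f"{spec.name} requires x > 0; offending indices: {bad.tolist()}"
            )
    if not spec.linear:
        raise ValueError(f"{spec.name} has no linear design matrix")
    return spec.design(x)


@dataclass
class GoodnessOfFit:
    n: int
    k: int
    ss_res: float
    ss_tot: float
    r2: float
    aic: float
    bic: float


def _gof(n, k, ss_res, ss_tot) -> GoodnessOfFit:
    # a constant response carries no variance to explain: report R^2 = 0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-12 else 0.0
    # guard ln(0) for exact fits: floor SS_res at eps·SS_tot (exact fits still rank first)
    floor = max(_EPS * ss_tot, np.finfo(float).tiny)
    ss = max(ss_res, floor)
    aic = n * np.log(ss / n) + 2 * k
    bic = n * np.log(ss / n) + k * np.log(n)
    return GoodnessOfFit(n, k, ss_res, ss_tot, r2, aic, bic)


@dataclass
class ModelFitResult:
    spec: ModelSpec
    params: np.ndarray
    cov: np.ndarray
    gof: GoodnessOfFit
    x_range: tuple
    converged: bool = True
    message: str = ""

    @property
    def name(self):
        return self.spec.name

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.spec.func(x, *self.params)


def _initial_guess(spec: ModelSpec, x, y):
    pos = y > 0
    if pos.sum() < 2:
        raise ValueError(f"{spec.name}: log-linearisation needs >= 2 positive y values")
    ly = np.log(y[pos])
    if spec.name == "Exponential":
        b, la = np.polyfit(x[pos], ly, 1)
    else:  # Power
        b, la = np.polyfit(np.log(x[pos]), ly, 1)
    return np.array([np.exp(la), b])


def fit_model(x, y, model: str | ModelSpec) -> ModelFitResult:
    """Fit one candidate model; linear forms by OLS, Exponential/Power by curve_fit."""
    spec = MODELS[model] if isinstance(model, str) else model
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite data")
    n = len(x)
    if n <= spec.k:
        raise ValueError(f"need n > k = {spec.k} points")
    if spec.positive_x and np.any(x <= 0):
        bad = np.flatnonzero(x <= 0)
        raise ValueError(f"{spec.name} requires x > 0; offending indices: {bad.tolist()}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    if spec.linear:
        X = spec.design(x)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        sigma2 = ss_res / (n - spec.k)
        xtx_inv = np.linalg.pinv(X.T @ X)
        cov = sigma2 * xtx_inv
        return ModelFitResult(spec, beta, cov, _gof(n, spec.k, ss_res, ss_tot),
                              (float(x.min()), float(x.max())))
    try:
        p0 = _initial_guess(spec, x, y)
        popt, pcov = optimize.curve_fit(spec.func, x, y, p0=p0, maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        logger.warning("%s fit failed: %s", spec.name, exc)
        return ModelFitResult(spec, np.full(spec.k, np.nan), np.full((spec.k, spec.k), np.nan),
                              _gof(n, spec.k, ss_tot, ss_tot),
                              (float(x.min()), float(x.max())),
                              converged=False, message=str(exc))
    resid = y - spec.func(x, *popt)
    ss_res = float(resid @ resid)
    return ModelFitResult(spec, popt, pcov, _gof(n, spec.k, ss_res, ss_tot),
                          (float(x.min()), float(x.max())))


def fit_all(x, y, models=None) -> list[ModelFitResult]:
    """Fit every applicable candidate model; domain-incompatible ones are skipped."""
    names = list(models) if models is not None else list(MODELS)
    fits = []
    for name in names:
        spec = MODELS[name]
        if spec.positive_x and np.any(np.asarray(x, float) <= 0):
            logger.info("skipping %s: x <= 0 present", name)
            continue
        try:
            fits.append(fit_model(x, y, spec))
        except ValueError as exc:
            logger.warning("skipping %s: %s", name, exc)
    return fits


def select_best(fits):
    """Rank converged fits by (AIC, BIC, k, name); return (best, ranking table)."""
    import pandas as pd

    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    ranked = sorted(ok, key=lambda f: (f.gof.aic, f.gof.bic, f.gof.k, f.name))
    table = pd.DataFrame(
        {
            "model": [f.name for f in ranked],
            "k": [f.gof.k for f in ranked],
            "ss_res": [f.gof.ss_res for f in ranked],
            "r2": [f.gof.r2 for f in ranked],
            "aic": [f.gof.aic for f in ranked],
            "bic": [f.gof.bic for f in ranked],
        }
    )
    return ranked[0], table


def confidence_band(fit: ModelFitResult, x_grid, level: float = 0.95):
    """Pointwise mean-response confidence band on the observed x-range."""
    if not fit.converged:
        raise ValueError("cannot compute a band for a non-converged fit")
    x_grid = np.asarray(x_grid, dtype=float)
    lo, hi = fit.x_range
    if np.any(x_grid < lo) or np.any(x_grid > hi):
        raise ValueError(f"x_grid outside observed range [{lo}, {hi}]: no extrapolation")
    J = fit.spec.jac(x_grid, fit.params) if not fit.spec.linear else fit.spec.design(x_grid)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", J, fit.cov, J), 0.0))
    tq = stats.t.ppf(0.5 + level / 2, fit.gof.n - fit.gof.k)
    yhat = fit.predict(x_grid)
    return yhat - tq * se, yhat + tq * se
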