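"""Parametric lactation-curve models and their closed-form features.

Three classical models of daily milk yield ``y`` as a function of days in
milk ``t`` are implemented:

* Wood (incomplete gamma):      ``y = a * t**b * exp(-c*t)``
* Wilmink (exponential+linear): ``y = a + b*exp(-k*t) + c*t``
* Dijkstra (mechanistic):       ``y = a * exp(b*(1 - exp(-c*t))/c - d*t)``

Sign conventions follow the standard parameterizations: all parameters are
strictly positive except Wilmink's ``b`` and ``c``, which are strictly
negative (an initial deficit that decays away, and a linear late-lactation
decline).

For the Wood and Dijkstra models the peak of the curve and the persistency
(relative rate of decline halfway between the peak and the end of
lactation) have closed forms; :func:`wood_features` and
:func:`dijkstra_features` evaluate them and flag parameter regimes where no
interior peak exists. Wilmink features are deliberately not provided: the
model's peak has no comparably simple closed form and the fitted curve is
used only for fit-error comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "MODEL_PARAM_NAMES",
    "ConstraintError",
    "LCParams",
    "LCFeatures",
    "eval_model",
    "fit_model",
    "wood_features",
    "dijkstra_features",
]

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "wood": ("a", "b", "c"),
    "wilmink": ("a", "b", "c", "k"),
    "dijkstra": ("a", "b", "c", "d"),
}

_EPS = 1e-8  # open sign constraints are implemented as closed bounds at +/-_EPS


class ConstraintError(ValueError):
    """Raised when a parameter vector violates a model's sign constraints."""


@dataclass
class LCParams:
    """A fitted (or supplied) lactation-curve parameter set.

    Attributes
    ----------
    model : str
        One of ``"wood"``, ``"wilmink"``, ``"dijkstra"``.
    params : np.ndarray
        Ordered parameter vector (see :data:`MODEL_PARAM_NAMES`).
    se : np.ndarray
        Asymptotic standard errors, ``sqrt(diag(sigma2 * (J'J)^-1))``.
    converged : bool
        False when the solver stalled or any parameter sits on a sign bound
        (the degenerate "flat curve" regime); the parameters are still
        reported as-is.
    residual_rmse : float
        Root-mean-square residual of the fit, in litres.
    """

    model: str
    params: np.ndarray
    se: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    residual_rmse: float = float("nan")

    def curve(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the fitted model on a DIM grid."""
        return eval_model(self.model, self.params, t)


@dataclass
class LCFeatures:
    """Closed-form curve features: peak and persistency.

    ``persistency`` is the relative rate of decline (per day, negative for
    a declining curve) evaluated at ``t_h = (peak_dim + tf)/2``, halfway
    between the peak and the end of lactation ``tf``. When the parameter
    regime admits no interior peak, ``computable`` is False and ``reason``
    explains why; the numeric fields are then NaN.
    """

    model: str
    peak_yield: float
    peak_dim: float
    persistency: float
    tf: float
    computable: bool
    reason: str = ""


def _validate_params(model: str, params: np.ndarray) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    names = MODEL_PARAM_NAMES.get(model)
    if names is None:
        raise ValueError(f"unknown model {model!r}")
    if params.shape != (len(names),):
        raise ValueError(
            f"{model} expects {len(names)} parameters {names}, got shape {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise ConstraintError(f"{model} parameters must be finite, got {params}")
    if model == "wilmink":
        a, b, c, k = params
        ok = a > 0 and k > 0 and b < 0 and c < 0
    else:
        ok = bool(np.all(params > 0))
    if not ok:
        raise ConstraintError(
            f"{model} parameter signs violated: "
            + ", ".join(f"{n}={v:g}" for n, v in zip(names, params))
        )
    return params


def eval_model(model: str, params, t) -> np.ndarray:
    """Evaluate a lactation-curve model at days-in-milk ``t`` (vectorized).

    ``t`` must be >= 0 (strictly > 0 for Wood, whose power term is
    undefined at 0). Raises :class:`ConstraintError` on sign violations.
    """
    params = _validate_params(model, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("days in milk must be non-negative")
    if model == "wood":
        if np.any(t == 0):
            raise ValueError("Wood model requires t > 0")
        a, b, c = params
        return a * t**b * np.exp(-c * t)
    if model == "wilmink":
        a, b, c, k = params
        return a + b * np.exp(-k * t) + c * t
    a, b, c, d = params
    return a * np.exp(b * (1.0 - np.exp(-c * t)) / c - d * t)


def _default_init(model: str, curve: np.ndarray) -> np.ndarray:
    if model == "wood":
        return np.array([max(float(np.mean(curve)), 1.0), 0.2, 0.003])
    if model == "wilmink":
        return np.array([max(float(np.max(curve)), 1.0), -25.0, -0.05, 0.05])
    return np.array([max(float(curve[0]), 1.0), 0.03, 0.05, 0.002])


def _bounds(model: str) -> tuple[np.ndarray, np.ndarray]:
    if model == "wilmink":
        lo = np.array([_EPS, -np.inf, -np.inf, _EPS])
        hi = np.array([np.inf, -_EPS, -_EPS, np.inf])
    else:
        p = len(MODEL_PARAM_NAMES[model])
        lo = np.full(p, _EPS)
        hi = np.full(p, np.inf)
    return lo, hi


def _lhs_starts(model: str, curve: np.ndarray, n: int = 16) -> np.ndarray:
    """Latin-hypercube multi-start grid over plausible parameter ranges."""
    level = max(float(np.mean(curve)), 1.0)
    if model == "wood":
        lo = np.array([0.2 * level, 0.01, 1e-4])
        hi = np.array([3.0 * level, 0.6, 0.01])
    elif model == "wilmink":
        lo = np.array([0.5 * level, -80.0, -0.3, 0.005])
        hi = np.array([3.0 * level, -1.0, -1e-3, 0.3])
    else:
        lo = np.array([0.2 * level, 0.005, 0.005, 1e-4])
        hi = np.array([3.0 * level, 0.3, 0.3, 0.01])
    sampler = qmc.LatinHypercube(d=len(lo), seed=0)
    return qmc.scale(sampler.random(n), lo, hi)


def fit_model(model: str, grid, curve, init=None) -> LCParams:
    """Least-squares fit of a lactation-curve model to a curve in litres.

    Minimizes ``sum_t (y_t - model(t))**2`` subject to the model's sign
    constraints (implemented as bounds at ``+/-1e-8``). Standard errors are
    the usual asymptotic ``sqrt(diag(sigma2 * (J'J)^-1))`` with
    ``sigma2 = RSS/(N - p)``. Fitting never raises on a difficult curve:
    when the solver stalls or a parameter ends on a sign bound the result
    is returned with ``converged=False``.

    A 16-point Latin-hypercube multi-start is tried when the initial solve
    does not succeed.
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if grid.shape != curve.shape or grid.ndim != 1:
        raise ValueError("grid and curve must be 1-D and the same length")
    p = len(MODEL_PARAM_NAMES[model])
    if len(curve) < p + 1:
        raise ValueError(f"need at least {p + 1} points to fit {model}")
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    lo, hi = _bounds(model)

    def residual(theta: np.ndarray) -> np.ndarray:
        return eval_model(model, theta, grid) - curve

    def solve(x0: np.ndarray):
        x0 = np.clip(x0, lo, hi)
        return optimize.least_squares(
            residual, x0, bounds=(lo, hi), method="trf", max_nfev=2000
        )

    res = solve(np.asarray(init, dtype=float) if init is not None else _default_init(model, curve))
    if not res.success:
        for x0 in _lhs_starts(model, curve):
            cand = solve(x0)
            if cand.cost < res.cost or (cand.success and not res.success):
                res = cand
            if res.success:
                break

    theta = res.x
    rss = float(2.0 * res.cost)
    n = len(curve)
    dof = max(n - p, 1)
    sigma2 = rss / dof
    jtj = res.jac.T @ res.jac
    cov = sigma2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    on_bound = np.any(np.isclose(theta, lo, atol=10 * _EPS)) or np.any(
        np.isclose(theta, hi, atol=10 * _EPS)
    )
    return LCParams(
        model=model,
        params=theta,
        se=se,
        converged=bool(res.success) and not bool(on_bound),
        residual_rmse=math.sqrt(rss / n),
    )


def wood_features(params, tf: float = 280.0) -> LCFeatures:
    """Closed-form peak and persistency of a Wood curve.

    peak DIM ``t_m = b/c``; peak yield ``a*(b/c)**b*exp(-b)``;
    persistency ``b/t_h - c`` with ``t_h = (t_m + tf)/2``.
    Not computable when ``b<=0`` or ``c<=0`` or the peak falls outside
    ``(0, tf)`` (no interior peak — the flat/no-peak regime).
    """
    a, b, c = np.asarray(params, dtype=float)
    if b <= 0 or c <= 0 or a <= 0:
        return LCFeatures("wood", math.nan, math.nan, math.nan, tf, False,
                          "parameters do not describe a peaked curve")
    peak_dim = b / c
    if not (1.0 <= peak_dim < tf):
        # a "peak" before the first day of lactation (b -> 0 limit) is the
        # flat/no-peak regime, not a biological peak
        return LCFeatures("wood", math.nan, math.nan, math.nan, tf, False,
                          f"peak DIM {peak_dim:.2f} outside [1, {tf:g})")
    peak_yield = a * (b / c) ** b * math.exp(-b)
    t_h = (peak_dim + tf) / 2.0
    persistency = b / t_h - c
    return LCFeatures("wood", peak_yield, peak_dim, persistency, tf, True)


def dijkstra_features(params, tf: float = 280.0) -> LCFeatures:
    """Closed-form peak and persistency of a Dijkstra curve.

    peak DIM ``t_m = ln(b/d)/c``; peak yield ``a*(d/b)**(d/c)*exp((b-d)/c)``;
    persistency ``b*exp(-c*t_h) - d`` with ``t_h = (t_m + tf)/2``.
    Not computable when ``b <= d`` (proliferation never outpaces cell death:
    no peak) or ``c <= 0``, or the peak falls outside ``(0, tf)``.
    """
    a, b, c, d = np.asarray(params, dtype=float)
    if c <= 0 or d <= 0 or a <= 0 or b <= d:
        return LCFeatures("dijkstra", math.nan, math.nan, math.nan, tf, False,
                          "parameters do not describe a peaked curve")
    peak_dim = math.log(b / d) / c
    if not (1.0 <= peak_dim < tf):
        return LCFeatures("dijkstra", math.nan, math.nan, math.nan, tf, False,
                          f"peak DIM {peak_dim:.2f} outside [1, {tf:g})")
    peak_yield = a * (d / b) ** (d / c) * math.exp((b - d) / c)
    t_h = (peak_dim + tf) / 2.0
    persistency = b * math.exp(-c * t_h) - d
    return LCFeatures("dijkstra", peak_yield, peak_dim, persistency, tf, True)
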