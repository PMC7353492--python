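"""Estimation of Arrhenius kinetic parameters from isothermal data.

Two estimation routes are provided:

* **two-step** — the traditional procedure: per-temperature linear
  regression of ln(retention) on time yields a rate constant at each
  temperature, then a second linear regression of ln k on
  (1/T − 1/T_ref) yields E_a (slope × −R) and k_ref (exp intercept).
* **one-step** — a single nonlinear least-squares regression of all
  observations jointly against the integrated model
  C/C0 = exp(−k_ref·exp(−(E_a/R)(1/T − 1/T_ref))·t), which uses every
  degree of freedom at once and typically gives tighter intervals.

Both return a :class:`FitResult` with asymptotic standard errors from
(JᵀJ)⁻¹·SSE/(n−p) and t-based 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ConvergenceError, InvalidInputError, RankDeficiencyError
from .kinetics import ArrheniusParameters, retention_isothermal
from .units import GAS_CONSTANT, T_REF_FROZEN_K, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "IsothermalDataset",
    "FitResult",
    "predict_retention",
    "model_jacobian",
    "fit_one_step",
    "fit_two_step",
    "confidence_intervals",
]


@dataclass(frozen=True)
class IsothermalDataset:
    """Isothermal degradation observations (temperature, time, retention).

    Temperatures are stored in Kelvin, times in days, retention as the
    dimensionless fraction C/C0 (must be > 0 so the logarithm exists for
    the two-step route).
    """

    temperature_K: np.ndarray
    time_days: np.ndarray
    retention: np.ndarray

    def __post_init__(self):
        T = np.asarray(self.temperature_K, dtype=float)
        t = np.asarray(self.time_days, dtype=float)
        r = np.asarray(self.retention, dtype=float)
        if not (T.shape == t.shape == r.shape) or T.ndim != 1:
            raise InvalidInputError("temperature, time and retention must be equal-length 1-D arrays")
        if T.size == 0:
            raise InvalidInputError("dataset is empty")
        if np.any(T <= 0):
            raise InvalidInputError("temperatures must be > 0 K")
        if np.any(t < 0):
            raise InvalidInputError("times must be nonnegative")
        if np.any(r <= 0):
            raise InvalidInputError("retention values must be > 0")
        object.__setattr__(self, "temperature_K", T)
        object.__setattr__(self, "time_days", t)
        object.__setattr__(self, "retention", r)

    @property
    def n(self) -> int:
        return int(self.temperature_K.size)

    @property
    def unique_temperatures(self) -> np.ndarray:
        return np.unique(self.temperature_K)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IsothermalDataset":
        """Build from a frame with columns temperature_C, time_days, retention."""
        return cls(
            temperature_K=celsius_to_kelvin(df["temperature_C"].to_numpy(dtype=float)),
            time_days=df["time_days"].to_numpy(dtype=float),
            retention=df["retention"].to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": kelvin_to_celsius(self.temperature_K),
                "time_days": self.time_days,
                "retention": self.retention,
            }
        )


@dataclass(frozen=True)
class FitResult:
    """Kinetic parameters plus uncertainty from a regression.

    ``covariance`` is the 2×2 asymptotic covariance over (k_ref, E_a);
    ``ci95`` holds the per-parameter 95% half-widths SE·t(0.975, df).
    ``df`` is the degrees of freedom used for t quantiles (n − p for the
    one-step fit; number of temperatures − 2 for the two-step Arrhenius
    regression).
    """

    parameters: ArrheniusParameters
    covariance: np.ndarray
    standard_errors: tuple[float, float]
    sse: float
    residuals: np.ndarray
    n: int
    p: int
    df: int
    ci95: tuple[float, float]
    method: str
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> dict:
        se_k, se_E = self.standard_errors
        return {
            "method": self.method,
            "k_ref_per_day": self.parameters.k_ref,
            "E_a_kJ_per_mol": self.parameters.E_a / 1000.0,
            "T_ref_C": kelvin_to_celsius(self.parameters.T_ref),
            "se_k_ref_per_day": se_k,
            "se_E_a_kJ_per_mol": se_E / 1000.0,
            "ci95_k_ref_per_day": self.ci95[0],
            "ci95_E_a_kJ_per_mol": self.ci95[1] / 1000.0,
            "covariance": np.asarray(self.covariance).tolist(),
            "sse": self.sse,
            "n": self.n,
            "p": self.p,
            "df": self.df,
            "warnings": list(self.warnings),
        }


def predict_retention(params: ArrheniusParameters, T, t):
    """Retention predicted by the integrated one-step model (first order)."""
    return retention_isothermal(params, T, t)


def model_jacobian(params: ArrheniusParameters, dataset: IsothermalDataset) -> np.ndarray:
    """Analytic n×2 Jacobian of predicted retention w.r.t. (k_ref, E_a).

    With A = exp(−(E_a/R)(1/T − 1/T_ref)) and Y the predicted retention:
    ∂Y/∂k_ref = −A·t·Y and ∂Y/∂E_a = k_ref·t·A·Y·(1/T − 1/T_ref)/R.
    """
    x = 1.0 / dataset.temperature_K - 1.0 / params.T_ref
    A = np.exp(-(params.E_a / params.gas_constant) * x)
    t = dataset.time_days
    Y = np.exp(-params.k_ref * A * t)
    J = np.empty((dataset.n, 2))
    J[:, 0] = -A * t * Y
    J[:, 1] = params.k_ref * t * A * Y * x / params.gas_constant
    return J


def _predictions(theta: np.ndarray, dataset: IsothermalDataset, T_ref: float) -> np.ndarray:
    k_ref, E_a = theta
    x = 1.0 / dataset.temperature_K - 1.0 / T_ref
    return np.exp(-k_ref * np.exp(-(E_a / GAS_CONSTANT) * x) * dataset.time_days)


def _crude_init(dataset: IsothermalDataset, T_ref: float) -> tuple[float, float]:
    """Log-linear least-squares start values: regress ln(−ln r / t) on −x."""
    mask = (dataset.time_days > 0) & (dataset.retention < 1)
    if mask.sum() < 2:
        return 0.002, 1.0e5
    lnk = np.log(-np.log(dataset.retention[mask]) / dataset.time_days[mask])
    x = 1.0 / dataset.temperature_K[mask] - 1.0 / T_ref
    X = np.column_stack([np.ones(mask.sum()), -x / GAS_CONSTANT])
    beta, *_ = np.linalg.lstsq(X, lnk, rcond=None)
    return float(np.exp(beta[0])), float(beta[1])


def _asymptotic_uncertainty(J: np.ndarray, sse: float, n: int, p: int):
    # column-equilibrate before the conditioning test: k_ref and E_a live on
    # scales ~8 orders of magnitude apart, which is benign; true rank
    # deficiency (proportional columns) survives the normalization
    norms = np.linalg.norm(J, axis=0)
    if np.any(norms == 0):
        raise RankDeficiencyError("a Jacobian column vanishes: a parameter has no effect on the fit")
    D = np.diag(1.0 / norms)
    M = D @ (J.T @ J) @ D
    if np.linalg.cond(M) > 1e10:
        raise RankDeficiencyError(
            "JᵀJ is numerically singular: the design cannot identify both k_ref and E_a "
            "(e.g. all observations at a single temperature)"
        )
    cov = (D @ np.linalg.inv(M) @ D) * sse / (n - p)
    se = np.sqrt(np.diag(cov))
    return cov, se


def fit_one_step(
    dataset: IsothermalDataset,
    init: Optional[ArrheniusParameters] = None,
    tol: float = 1e-10,
    T_ref: float = T_REF_FROZEN_K,
) -> FitResult:
    """Joint nonlinear least-squares fit of (k_ref, E_a) to all observations.

    Minimizes Σ (observed − predicted retention)² with a
    Levenberg–Marquardt least-squares solver and the analytic Jacobian.
    Initialization defaults to the two-step estimates (falling back to a
    crude log-linear start when the two-step design requirements are not
    met).
    """
    p = 2
    if dataset.n <= p:
        raise InvalidInputError(f"need more than {p} observations, got {dataset.n}")
    if dataset.unique_temperatures.size < 2:
        raise RankDeficiencyError("all observations share one temperature: E_a is unidentifiable")

    if init is None:
        try:
            init_theta = fit_two_step(dataset, T_ref=T_ref).parameters
            theta0 = np.array([init_theta.k_ref, init_theta.E_a])
        except (InvalidInputError, RankDeficiencyError):
            theta0 = np.array(_crude_init(dataset, T_ref))
    else:
        theta0 = np.array([init.k_ref, init.E_a])

    def residual_fun(theta):
        return dataset.retention - _predictions(theta, dataset, T_ref)

    def jac_fun(theta):
        params = ArrheniusParameters(max(theta[0], np.finfo(float).tiny), theta[1], T_ref)
        return -model_jacobian(params, dataset)

    result = optimize.least_squares(
        residual_fun,
        theta0,
        jac=jac_fun,
        method="lm",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=2000,
    )
    if not result.success:
        raise ConvergenceError(
            f"one-step fit did not converge: {result.message} (nfev={result.nfev})",
            trace=result,
        )
    k_ref_hat, E_a_hat = result.x
    if k_ref_hat <= 0:
        raise ConvergenceError(f"one-step fit converged to nonphysical k_ref={k_ref_hat}", trace=result)

    params = ArrheniusParameters(k_ref_hat, E_a_hat, T_ref)
    residuals = dataset.retention - _predictions(result.x, dataset, T_ref)
    sse = float(residuals @ residuals)
    J = model_jacobian(params, dataset)
    cov, se = _asymptotic_uncertainty(J, sse, dataset.n, p)
    df = dataset.n - p
    tq = stats.t.ppf(0.975, df)
    return FitResult(
        parameters=params,
        covariance=cov,
        standard_errors=(float(se[0]), float(se[1])),
        sse=sse,
        residuals=residuals,
        n=dataset.n,
        p=p,
        df=df,
        ci95=(float(se[0] * tq), float(se[1] * tq)),
        method="one-step",
    )


def fit_two_step(
    dataset: IsothermalDataset,
    with_intercept: bool = False,
    T_ref: float = T_REF_FROZEN_K,
) -> FitResult:
    """Traditional two-step estimate: per-temperature rates, then Arrhenius.

    Step 1 regresses ln(retention) on time at each temperature (through
    the origin by default, since retention is normalized to 1 at t = 0;
    ``with_intercept=True`` frees the intercept).  Step 2 regresses ln k
    on (1/T − 1/T_ref): slope = −E_a/R, intercept = ln k_ref.  Standard
    errors for (k_ref, E_a) follow from the step-2 regression covariance
    by the delta method, with t quantiles on (number of temperatures − 2)
    degrees of freedom.
    """
    temps = dataset.unique_temperatures
    if temps.size < 3:
        raise InvalidInputError(f"two-step fit needs ≥ 3 distinct temperatures, got {temps.size}")

    warnings: list[str] = []
    k_values: list[float] = []
    k_temps: list[float] = []
    for T in temps:
        mask = dataset.temperature_K == T
        if mask.sum() < 3:
            raise InvalidInputError(
                f"two-step fit needs ≥ 3 time points per temperature; {kelvin_to_celsius(T):.2f} °C has {mask.sum()}"
            )
        y = np.log(dataset.retention[mask])
        t = dataset.time_days[mask]
        X = sm.add_constant(t) if with_intercept else t[:, None]
        ols = sm.OLS(y, X).fit()
        slope = ols.params[-1]
        if slope >= 0:
            warnings.append(
                f"nonpositive decay slope at {kelvin_to_celsius(T):.2f} °C (slope={slope:.3g}); temperature excluded"
            )
            continue
        k_values.append(-slope)
        k_temps.append(T)

    if len(k_values) < 3:
        raise RankDeficiencyError(
            f"fewer than 3 usable rate constants after step 1 ({len(k_values)} usable)"
        )

    x = 1.0 / np.asarray(k_temps) - 1.0 / T_ref
    lnk = np.log(k_values)
    X2 = sm.add_constant(x)
    ols2 = sm.OLS(lnk, X2).fit()
    b0, b1 = ols2.params
    k_ref = float(np.exp(b0))
    E_a = float(-GAS_CONSTANT * b1)
    params = ArrheniusParameters(k_ref, E_a, T_ref)

    # delta method: k_ref = exp(b0), E_a = −R·b1
    G = np.array([[k_ref, 0.0], [0.0, -GAS_CONSTANT]])
    cov = G @ ols2.cov_params() @ G.T
    se = np.sqrt(np.diag(cov))

    predicted = _predictions(np.array([k_ref, E_a]), dataset, T_ref)
    residuals = dataset.retention - predicted
    sse = float(residuals @ residuals)
    df = len(k_values) - 2
    tq = stats.t.ppf(0.975, df)
    return FitResult(
        parameters=params,
        covariance=cov,
        standard_errors=(float(se[0]), float(se[1])),
        sse=sse,
        residuals=residuals,
        n=dataset.n,
        p=2,
        df=df,
        ci95=(float(se[0] * tq), float(se[1] * tq)),
        method="two-step",
        warnings=tuple(warnings),
    )


def confidence_intervals(fit: FitResult, alpha: float = 0.05) -> np.ndarray:
    """Per-parameter (1−alpha) intervals: estimate ± SE·t(1−alpha/2, df).

    Returns a 2×2 array of (lower, upper) rows for (k_ref, E_a).
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    tq = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
    est = np.array([fit.parameters.k_ref, fit.parameters.E_a])
    half = tq * np.asarray(fit.standard_errors)
    return np.column_stack([est - half, est + half])
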