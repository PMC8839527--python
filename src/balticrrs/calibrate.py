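"""Coefficient re-derivation from station data.

Thin functional wrappers over the estimators in
:mod:`balticrrs.estimators`, mirroring the three-stage calibration:

1. one-parameter power-law fits of each IOP on its primary driver,
2. exponential regressions of the prediction/measurement ratio on a
   composition covariate (SumC/Chl or SPM_inorg/SPM),
3. composition of the two into the two-parameter constants,

plus the CDOM log10-quadratic fit and the empirical f/Q aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

from .bands import BANDS, validate_band
from .coefficients import ModelCoefficients
from .estimators import (
    CdomLogPolyRegressor,
    FiveParameterReflectanceModel,
    PowerLawRegressor,
    RatioExponentialRegressor,
)

__all__ = [
    "PowerLawFit",
    "RatioExponentialFit",
    "LogPolyFit",
    "CalibrationResult",
    "fit_power_law",
    "fit_ratio_exponential",
    "compose_two_parameter",
    "fit_cdom_logpoly",
    "fit_f_over_q",
    "calibrate_all",
    "train_test_split_stations",
]


@dataclass(frozen=True)
class PowerLawFit:
    coefficient: float
    exponent: float
    n_used: int
    r_squared_log: float

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("power-law coefficient must be positive")
        if self.n_used < 2:
            raise ValueError("power-law fit needs n_used >= 2")


@dataclass(frozen=True)
class RatioExponentialFit:
    prefactor: float
    rate: float
    n_used: int
    r_squared: float

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise ValueError("prefactor must be positive")


@dataclass(frozen=True)
class LogPolyFit:
    m: float
    n: float
    p: float
    n_used: int


@dataclass
class CalibrationResult:
    """Full re-derived coefficient set plus fit diagnostics."""

    coefficients: ModelCoefficients
    one_param: dict[tuple[str, int], PowerLawFit]
    residual: dict[tuple[str, int], RatioExponentialFit | None]
    cdom: dict[int, LogPolyFit]
    f_over_q: dict[int, float]
    provenance: dict[str, Any] = field(default_factory=dict)


def fit_power_law(x: ArrayLike, y: ArrayLike) -> PowerLawFit:
    """OLS of log10(y) on log10(x): ``y = coefficient * x**exponent``."""
    est = PowerLawRegressor().fit(x, y)
    return PowerLawFit(est.coefficient_, est.exponent_, est.n_used_, est.r_squared_log_)


def fit_ratio_exponential(ratio_cal_over_meas: ArrayLike,
                          covariate: ArrayLike) -> RatioExponentialFit:
    """OLS of ln(ratio) on the covariate: ``ratio = prefactor * exp(rate*c)``."""
    est = RatioExponentialRegressor().fit(covariate, ratio_cal_over_meas)
    return RatioExponentialFit(est.prefactor_, est.rate_, est.n_used_, est.r_squared_)


def compose_two_parameter(one_param: PowerLawFit,
                          residual: RatioExponentialFit) -> tuple[float, float, float]:
    """Compose a one-parameter fit and its residual correction.

    The residual fit models prediction/measurement, so measurement =
    (coefficient/prefactor) * x**exponent * exp(-rate * c):

    returns ``(coefficient / prefactor, exponent, -rate)``.  The
    power-law exponent is never altered by the correction.
    """
    return (one_param.coefficient / residual.prefactor,
            one_param.exponent,
            -residual.rate)


def fit_cdom_logpoly(a400: ArrayLike, a_lambda: ArrayLike) -> LogPolyFit:
    """Fit ``a_lambda = 10**(-m*u**2 + n*u - p)``, ``u = log10(a400)``."""
    est = CdomLogPolyRegressor().fit(a400, a_lambda)
    return LogPolyFit(est.m_, est.n_, est.p_, est.n_used_)


def fit_f_over_q(stations: pd.DataFrame, band: int,
                 statistic: str = "median",
                 coefficients: ModelCoefficients | None = None) -> float:
    """Aggregate per-station empirical f/Q at one band.

    Per station f/Q = (L_u/E_d) * (a + b_b)/b_b with a, b_b assembled
    from the measured IOP columns plus the fixed pure-water constants.
    """
    band = validate_band(band)
    base = coefficients if coefficients is not None else ModelCoefficients.baltic()
    lu = stations[f"lu_{band}"].to_numpy(dtype=float)
    ed = stations[f"ed_{band}"].to_numpy(dtype=float)
    a = (stations[f"aph_{band}"].to_numpy(dtype=float)
         + stations[f"ad_{band}"].to_numpy(dtype=float)
         + stations[f"acdom_{band}"].to_numpy(dtype=float)
         + base.band(band).a_w)
    bb = stations[f"bbp_{band}"].to_numpy(dtype=float) + base.band(band).b_bw
    ok = np.isfinite(lu) & np.isfinite(ed) & (ed > 0) & (bb > 0) & np.isfinite(a)
    if not ok.any():
        raise ValueError(f"no usable stations for f/Q at {band} nm")
    fq = (lu[ok] / ed[ok]) * (a[ok] + bb[ok]) / bb[ok]
    agg = {"median": np.median, "mean": np.mean}[statistic]
    return float(agg(fq))


def calibrate_all(stations: pd.DataFrame,
                  fit_method: str = "two_step",
                  f_over_q_statistic: str = "median",
                  covariate_guard: bool = True,
                  coefficients: ModelCoefficients | None = None) -> CalibrationResult:
    """Run the full calibration pipeline on a station table.

    Returns the re-derived coefficient set (two-parameter constants per
    family/band, CDOM log-quadratic, empirical f/Q) with diagnostics.
    Pure-water constants are taken from ``coefficients`` (default: the
    shipped Baltic set); they are physical constants, not fitted.
    """
    est = FiveParameterReflectanceModel(
        fit_method=fit_method,
        f_over_q_statistic=f_over_q_statistic,
        covariate_guard=covariate_guard,
        coefficients=coefficients,
    ).fit(stations)
    one_param = {
        key: PowerLawFit(e.coefficient_, e.exponent_, e.n_used_, e.r_squared_log_)
        for key, e in est.one_param_fits_.items()
    }
    residual = {
        key: (None if e is None
              else RatioExponentialFit(e.prefactor_, e.rate_, e.n_used_, e.r_squared_))
        for key, e in est.residual_fits_.items()
    }
    cdom = {b: LogPolyFit(e.m_, e.n_, e.p_, e.n_used_) for b, e in est.cdom_fits_.items()}
    return CalibrationResult(
        coefficients=est.coefficients_,
        one_param=one_param,
        residual=residual,
        cdom=cdom,
        f_over_q=dict(est.f_over_q_),
        provenance=dict(est.provenance_),
    )


def train_test_split_stations(stations: pd.DataFrame, test_fraction: float = 0.25,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded row-wise split of a station table (no stratification)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(stations)
    idx = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test = stations.iloc[np.sort(idx[:n_test])]
    train = stations.iloc[np.sort(idx[n_test:])]
    return train, test
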