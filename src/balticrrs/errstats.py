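"""Arithmetic and logarithmic error statistics for model validation.

Bio-optical quantities span orders of magnitude, so validation uses two
complementary summaries of calculated-vs-measured pairs:

* arithmetic: the mean of the pointwise relative errors
  eps_i = (cal_i - meas_i)/meas_i (systematic error) and their
  population standard deviation (statistical error);
* logarithmic: statistics of log10(cal/meas) — the mean log error
  <eps>_g = 10**<log ratio> - 1, the standard error factor
  x = 10**SD(log ratio), and the asymmetric bounds
  sigma+ = x - 1, sigma- = 1/x - 1.

Percentages are reported x100, matching the conventional error tables;
the standard error factor is a unitless multiplier >= 1.  Population
(1/N) denominators are used for both standard deviations by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

from .bands import BANDS
from .coefficients import ModelCoefficients
from . import model as fwd

__all__ = [
    "ErrorReport",
    "pointwise_relative_errors",
    "arithmetic_summary",
    "logarithmic_summary",
    "error_report",
    "build_error_table",
    "ERROR_TABLE_COLUMNS",
]

#: CSV column order of the standard error-table layout.
ERROR_TABLE_COLUMNS = [
    "eps_mean_pct", "sigma_eps_pct",
    "eps_g_pct", "x_factor", "sigma_plus_pct", "sigma_minus_pct",
    "n",
]


@dataclass(frozen=True)
class ErrorReport:
    """The six error statistics for one quantity at one band."""

    eps_mean: float      # systematic (arithmetic) error, %
    sigma_eps: float     # statistical (arithmetic) error, %
    eps_g: float         # systematic logarithmic error, %
    sigma_log: float     # SD of log10(cal/meas), unitless
    x_factor: float      # standard error factor, unitless (>= 1)
    sigma_plus: float    # (x - 1) * 100, %
    sigma_minus: float   # (1/x - 1) * 100, %
    n: int

    def __post_init__(self) -> None:
        if self.x_factor < 1:
            raise ValueError("standard error factor must be >= 1")


def _positive_pairs(measured: ArrayLike, calculated: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    meas = np.asarray(measured, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if meas.shape != cal.shape:
        raise ValueError("measured and calculated must have equal length")
    if meas.size == 0:
        raise ValueError("empty input")
    if np.any(meas <= 0) or np.any(cal <= 0):
        raise ValueError("logarithmic statistics require strictly positive values")
    return meas, cal


def pointwise_relative_errors(measured: ArrayLike, calculated: ArrayLike) -> np.ndarray:
    """eps_i = (cal_i - meas_i) / meas_i, elementwise."""
    meas = np.asarray(measured, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if meas.shape != cal.shape:
        raise ValueError("measured and calculated must have equal length")
    if np.any(meas <= 0):
        raise ValueError("measured values must be strictly positive")
    return (cal - meas) / meas


def arithmetic_summary(eps: ArrayLike, population_sd: bool = True) -> tuple[float, float]:
    """(mean of eps x100, SD of eps x100); population (1/N) SD by default."""
    e = np.asarray(eps, dtype=float)
    if e.size == 0:
        raise ValueError("empty input")
    ddof = 0 if population_sd else 1
    return float(e.mean() * 100.0), float(e.std(ddof=ddof) * 100.0)


def logarithmic_summary(measured: ArrayLike, calculated: ArrayLike,
                        population_sd: bool = True,
                        ) -> tuple[float, float, float, float, float]:
    """(eps_g %, sigma_log, x, sigma+ %, sigma- %) of log10(cal/meas).

    The logarithmic statistics are invariant under common rescaling of
    both arrays, and swapping the roles of measured and calculated
    negates the mean log ratio while leaving x unchanged.
    """
    meas, cal = _positive_pairs(measured, calculated)
    log_ratio = np.log10(cal / meas)
    ddof = 0 if population_sd else 1
    sigma_log = float(log_ratio.std(ddof=ddof))
    eps_g = float((10.0 ** log_ratio.mean() - 1.0) * 100.0)
    x = 10.0**sigma_log
    return eps_g, sigma_log, x, (x - 1.0) * 100.0, (1.0 / x - 1.0) * 100.0


def error_report(measured: ArrayLike, calculated: ArrayLike,
                 population_sd: bool = True) -> ErrorReport:
    """Both summaries for one calculated-vs-measured pairing.

    Pairs with a nonpositive measured or calculated value are excluded
    (log statistics force positivity); the count reported is the number
    of pairs actually used.
    """
    meas = np.asarray(measured, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if meas.shape != cal.shape:
        raise ValueError("measured and calculated must have equal length")
    ok = np.isfinite(meas) & np.isfinite(cal) & (meas > 0) & (cal > 0)
    meas, cal = meas[ok], cal[ok]
    if meas.size == 0:
        raise ValueError("no usable (strictly positive) pairs")
    eps = pointwise_relative_errors(meas, cal)
    eps_mean, sigma_eps = arithmetic_summary(eps, population_sd)
    eps_g, sigma_log, x, s_plus, s_minus = logarithmic_summary(meas, cal, population_sd)
    return ErrorReport(eps_mean, sigma_eps, eps_g, sigma_log, x, s_plus, s_minus,
                       int(meas.size))


_PREDICTORS = {
    ("aph", "one_param"): lambda st, b, c: fwd.aph_one_param(st["chl_a_mg_m3"], b),
    ("ad", "one_param"): lambda st, b, c: fwd.ad_one_param(st["spm_g_m3"], b),
    ("bbp", "one_param"): lambda st, b, c: fwd.bbp_one_param(st["spm_g_m3"], b),
    ("acdom", "one_param"): lambda st, b, c: fwd.acdom_model(st["a_cdom_400_m1"], b, c),
    ("aph", "two_param"): lambda st, b, c: fwd.aph_two_param(
        st["chl_a_mg_m3"], st["sum_c_mg_m3"], b, c),
    ("ad", "two_param"): lambda st, b, c: fwd.ad_two_param(
        st["spm_g_m3"], st["spm_inorg_g_m3"], b, c),
    ("bbp", "two_param"): lambda st, b, c: fwd.bbp_two_param(
        st["spm_g_m3"], st["spm_inorg_g_m3"], b, c),
}


def build_error_table(stations: pd.DataFrame, model_constants: ModelCoefficients | None,
                      quantity: str, mode: str,
                      population_sd: bool = True) -> pd.DataFrame:
    """Per-band error statistics for one model family on a station table.

    Parameters
    ----------
    quantity : {"aph", "ad", "acdom", "bbp", "rrs"}
        Which measured columns to validate against.
    mode : {"one_param", "two_param", "five_param"}
        Which model variant produces the predictions ("five_param" is
        the full reflectance model and applies to quantity "rrs" only).

    Returns
    -------
    DataFrame indexed by band with the standard error-table columns.
    """
    coeffs = model_constants if model_constants is not None else ModelCoefficients.baltic()
    if quantity == "rrs":
        if mode != "five_param":
            raise ValueError("quantity 'rrs' requires mode 'five_param'")
        predictor = None
    else:
        try:
            predictor = _PREDICTORS[(quantity, mode)]
        except KeyError:
            raise ValueError(f"no {mode!r} model for quantity {quantity!r}") from None
    rows = {}
    for band in BANDS:
        col = f"{quantity}_{band}"
        if col not in stations.columns:
            raise KeyError(f"station table missing measured column {col!r}")
        measured = stations[col].to_numpy(dtype=float)
        if predictor is None:
            cv = fwd.ConstituentVector(
                chl_a=stations["chl_a_mg_m3"].to_numpy(dtype=float),
                sum_c=stations["sum_c_mg_m3"].to_numpy(dtype=float),
                spm=stations["spm_g_m3"].to_numpy(dtype=float),
                spm_inorg=stations["spm_inorg_g_m3"].to_numpy(dtype=float),
                a_cdom_400=stations["a_cdom_400_m1"].to_numpy(dtype=float),
            )
            calculated = fwd.rrs_forward(cv, band, coeffs)
        else:
            calculated = np.asarray(predictor(stations, band, coeffs), dtype=float)
        rep = error_report(measured, calculated, population_sd)
        rows[band] = [rep.eps_mean, rep.sigma_eps, rep.eps_g, rep.x_factor,
                      rep.sigma_plus, rep.sigma_minus, rep.n]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=ERROR_TABLE_COLUMNS)
    table.index.name = "band_nm"
    return table
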