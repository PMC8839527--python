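"""Scikit-learn style estimators for model calibration and prediction.

Each component fit of the calibration pipeline is exposed as a small
estimator with ``fit``/``predict`` and trailing-underscore fitted
attributes, so the pieces compose with sklearn model selection.  The
top-level :class:`FiveParameterReflectanceModel` re-derives the full
coefficient set from a station table (``fit``) and predicts four-band
remote-sensing reflectance from constituent concentrations
(``predict``).

All regressions are ordinary least squares on log-transformed values,
consistent with the multiplicative (lognormal) error structure of
bio-optical measurements: a noiseless dataset generated by the model is
recovered exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from sklearn.base import BaseEstimator, RegressorMixin

from .bands import BANDS
from .coefficients import BandCoefficients, ModelCoefficients
from . import model as fwd

_LN10 = np.log(10.0)


def _column(x: ArrayLike) -> np.ndarray:
    """Flatten scalar / 1-d / single-column-2-d input to a 1-d float array."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim > 1:
        raise ValueError(f"expected a single predictor column, got shape {arr.shape}")
    return np.atleast_1d(arr)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = intercept + slope*x; returns (intercept, slope, r2)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return float(beta[0]), float(beta[1]), r2


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Power law ``y = coefficient * x**exponent`` fitted in log10 space.

    Pairs with a nonpositive or non-finite member are dropped and
    counted in ``n_dropped_``; at least two usable pairs are required.

    Attributes
    ----------
    coefficient_, exponent_ : float
        Fitted constants; ``coefficient_ = 10**intercept``.
    n_used_, n_dropped_ : int
    r_squared_log_ : float
        R^2 of the straight-line fit in log10-log10 space.
    """

    def fit(self, X: ArrayLike, y: ArrayLike) -> "PowerLawRegressor":
        x = _column(X)
        y = _column(y)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        self.n_dropped_ = int((~ok).sum())
        x, y = x[ok], y[ok]
        self.n_used_ = int(x.size)
        if self.n_used_ < 2:
            raise ValueError(f"need >= 2 strictly positive pairs, got {self.n_used_}")
        intercept, slope, r2 = _ols_line(np.log10(x), np.log10(y))
        self.coefficient_ = 10.0**intercept
        self.exponent_ = slope
        self.r_squared_log_ = r2
        return self

    def predict(self, X: ArrayLike) -> np.ndarray:
        return self.coefficient_ * np.power(_column(X), self.exponent_)


class RatioExponentialRegressor(RegressorMixin, BaseEstimator):
    """Exponential-in-covariate model ``ratio = prefactor * exp(rate * c)``.

    Fitted by OLS of ``ln(ratio)`` on the covariate.  Used for the
    residual-ratio corrections in which the one-parameter prediction
    over the measurement is regressed on a composition ratio.
    """

    def fit(self, X: ArrayLike, y: ArrayLike) -> "RatioExponentialRegressor":
        c = _column(X)
        ratio = _column(y)
        if c.shape != ratio.shape:
            raise ValueError("covariate and ratio must have equal length")
        ok = np.isfinite(c) & np.isfinite(ratio) & (ratio > 0)
        self.n_dropped_ = int((~ok).sum())
        c, ratio = c[ok], ratio[ok]
        self.n_used_ = int(c.size)
        if self.n_used_ < 2:
            raise ValueError(f"need >= 2 usable pairs, got {self.n_used_}")
        intercept, slope, r2 = _ols_line(c, np.log(ratio))
        self.prefactor_ = float(np.exp(intercept))
        self.rate_ = slope
        self.r_squared_ = r2
        return self

    def predict(self, X: ArrayLike) -> np.ndarray:
        return self.prefactor_ * np.exp(self.rate_ * _column(X))


class CdomLogPolyRegressor(RegressorMixin, BaseEstimator):
    """CDOM spectral model ``y = 10**(-m*u**2 + n*u - p)``, ``u = log10(x)``.

    Fitted by OLS of log10(y) on ``[u**2, u, 1]``; the fitted attributes
    follow the sign convention above (so ``m_`` and ``p_`` are the
    negated quadratic and constant OLS terms).
    """

    def fit(self, X: ArrayLike, y: ArrayLike) -> "CdomLogPolyRegressor":
        x = _column(X)
        y = _column(y)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        self.n_dropped_ = int((~ok).sum())
        x, y = x[ok], y[ok]
        self.n_used_ = int(x.size)
        if self.n_used_ < 3:
            raise ValueError(f"need >= 3 usable pairs, got {self.n_used_}")
        u = np.log10(x)
        design = np.column_stack([u**2, u, np.ones_like(u)])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("collinear design: a_CDOM(400) values span too few levels")
        beta, _, _, _ = np.linalg.lstsq(design, np.log10(y), rcond=None)
        self.m_ = -float(beta[0])
        self.n_ = float(beta[1])
        self.p_ = -float(beta[2])
        return self

    def predict(self, X: ArrayLike) -> np.ndarray:
        u = np.log10(_column(X))
        return np.power(10.0, -self.m_ * u**2 + self.n_ * u - self.p_)


class FiveParameterReflectanceModel(RegressorMixin, BaseEstimator):
    """Four-band reflectance model calibrated from a station table.

    ``fit`` re-derives every model constant from measured constituents
    and IOPs (and radiometry, when present, for the empirical f/Q);
    ``predict`` evaluates R_rs at the four bands from constituent
    concentrations.  An unfitted instance predicts with the shipped
    Baltic coastal coefficient set.

    Parameters
    ----------
    fit_method : {"two_step", "joint"}
        "two_step" reproduces the published procedure: a one-parameter
        power-law fit per band, then an exponential regression of the
        prediction/measurement ratio on a composition covariate, the two
        composed into the two-parameter constants.  "joint" fits
        intercept, log-driver slope and covariate rate in one log-space
        OLS; it is exactly closed under noiseless model-generated data,
        which the two-step variant is not (finite-sample coupling
        between the log-driver and the covariate leaks into the
        one-parameter exponent).
    f_over_q_statistic : {"median", "mean"}
        Aggregator for per-station empirical f/Q values.
    covariate_guard : bool
        If True, stations with SumC/Chl outside [0, 2] or
        SPM_inorg/SPM outside [0, 1] are excluded from the residual
        fits (counted in the provenance).
    coefficients : ModelCoefficients, optional
        Coefficient set used for prediction before ``fit`` and as the
        source of the fixed pure-water constants; defaults to the
        shipped Baltic set.
    """

    def __init__(self, fit_method: str = "two_step",
                 f_over_q_statistic: str = "median",
                 covariate_guard: bool = True,
                 coefficients: ModelCoefficients | None = None):
        self.fit_method = fit_method
        self.f_over_q_statistic = f_over_q_statistic
        self.covariate_guard = covariate_guard
        self.coefficients = coefficients

    # -- helpers ---------------------------------------------------------

    def _base(self) -> ModelCoefficients:
        return self.coefficients if self.coefficients is not None else ModelCoefficients.baltic()

    @staticmethod
    def _require(stations: pd.DataFrame, columns: list[str]) -> None:
        missing = [c for c in columns if c not in stations.columns]
        if missing:
            raise KeyError(f"station table missing required column(s): {missing}")

    def _fit_family(self, driver: np.ndarray, covariate: np.ndarray,
                    measured: np.ndarray, guard_range: tuple[float, float],
                    ) -> tuple[PowerLawRegressor, RatioExponentialRegressor | None,
                               tuple[float, float, float], int]:
        """One component family at one band -> (1p fit, residual fit, 2p constants, n_guarded)."""
        one_p = PowerLawRegressor().fit(driver, measured)
        ok = np.isfinite(driver) & np.isfinite(measured) & (driver > 0) & (measured > 0)
        ok &= np.isfinite(covariate) & (covariate >= 0)
        n_guarded = 0
        if self.covariate_guard:
            guard = (covariate >= guard_range[0]) & (covariate <= guard_range[1])
            n_guarded = int((ok & ~guard).sum())
            ok &= guard
        d, c, m = driver[ok], covariate[ok], measured[ok]
        if self.fit_method == "joint":
            design = np.column_stack([np.ones_like(d), np.log10(d), c])
            beta, _, _, _ = np.linalg.lstsq(design, np.log10(m), rcond=None)
            two_p = (10.0 ** float(beta[0]), float(beta[1]), float(beta[2]) * _LN10)
            return one_p, None, two_p, n_guarded
        if self.fit_method != "two_step":
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        ratio = one_p.predict(d) / m
        residual = RatioExponentialRegressor().fit(c, ratio)
        two_p = (one_p.coefficient_ / residual.prefactor_, one_p.exponent_, -residual.rate_)
        return one_p, residual, two_p, n_guarded

    # -- sklearn API -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "FiveParameterReflectanceModel":
        """Calibrate every model constant from a station table.

        ``X`` must carry the constituent columns and the per-band
        measured IOP columns; radiometry columns (``lu_*``, ``ed_*``)
        are optional and only feed the empirical f/Q.
        """
        from .io import constituent_columns, iop_columns, radiometry_columns

        stations = X
        self._require(stations, constituent_columns() + iop_columns())
        base = self._base()

        chl = stations["chl_a_mg_m3"].to_numpy(dtype=float)
        sum_c = stations["sum_c_mg_m3"].to_numpy(dtype=float)
        spm = stations["spm_g_m3"].to_numpy(dtype=float)
        inorg = stations["spm_inorg_g_m3"].to_numpy(dtype=float)
        a400 = stations["a_cdom_400_m1"].to_numpy(dtype=float)

        with np.errstate(invalid="ignore", divide="ignore"):
            pig_ratio = np.where(chl > 0, sum_c / np.where(chl > 0, chl, 1.0), np.nan)
            inorg_frac = np.where(spm > 0, inorg / np.where(spm > 0, spm, 1.0), np.nan)

        self.one_param_fits_ = {}
        self.residual_fits_ = {}
        self.cdom_fits_ = {}
        self.provenance_ = {"fit_method": self.fit_method,
                            "f_over_q_statistic": self.f_over_q_statistic,
                            "n_stations": int(len(stations)),
                            "dropped": {}}
        bands_out: dict[int, BandCoefficients] = {}
        two_p: dict[str, dict[int, tuple[float, float, float]]] = {"aph": {}, "ad": {}, "bbp": {}}

        families = {
            "aph": (chl, pig_ratio, "aph", (0.0, 2.0)),
            "ad": (spm, inorg_frac, "ad", (0.0, 1.0)),
            "bbp": (spm, inorg_frac, "bbp", (0.0, 1.0)),
        }
        for fam, (driver, covariate, prefix, guard) in families.items():
            for band in BANDS:
                meas = stations[f"{prefix}_{band}"].to_numpy(dtype=float)
                one_p, residual, constants, n_guarded = self._fit_family(
                    driver, covariate, meas, guard)
                self.one_param_fits_[(fam, band)] = one_p
                self.residual_fits_[(fam, band)] = residual
                two_p[fam][band] = constants
                self.provenance_["dropped"][f"{fam}_{band}"] = {
                    "nonpositive": one_p.n_dropped_, "covariate_guard": n_guarded}

        for band in BANDS:
            meas = stations[f"acdom_{band}"].to_numpy(dtype=float)
            cdom = CdomLogPolyRegressor().fit(a400, meas)
            self.cdom_fits_[band] = cdom
            self.provenance_["dropped"][f"acdom_{band}"] = {"nonpositive": cdom.n_dropped_}

        self.f_over_q_ = self._fit_f_over_q(stations, base)

        for band in BANDS:
            cdom = self.cdom_fits_[band]
            bands_out[band] = BandCoefficients(
                bbp=two_p["bbp"][band],
                aph=two_p["aph"][band],
                ad=two_p["ad"][band],
                acdom=(cdom.m_, cdom.n_, cdom.p_),
                a_w=base.band(band).a_w,
                b_bw=base.band(band).b_bw,
                f_over_q=self.f_over_q_[band],
            )
        self.coefficients_ = ModelCoefficients(
            bands=bands_out, name="calibrated", metadata=dict(self.provenance_))
        return self

    def _fit_f_over_q(self, stations: pd.DataFrame,
                      base: ModelCoefficients) -> dict[int, float]:
        from .io import radiometry_columns

        have_radiometry = all(
            c in stations.columns for c in radiometry_columns(include_eu=False))
        out: dict[int, float] = {}
        if not have_radiometry:
            warnings.warn(
                "station table carries no radiometry (lu_*/ed_* columns); "
                "keeping the base f/Q values", stacklevel=2)
            self.provenance_["f_over_q"] = "base (no radiometry)"
            return {b: base.band(b).f_over_q for b in BANDS}
        agg = {"median": np.median, "mean": np.mean}.get(self.f_over_q_statistic)
        if agg is None:
            raise ValueError(f"unknown f_over_q_statistic {self.f_over_q_statistic!r}")
        for band in BANDS:
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
            out[band] = float(agg(fq))
        self.provenance_["f_over_q"] = f"empirical ({self.f_over_q_statistic})"
        return out

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predict R_rs [1/sr] at the four bands for each input row.

        ``X`` is a DataFrame with the five constituent columns (the
        station-table naming); returns a DataFrame with columns
        ``rrs_420 ... rrs_620``.
        """
        from .io import constituent_columns

        self._require(X, constituent_columns())
        coeffs = getattr(self, "coefficients_", None) or self._base()
        cv = fwd.ConstituentVector(
            chl_a=X["chl_a_mg_m3"].to_numpy(dtype=float),
            sum_c=X["sum_c_mg_m3"].to_numpy(dtype=float),
            spm=X["spm_g_m3"].to_numpy(dtype=float),
            spm_inorg=X["spm_inorg_g_m3"].to_numpy(dtype=float),
            a_cdom_400=X["a_cdom_400_m1"].to_numpy(dtype=float),
        )
        out = {f"rrs_{b}": fwd.rrs_forward(cv, b, coeffs) for b in BANDS}
        return pd.DataFrame(out, index=X.index)
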