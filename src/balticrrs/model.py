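"""Forward evaluation of the five-parameter reflectance model.

The model predicts remote-sensing reflectance just below the surface,

    R_rs(band) = (f/Q)(band) * b_b / (a + b_b)   [1/sr],

from five biogeochemical drivers: chlorophyll a, the sum of accessory
pigments, total and inorganic suspended particulate matter, and CDOM
absorption at the 400 nm reference wavelength.  Total absorption and
backscattering are budgets over component models:

    a   = a_ph + a_d + a_CDOM + a_w
    b_b = b_bp + b_bw

Each component is a power law in its primary driver, modulated (in the
two-parameter forms) by an exponential in a composition ratio
(SumC/Chl for phytoplankton, SPM_inorg/SPM for particles); CDOM
absorption is a log10-quadratic in a_CDOM(400).  All functions accept
scalars or numpy arrays and are defined only at the four model bands.

Units: Chl a and SumC in mg m-3, SPM in g m-3, absorption and
backscattering in 1/m, R_rs and f/Q in 1/sr.  Units are enforced by
naming and documentation, not unit objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

from .bands import BANDS, nearest_band, validate_band
from .coefficients import (
    ONE_PARAM_AD,
    ONE_PARAM_APH,
    ONE_PARAM_BBP,
    ModelCoefficients,
)

__all__ = [
    "ConstituentVector",
    "aph_one_param",
    "ad_one_param",
    "bbp_one_param",
    "acdom_model",
    "aph_two_param",
    "ad_two_param",
    "bbp_two_param",
    "a_total",
    "bb_total",
    "rrs_forward",
    "rrs_from_radiometry",
    "q_factor",
    "f_over_q_empirical",
    "nearest_band",
]


@dataclass(frozen=True)
class ConstituentVector:
    """The five model drivers for one station (or arrays of stations).

    Attributes
    ----------
    chl_a : float or ndarray
        Chlorophyll a concentration [mg m-3].
    sum_c : float or ndarray
        Sum of accessory pigment concentrations [mg m-3].
    spm : float or ndarray
        Suspended particulate matter dry mass [g m-3].
    spm_inorg : float or ndarray
        Inorganic SPM fraction dry mass [g m-3]; must not exceed ``spm``.
    a_cdom_400 : float or ndarray
        CDOM absorption at 400 nm [1/m].
    """

    chl_a: ArrayLike
    sum_c: ArrayLike
    spm: ArrayLike
    spm_inorg: ArrayLike
    a_cdom_400: ArrayLike

    def __post_init__(self) -> None:
        chl, sc, spm, inorg, a4 = (
            np.asarray(getattr(self, f), dtype=float)
            for f in ("chl_a", "sum_c", "spm", "spm_inorg", "a_cdom_400")
        )
        for name, arr in (("chl_a", chl), ("sum_c", sc), ("spm", spm),
                          ("spm_inorg", inorg), ("a_cdom_400", a4)):
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and >= 0")
        if np.any(inorg > spm * (1 + 1e-12)):
            raise ValueError("spm_inorg must not exceed spm")
        if np.any((sc > 0) & (chl == 0)):
            raise ValueError("sum_c > 0 requires chl_a > 0 (SumC/Chl must be finite)")


def _require_nonnegative(name: str, x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and >= 0")
    return arr


def _power_law(x: np.ndarray, coefficient: float, exponent: float) -> np.ndarray:
    return coefficient * np.power(x, exponent)


def _safe_ratio(numerator: ArrayLike, denominator: ArrayLike,
                names: tuple[str, str]) -> np.ndarray:
    """num/den with 0/0 := 0; positive numerator over zero denominator is an error."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if np.any((num > 0) & (den == 0)):
        raise ValueError(f"{names[0]} > 0 with {names[1]} = 0: ratio diverges")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return ratio


# ---------------------------------------------------------------------------
# one-parameter component models
# ---------------------------------------------------------------------------

def aph_one_param(chl_a: ArrayLike, band: int) -> np.ndarray:
    """Phytoplankton absorption [1/m] from Chl a alone (power law)."""
    band = validate_band(band)
    chl = _require_nonnegative("chl_a", chl_a)
    c, e = ONE_PARAM_APH[band]
    return _power_law(chl, c, e)


def ad_one_param(spm: ArrayLike, band: int) -> np.ndarray:
    """Non-algal particle absorption [1/m] from SPM alone (power law)."""
    band = validate_band(band)
    s = _require_nonnegative("spm", spm)
    c, e = ONE_PARAM_AD[band]
    return _power_law(s, c, e)


def bbp_one_param(spm: ArrayLike, band: int) -> np.ndarray:
    """Particulate backscattering [1/m] from SPM alone (power law)."""
    band = validate_band(band)
    s = _require_nonnegative("spm", spm)
    c, e = ONE_PARAM_BBP[band]
    return _power_law(s, c, e)


# ---------------------------------------------------------------------------
# two-parameter component models and CDOM
# ---------------------------------------------------------------------------

def _coeffs(coeffs: ModelCoefficients | None) -> ModelCoefficients:
    return ModelCoefficients.baltic() if coeffs is None else coeffs


def acdom_model(a_cdom_400: ArrayLike, band: int,
                coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """CDOM absorption [1/m] from the 400 nm reference value.

    Evaluates ``10**(-M*u**2 + N*u - P)`` with ``u = log10(a_CDOM(400))``.
    The quadratic acts on the log10 of the driver, so the spectrum shifts
    multiplicatively and stays physical (a_CDOM decreases from 400 nm
    toward longer wavelengths for typical CDOM).  At a_CDOM(400) = 0 the
    continuous limit 0 is returned (the -M*u**2 term dominates as
    u -> -inf).
    """
    band = validate_band(band)
    a4 = _require_nonnegative("a_cdom_400", a_cdom_400)
    m, n, p = _coeffs(coeffs).band(band).acdom
    out = np.zeros_like(a4)
    pos = a4 > 0
    with np.errstate(divide="ignore"):
        u = np.log10(np.where(pos, a4, 1.0))
    out = np.where(pos, np.power(10.0, -m * u**2 + n * u - p), 0.0)
    return out


def aph_two_param(chl_a: ArrayLike, sum_c: ArrayLike, band: int,
                  coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Phytoplankton absorption [1/m] from Chl a and accessory pigments.

    ``G * Chl**F * exp(H * SumC/Chl)``; zero when Chl a is zero.
    """
    band = validate_band(band)
    chl = _require_nonnegative("chl_a", chl_a)
    sc = _require_nonnegative("sum_c", sum_c)
    g, f, h = _coeffs(coeffs).band(band).aph
    ratio = _safe_ratio(sc, chl, ("sum_c", "chl_a"))
    return _power_law(chl, g, f) * np.exp(h * ratio)


def ad_two_param(spm: ArrayLike, spm_inorg: ArrayLike, band: int,
                 coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Non-algal particle absorption [1/m] from SPM and its inorganic part.

    ``K * SPM**J * exp(L * SPM_inorg/SPM)``; zero when SPM is zero.
    """
    band = validate_band(band)
    s = _require_nonnegative("spm", spm)
    si = _require_nonnegative("spm_inorg", spm_inorg)
    if np.any(np.asarray(si) > np.asarray(s)):
        raise ValueError("spm_inorg must not exceed spm")
    k, j, l = _coeffs(coeffs).band(band).ad
    ratio = _safe_ratio(si, s, ("spm_inorg", "spm"))
    return _power_law(s, k, j) * np.exp(l * ratio)


def bbp_two_param(spm: ArrayLike, spm_inorg: ArrayLike, band: int,
                  coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Particulate backscattering [1/m] from SPM and its inorganic part.

    ``C * SPM**B * exp(D * SPM_inorg/SPM)``; zero when SPM is zero.
    """
    band = validate_band(band)
    s = _require_nonnegative("spm", spm)
    si = _require_nonnegative("spm_inorg", spm_inorg)
    if np.any(np.asarray(si) > np.asarray(s)):
        raise ValueError("spm_inorg must not exceed spm")
    c, b, d = _coeffs(coeffs).band(band).bbp
    ratio = _safe_ratio(si, s, ("spm_inorg", "spm"))
    return _power_law(s, c, b) * np.exp(d * ratio)


# ---------------------------------------------------------------------------
# budgets and reflectance
# ---------------------------------------------------------------------------

def a_total(cv: ConstituentVector, band: int,
            coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Total absorption budget [1/m]: a_ph + a_d + a_CDOM + a_w."""
    coeffs = _coeffs(coeffs)
    band = validate_band(band)
    return (
        aph_two_param(cv.chl_a, cv.sum_c, band, coeffs)
        + ad_two_param(cv.spm, cv.spm_inorg, band, coeffs)
        + acdom_model(cv.a_cdom_400, band, coeffs)
        + coeffs.band(band).a_w
    )


def bb_total(cv: ConstituentVector, band: int,
             coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Total backscattering budget [1/m]: b_bp + b_bw."""
    coeffs = _coeffs(coeffs)
    band = validate_band(band)
    return bbp_two_param(cv.spm, cv.spm_inorg, band, coeffs) + coeffs.band(band).b_bw


def rrs_forward(cv: ConstituentVector, band: int,
                coeffs: ModelCoefficients | None = None) -> np.ndarray:
    """Remote-sensing reflectance [1/sr] from the five constituents.

    ``R_rs = (f/Q) * b_b / (a + b_b)``.  The result is bounded above by
    f/Q at the band and is strictly positive (pure water backscatters).
    """
    coeffs = _coeffs(coeffs)
    band = validate_band(band)
    a = a_total(cv, band, coeffs)
    bb = bb_total(cv, band, coeffs)
    return coeffs.band(band).f_over_q * bb / (a + bb)


# ---------------------------------------------------------------------------
# radiometric definitions
# ---------------------------------------------------------------------------

def rrs_from_radiometry(l_u0m: ArrayLike, e_d0m: ArrayLike) -> np.ndarray:
    """R_rs [1/sr] = L_u(0-) / E_d(0-), just below the surface."""
    lu = np.asarray(l_u0m, dtype=float)
    ed = np.asarray(e_d0m, dtype=float)
    if np.any(ed <= 0):
        raise ValueError("E_d(0-) must be strictly positive")
    return lu / ed


def q_factor(e_u0m: ArrayLike, l_u0m: ArrayLike) -> np.ndarray:
    """Q [sr] = E_u(0-) / L_u(0-), the non-isotropy of the upward field."""
    eu = np.asarray(e_u0m, dtype=float)
    lu = np.asarray(l_u0m, dtype=float)
    if np.any(lu <= 0):
        raise ValueError("L_u(0-) must be strictly positive")
    return eu / lu


def f_over_q_empirical(r_rs: ArrayLike, a: ArrayLike, b_b: ArrayLike) -> np.ndarray:
    """Invert the reflectance relation for f/Q [1/sr].

    ``f/Q = R_rs * (a + b_b) / b_b``; requires b_b > 0.
    """
    r = np.asarray(r_rs, dtype=float)
    a = np.asarray(a, dtype=float)
    bb = np.asarray(b_b, dtype=float)
    if np.any(bb <= 0):
        raise ValueError("b_b must be strictly positive to invert for f/Q")
    if np.any(a < 0):
        raise ValueError("a must be >= 0")
    return r * (a + bb) / bb
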