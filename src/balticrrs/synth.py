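"""Synthetic station tables with Baltic-coastal statistical structure.

The generator emulates the statistical shape of a coastal Case 2
cruise dataset so the calibration, error-statistics and reflectance
pipeline are testable end to end without field data:

* constituent concentrations are lognormal (they span orders of
  magnitude in coastal waters), the inorganic SPM fraction is Beta on
  [0, 1], and the accessory-pigment/chlorophyll ratio is a truncated
  normal on a physiologically sensible interval;
* "measured" IOPs are the forward-model values perturbed by
  multiplicative lognormal noise (log-symmetric, matching the
  logarithmic error statistics used for validation);
* radiometry is generated by consistent inversion of the reflectance
  relation: R_rs from the measured IOPs, L_u = R_rs * E_d, E_u = Q * L_u,
  so the radiometric identities hold exactly and the empirical f/Q
  inversion recovers the generating value before any radiance noise.

Default marginals are calibrated so the generated population's mean
non-water absorption budget at 420 nm is close to the CDOM-dominated
68/20/12 (CDOM/phytoplankton/detritus) split characteristic of these
waters.  All draws are governed by explicit seeds; identical parameters
and seed give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .bands import BANDS
from .coefficients import ModelCoefficients
from . import model as fwd
from .io import station_columns

__all__ = [
    "PopulationParams",
    "generate_constituents",
    "synthesize_iops",
    "synthesize_radiometry",
    "generate_dataset",
]


@dataclass(frozen=True)
class PopulationParams:
    """Distributional parameters of the synthetic station population.

    Lognormal marginals are parameterised by the median and the spread
    of log10 (dex); the inorganic SPM fraction is Beta(a, b); the
    accessory-pigment ratio SumC/Chl is a truncated normal.  Noise
    fields give per-quantity multiplicative lognormal measurement noise
    as sigma of log10.
    """

    chl_a_median: float = 5.0          # mg m-3
    chl_a_sigma_log10: float = 0.4     # dex
    spm_median: float = 1.3            # g m-3
    spm_sigma_log10: float = 0.35      # dex
    a_cdom_400_median: float = 0.9     # 1/m
    a_cdom_400_sigma_log10: float = 0.2
    inorg_beta: tuple[float, float] = (2.0, 3.0)
    pigment_ratio_mean: float = 0.35
    pigment_ratio_sd: float = 0.1
    pigment_ratio_bounds: tuple[float, float] = (0.05, 1.0)
    iop_noise_sigma_log10: float = 0.14
    lu_noise_sigma_log10: float = 0.0
    n_stations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chl_a_sigma_log10", "spm_sigma_log10", "a_cdom_400_sigma_log10"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("chl_a_median", "spm_median", "a_cdom_400_median"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not all(v > 0 for v in self.inorg_beta):
            raise ValueError("inorg_beta shape parameters must be > 0")
        lo, hi = self.pigment_ratio_bounds
        if not (0 < lo < hi <= 2.0):
            raise ValueError("pigment_ratio_bounds must satisfy 0 < lo < hi <= 2")
        if self.iop_noise_sigma_log10 < 0 or self.lu_noise_sigma_log10 < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")

    def with_(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


def _lognormal(rng: np.random.Generator, median: float, sigma_log10: float,
               n: int) -> np.ndarray:
    return median * 10.0 ** (sigma_log10 * rng.standard_normal(n))


def generate_constituents(params: PopulationParams) -> pd.DataFrame:
    """Draw the five-constituent columns for ``params.n_stations`` stations.

    Constituents are drawn independently apart from the structural
    couplings: SumC is Chl a times the pigment ratio, and SPM_inorg is
    SPM times the inorganic fraction, so every row satisfies the
    constituent invariants by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_stations
    chl = _lognormal(rng, params.chl_a_median, params.chl_a_sigma_log10, n)
    spm = _lognormal(rng, params.spm_median, params.spm_sigma_log10, n)
    a400 = _lognormal(rng, params.a_cdom_400_median, params.a_cdom_400_sigma_log10, n)
    frac = rng.beta(*params.inorg_beta, size=n)
    lo, hi = params.pigment_ratio_bounds
    mu, sd = params.pigment_ratio_mean, params.pigment_ratio_sd
    ratio = truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd,
                          size=n, random_state=rng)
    return pd.DataFrame({
        "station_id": [f"S{i:04d}" for i in range(n)],
        "chl_a_mg_m3": chl,
        "sum_c_mg_m3": chl * ratio,
        "spm_g_m3": spm,
        "spm_inorg_g_m3": spm * frac,
        "a_cdom_400_m1": a400,
    })


def _constituent_vector(table: pd.DataFrame) -> fwd.ConstituentVector:
    return fwd.ConstituentVector(
        chl_a=table["chl_a_mg_m3"].to_numpy(dtype=float),
        sum_c=table["sum_c_mg_m3"].to_numpy(dtype=float),
        spm=table["spm_g_m3"].to_numpy(dtype=float),
        spm_inorg=table["spm_inorg_g_m3"].to_numpy(dtype=float),
        a_cdom_400=table["a_cdom_400_m1"].to_numpy(dtype=float),
    )


def synthesize_iops(constituents: pd.DataFrame,
                    coeffs: ModelCoefficients | None = None,
                    noise_sigma_log10: float = 0.14,
                    seed: int = 0) -> pd.DataFrame:
    """Add measured IOP columns: forward-model values times lognormal noise.

    measured = model * 10**(sigma * z), with an independent standard
    normal z per station, band and quantity; sigma = 0 reproduces the
    model exactly.
    """
    if noise_sigma_log10 < 0:
        raise ValueError("noise_sigma_log10 must be >= 0")
    coeffs = ModelCoefficients.baltic() if coeffs is None else coeffs
    rng = np.random.default_rng(seed)
    cv = _constituent_vector(constituents)
    out = constituents.copy()
    for band in BANDS:
        truths = {
            "aph": fwd.aph_two_param(cv.chl_a, cv.sum_c, band, coeffs),
            "ad": fwd.ad_two_param(cv.spm, cv.spm_inorg, band, coeffs),
            "acdom": fwd.acdom_model(cv.a_cdom_400, band, coeffs),
            "bbp": fwd.bbp_two_param(cv.spm, cv.spm_inorg, band, coeffs),
        }
        for name, truth in truths.items():
            noise = 10.0 ** (noise_sigma_log10 * rng.standard_normal(len(out)))
            out[f"{name}_{band}"] = truth * noise
    return out


def synthesize_radiometry(station_iops: pd.DataFrame,
                          coeffs: ModelCoefficients | None = None,
                          q_value: float = 3.5,
                          e_d_scale: float = 100.0,
                          lu_noise_sigma_log10: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Add L_u, E_d, E_u and R_rs columns by inverting the reflectance relation.

    R_rs at each band is computed from the measured IOP columns, then
    L_u = R_rs * E_d (with optional multiplicative lognormal noise on
    L_u) and E_u = Q * L_u.  Before noise, inverting for f/Q on any row
    returns the generating value exactly.
    """
    if not q_value > 0:
        raise ValueError("q_value must be > 0")
    if not e_d_scale > 0:
        raise ValueError("e_d_scale must be > 0")
    if lu_noise_sigma_log10 < 0:
        raise ValueError("lu_noise_sigma_log10 must be >= 0")
    coeffs = ModelCoefficients.baltic() if coeffs is None else coeffs
    rng = np.random.default_rng(seed)
    out = station_iops.copy()
    n = len(out)
    for band in BANDS:
        bc = coeffs.band(band)
        a = (out[f"aph_{band}"].to_numpy(dtype=float)
             + out[f"ad_{band}"].to_numpy(dtype=float)
             + out[f"acdom_{band}"].to_numpy(dtype=float)
             + bc.a_w)
        bb = out[f"bbp_{band}"].to_numpy(dtype=float) + bc.b_bw
        r_rs = bc.f_over_q * bb / (a + bb)
        ed = np.full(n, e_d_scale)
        lu = r_rs * ed
        if lu_noise_sigma_log10 > 0:
            lu = lu * 10.0 ** (lu_noise_sigma_log10 * rng.standard_normal(n))
        out[f"lu_{band}"] = lu
        out[f"ed_{band}"] = ed
        out[f"eu_{band}"] = q_value * lu
        out[f"rrs_{band}"] = lu / ed
    return out


def generate_dataset(params: PopulationParams | None = None,
                     coeffs: ModelCoefficients | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Complete synthetic station table (constituents, IOPs, radiometry).

    ``seed`` overrides ``params.seed``; sub-generators are seeded by
    fixed offsets of it, so a single integer reproduces the table
    byte-for-byte.
    """
    params = PopulationParams() if params is None else params
    if seed is not None:
        params = params.with_(seed=int(seed))
    coeffs = ModelCoefficients.baltic() if coeffs is None else coeffs
    constituents = generate_constituents(params)
    iops = synthesize_iops(constituents, coeffs,
                           noise_sigma_log10=params.iop_noise_sigma_log10,
                           seed=params.seed + 1)
    full = synthesize_radiometry(iops, coeffs,
                                 lu_noise_sigma_log10=params.lu_noise_sigma_log10,
                                 seed=params.seed + 2)
    return full[[c for c in station_columns() if c in full.columns]]
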