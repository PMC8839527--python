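"""Per-band constants of the five-parameter reflectance model.

A :class:`ModelCoefficients` object carries, for each of the four model
bands, the constants of the component models

* particulate backscattering  ``b_bp = C * SPM**B * exp(D * SPM_inorg/SPM)``
* phytoplankton absorption    ``a_ph = G * Chl**F * exp(H * SumC/Chl)``
* non-algal particle absorption ``a_d = K * SPM**J * exp(L * SPM_inorg/SPM)``
* CDOM absorption             ``a_CDOM = 10**(-M*u**2 + N*u - P)``,
  ``u = log10(a_CDOM(400))``

plus the pure-seawater absorption ``a_w`` and backscattering ``b_bw``
[1/m] and the radiance-distribution factor ``f/Q`` [1/sr].

The shipped Baltic coastal set is loaded from a JSON file packaged with
the library; any coefficient set with the same schema can be loaded from
disk, and a calibration produces one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

from .bands import BANDS, validate_band

_FAMILY_KEYS = {
    "bbp": ("C", "B", "D"),
    "aph": ("G", "F", "H"),
    "ad": ("K", "J", "L"),
    "acdom": ("M", "N", "P"),
}

_F_OVER_Q_RANGE = (0.07, 0.13)


@dataclass(frozen=True)
class BandCoefficients:
    """Constants of the five-parameter model at one band."""

    bbp: tuple[float, float, float]  # C, B, D
    aph: tuple[float, float, float]  # G, F, H
    ad: tuple[float, float, float]  # K, J, L
    acdom: tuple[float, float, float]  # M, N, P
    a_w: float
    b_bw: float
    f_over_q: float


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficient set for all four bands.

    Use :meth:`baltic` for the shipped southern-Baltic coastal set,
    :meth:`load` / :meth:`save` for JSON files, or build one from a
    calibration result.
    """

    bands: dict[int, BandCoefficients]
    name: str = "custom"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in BANDS if b not in self.bands]
        if missing:
            raise ValueError(f"coefficient set missing bands {missing}; all of {BANDS} required")
        for b, bc in self.bands.items():
            validate_band(b)
            for fam in ("bbp", "aph", "ad"):
                coef = getattr(bc, fam)[0]
                if not coef > 0:
                    raise ValueError(f"{fam} coefficient at {b} nm must be positive, got {coef}")
            if not (bc.a_w > 0 and bc.b_bw > 0):
                raise ValueError(f"pure-water constants at {b} nm must be positive")
            if not bc.f_over_q > 0:
                raise ValueError(f"f/Q at {b} nm must be positive, got {bc.f_over_q}")

    def band(self, wavelength_nm: int) -> BandCoefficients:
        return self.bands[validate_band(wavelength_nm)]

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"name": self.name, "bands": {}}
        if self.metadata:
            out["metadata"] = self.metadata
        for b in BANDS:
            bc = self.bands[b]
            out["bands"][str(b)] = {
                **{
                    fam: dict(zip(_FAMILY_KEYS[fam], getattr(bc, fam)))
                    for fam in _FAMILY_KEYS
                },
                "a_w": bc.a_w,
                "b_bw": bc.b_bw,
                "f_over_q": bc.f_over_q,
            }
        return out

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelCoefficients":
        bands: dict[int, BandCoefficients] = {}
        for key, blk in d["bands"].items():
            b = validate_band(int(key))
            fams = {}
            for fam, names in _FAMILY_KEYS.items():
                fams[fam] = tuple(float(blk[fam][n]) for n in names)
            bands[b] = BandCoefficients(
                a_w=float(blk["a_w"]),
                b_bw=float(blk["b_bw"]),
                f_over_q=float(blk["f_over_q"]),
                **fams,
            )
        return cls(bands=bands, name=d.get("name", "custom"), metadata=d.get("metadata", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def baltic(cls) -> "ModelCoefficients":
        """The shipped southern-Baltic coastal coefficient set.

        For this set f/Q lies in [0.07, 0.13] 1/sr and increases with
        wavelength, as established empirically for these waters.
        """
        text = resources.files("balticrrs.data").joinpath("baltic_coefficients.json").read_text()
        mc = cls.from_dict(json.loads(text))
        for b in BANDS:
            fq = mc.bands[b].f_over_q
            if not _F_OVER_Q_RANGE[0] <= fq <= _F_OVER_Q_RANGE[1]:
                raise ValueError(f"shipped f/Q at {b} nm outside {_F_OVER_Q_RANGE}: {fq}")
        return mc


#: One-parameter power-law constants (coefficient, exponent), fitted on the
#: same campaigns but prior to the residual-ratio correction.  These are a
#: separate published set and are deliberately NOT derived from the
#: two-parameter constants above.
ONE_PARAM_APH: dict[int, tuple[float, float]] = {
    420: (0.056, 0.827),
    488: (0.037, 0.820),
    555: (0.013, 0.815),
    620: (0.008, 0.926),
}

ONE_PARAM_AD: dict[int, tuple[float, float]] = {
    420: (0.071, 0.809),
    488: (0.045, 0.762),
    # The 620 nm coefficient is published as 0.002, inconsistent with the
    # monotone trend of the other bands and with the two-parameter K=0.015;
    # kept as published.  See docs/methods.md.
    555: (0.031, 0.646),
    620: (0.002, 0.592),
}

ONE_PARAM_BBP: dict[int, tuple[float, float]] = {
    420: (0.011, 0.911),
    488: (0.008, 0.891),
    555: (0.007, 0.935),
    620: (0.005, 0.881),
}
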