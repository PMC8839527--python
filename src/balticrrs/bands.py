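"""Model wavelength bands.

The reflectance model is defined at exactly four wavelengths
(420, 488, 555 and 620 nm), dictated by the backscattering-meter
channels of the underlying field campaigns.  Every band-indexed
routine in the package validates its band against this set; there is
no spectral interpolation.
"""

from __future__ import annotations

from collections.abc import Sequence

BANDS: tuple[int, ...] = (420, 488, 555, 620)

#: OCP-100 radiometer channels [nm], used for nearest-band mapping.
RADIOMETER_CHANNELS: tuple[int, ...] = (412, 443, 490, 510, 555, 670, 683)


def validate_band(wavelength_nm: int) -> int:
    """Return ``wavelength_nm`` if it is one of the four model bands.

    Raises
    ------
    ValueError
        If the wavelength is not in :data:`BANDS`.
    """
    w = int(wavelength_nm)
    if w != wavelength_nm or w not in BANDS:
        raise ValueError(
            f"wavelength {wavelength_nm!r} nm is not a model band; "
            f"valid bands are {BANDS}"
        )
    return w


def nearest_band(wavelength_nm: int, channels: Sequence[int]) -> int:
    """Nearest-neighbour channel for a target wavelength.

    Ties are broken toward the shorter wavelength, deterministically.

    Parameters
    ----------
    wavelength_nm : int
        Target wavelength.
    channels : sequence of int
        Available instrument channels; must be non-empty.
    """
    if len(channels) == 0:
        raise ValueError("channel list must be non-empty")
    return min(sorted(channels), key=lambda c: abs(c - wavelength_nm))
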