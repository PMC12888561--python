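"""Shoot-level reflectance spectra: white-referencing, background
correction by linear spectral unmixing, and the PRI / REP indices.

A single seedling measured against a black background fills only part of
the spectroradiometer field of view, so the recorded signal is a linear
mixture of the seedling and the background spectra weighted by their
coverage fractions.  Given the seedling coverage ``C1`` estimated from a
photograph, the seedling endmember is recovered per band as

    R1(lambda) = (I(lambda) - C2 * R2(lambda)) / C1,   C2 = 1 - C1

where ``I`` is the measured reflectance and ``R2`` the averaged black
background reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "normalize_to_reflectance",
    "average_background",
    "unmix_seedling",
    "band_value",
    "pri",
    "rep",
]

_ROLES = frozenset(
    {"raw", "white", "background", "endmember", "measured", "corrected"}
)


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed spectral record.

    Parameters
    ----------
    wavelengths : array of float, nm, strictly increasing
    values : array of float, same length; reflectance fraction for
        reflectance roles, raw instrument counts for ``role='raw'`` /
        ``role='white'``.
    role : one of raw, white, background, endmember, measured, corrected
    metadata : free-form mapping (seedling id, DAT, coverage used, flags)
    """

    wavelengths: np.ndarray
    values: np.ndarray
    role: str = "measured"
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths, {vals.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(_ROLES)}")
        if self.role not in ("raw", "white") and not np.all(np.isfinite(vals)):
            raise ValueError("reflectance-role values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values, role=None, **extra_meta) -> "Spectrum":
        meta = {**self.metadata, **extra_meta}
        return Spectrum(self.wavelengths, values, role or self.role, meta)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.wavelengths, name="wavelength_nm"))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str = "measured", **metadata) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), role, metadata)


def _require_shared_grid(*spectra: Spectrum) -> None:
    ref = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.size != ref.size or not np.array_equal(s.wavelengths, ref):
            raise ValueError("spectra are not on a shared wavelength grid")


def normalize_to_reflectance(
    raw: Spectrum, white_raw: Spectrum, panel_reflectance: float = 0.99
) -> Spectrum:
    """Convert raw counts to reflectance against the white reference panel.

    The panel is assumed spectrally flat with known reflectance (0.99 for
    the usual Spectralon-type panel): ``R = raw / white * panel``.
    """
    _require_shared_grid(raw, white_raw)
    white = np.asarray(white_raw.values, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white reference contains non-positive values")
    return raw.with_values(raw.values / white * panel_reflectance, role="measured")


def average_background(spectra: Iterable[Spectrum]) -> Spectrum:
    """Per-band arithmetic mean of repeated black-background measurements."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one background spectrum")
    _require_shared_grid(*spectra)
    mean = np.mean([s.values for s in spectra], axis=0)
    return spectra[0].with_values(mean, role="background")


def unmix_seedling(
    measured: Spectrum,
    background: Spectrum,
    coverage,
    min_coverage: float = 0.10,
) -> Spectrum:
    """Recover the seedling endmember from a mixed measurement.

    ``coverage`` is either a seedling fraction in [0, 1] or an object with
    ``c_seedling`` / ``c_background`` attributes (a CoverageEstimate).
    Refuses spectra whose seedling coverage is below ``min_coverage``:
    the 1/C1 amplification makes such spectra unreliable.

    Corrected values may leave [0, 1] under noise; they are flagged in
    metadata (``out_of_range``), never clipped.
    """
    c1 = float(getattr(coverage, "c_seedling", coverage))
    if not 0.0 <= c1 <= 1.0:
        raise ValueError(f"seedling coverage {c1} outside [0, 1]")
    if c1 < min_coverage:
        raise ValueError(
            f"seedling coverage {c1:.3f} below the reliability floor "
            f"{min_coverage:.3f}; spectrum rejected"
        )
    _require_shared_grid(measured, background)
    c2 = 1.0 - c1
    r1 = (measured.values - c2 * background.values) / c1
    out_of_range = bool(np.any((r1 < 0) | (r1 > 1)))
    return measured.with_values(
        r1, role="corrected", c_seedling=c1, out_of_range=out_of_range
    )


def band_value(s: Spectrum, target_nm: float) -> float:
    """Reflectance at the grid wavelength nearest to ``target_nm``.

    Ties between two equidistant grid points resolve to the lower
    wavelength.  Raises if the target lies outside the grid range.
    """
    wl = s.wavelengths
    if not wl[0] <= target_nm <= wl[-1]:
        raise ValueError(
            f"target {target_nm} nm outside grid range [{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - target_nm)
    # argmin returns the first (lowest-wavelength) minimiser, which is the tie rule
    return float(s.values[int(np.argmin(dist))])


def pri(s: Spectrum) -> float:
    """Photochemical reflectance index, (R531 - R570) / (R531 + R570).

    Tracks xanthophyll-cycle de-epoxidation: lower values indicate more
    de-epoxidised pigments and stronger non-photochemical quenching.
    """
    r531 = band_value(s, 531.0)
    r570 = band_value(s, 570.0)
    denom = r531 + r570
    if denom == 0:
        raise ZeroDivisionError("PRI undefined: R531 + R570 = 0")
    return (r531 - r570) / denom


def rep(s: Spectrum) -> float:
    """Red edge position by linear four-point interpolation (nm).

    Uses bands 670, 700, 740 and 780 nm:

        Rre = (R670 + R780) / 2
        REP = 700 + 40 * (Rre - R700) / (R740 - R700)
    """
    r670 = band_value(s, 670.0)
    r700 = band_value(s, 700.0)
    r740 = band_value(s, 740.0)
    r780 = band_value(s, 780.0)
    if r740 == r700:
        raise ZeroDivisionError("REP undefined: R740 = R700")
    r_re = (r670 + r780) / 2.0
    return 700.0 + 40.0 * (r_re - r700) / (r740 - r700)
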