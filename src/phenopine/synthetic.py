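"""Synthetic study generator with known ground truth.

Emulates the measurement structure of a greenhouse drought experiment on
pine seedlings of two ecotypes: RGB photographs of a seedling over a
black background inside the spectroradiometer footprint, two-endmember
mixed reflectance spectra (350-2,500 nm), quenching-protocol
fluorescence traces, soil-drying calibration series, and AR1-correlated
repeated-measures trait tables with ecotype x treatment x time effects.

Every generator is a pure function of its specification and seed, and
every injected truth is recoverable by the matching analysis operation
at zero noise.  The spectral endmember is a piecewise parametric curve
(green-peak Gaussian, chlorophyll absorption well, logistic red-edge
sigmoid, NIR plateau, SWIR water features): no radiative-transfer
fidelity is attempted, only the qualitative index responses (red edge
shifts with chlorophyll, 531-nm reflectance drops with xanthophyll
de-epoxidation) are contractual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fluorescence import (
    FluorescenceFeatures,
    FluorescenceTrace,
    QuenchingProtocol,
    default_protocol,
)
from .imaging import circle_mask
from .spectra import Spectrum

__all__ = [
    "SceneTruth",
    "EndmemberModel",
    "FluorescenceTruth",
    "TraitEffectSpec",
    "SoilDryingData",
    "default_grid",
    "generate_seedling_image",
    "generate_endmember_spectrum",
    "generate_background_spectrum",
    "mix_measurement",
    "generate_fluorescence_trace",
    "generate_trait_dataset",
    "generate_soil_drying",
]

ECOTYPES = ("lowland", "upland")
TREATMENTS = ("C", "MD", "D")


def default_grid() -> np.ndarray:
    """The 1-nm resampled spectroradiometer grid, 350-2,500 nm (2,151 bands)."""
    return np.arange(350.0, 2501.0)


# ---------------------------------------------------------------------------
# scene images

@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one footprint photograph."""

    coverage_seedling: float
    image_size: tuple[int, int] = (96, 96)
    fov_center: tuple[float, float] = (48.0, 48.0)
    fov_radius: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coverage_seedling <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        h, w = self.image_size
        cy, cx = self.fov_center
        r = self.fov_radius
        if cy - r < -0.5 or cx - r < -0.5 or cy + r > h - 0.5 or cx + r > w - 0.5:
            raise ValueError("FOV circle does not fit inside the image")


def generate_seedling_image(truth: SceneTruth) -> tuple[np.ndarray, np.ndarray]:
    """Render an RGB photo plus boolean truth mask (True = seedling).

    Inside the footprint circle, exactly round(coverage * n_circle)
    pixels (a raster-order cap, i.e. the top of the disk) are seedling
    coloured; everything else is near-black background.  Colours are
    well separated so a pixel classifier can be exact.
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_size
    inside = circle_mask((h, w), truth.fov_center, truth.fov_radius)
    n_circle = int(inside.sum())
    n_seed = int(round(truth.coverage_seedling * n_circle))
    mask = np.zeros((h, w), dtype=bool)
    rows, cols = np.nonzero(inside)  # raster order
    mask[rows[:n_seed], cols[:n_seed]] = True

    img = np.empty((h, w, 3), dtype=np.uint8)
    n_bg = h * w - n_seed
    bg = rng.integers(2, 22, size=(n_bg, 3))
    fg = np.stack([
        rng.integers(30, 70, size=n_seed),
        rng.integers(100, 170, size=n_seed),
        rng.integers(30, 80, size=n_seed),
    ], axis=1)
    img[~mask] = bg
    img[mask] = fg
    return img, mask


# ---------------------------------------------------------------------------
# spectra

@dataclass(frozen=True)
class EndmemberModel:
    """Parametric green-vegetation endmember.

    ``chlorophyll_level`` deepens the red absorption well and pushes the
    red-edge inflection to longer wavelengths; ``carotenoid_level``
    darkens the blue region; ``xanthophyll_deepoxidation`` in [0, 1]
    depresses reflectance at 531 nm relative to 570 nm (lowering PRI).
    ``red_edge_midpoint`` is the inflection wavelength at reference
    chlorophyll level 1.
    """

    chlorophyll_level: float = 1.0
    carotenoid_level: float = 1.0
    xanthophyll_deepoxidation: float = 0.0
    red_edge_midpoint: float = 715.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chlorophyll_level < 0 or self.carotenoid_level < 0:
            raise ValueError("pigment levels must be non-negative")
        if not 0.0 <= self.xanthophyll_deepoxidation <= 1.0:
            raise ValueError("de-epoxidation must lie in [0, 1]")
        if not 680.0 < self.red_edge_midpoint < 760.0:
            raise ValueError("red_edge_midpoint must lie in (680, 760) nm")


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def generate_endmember_spectrum(
    model: EndmemberModel, grid: Optional[np.ndarray] = None
) -> Spectrum:
    """Deterministic parametric reflectance of the seedling endmember."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("grid must be strictly increasing")

    chl = model.chlorophyll_level
    # red edge: logistic rise from the red absorption well to the NIR plateau;
    # more chlorophyll -> inflection at longer wavelength
    midpoint = float(np.clip(model.red_edge_midpoint + 10.0 * np.tanh(chl - 1.0),
                             681.0, 759.0))
    red_floor = 0.03 + 0.05 / (1.0 + chl)          # deeper well with more chl
    nir = 0.45
    r = red_floor + (nir - red_floor) / (1.0 + np.exp(-(wl - midpoint) / 9.0))

    # visible structure on the short-wave side of the red edge
    vis = wl < midpoint
    green_peak = (0.10 / (1.0 + 0.3 * model.carotenoid_level)
                  + 0.04 / (1.0 + chl))
    r = r + green_peak * _gauss(wl, 552.0, 38.0) * vis
    r = r - 0.02 * model.carotenoid_level * _gauss(wl, 480.0, 30.0) * vis
    # xanthophyll de-epoxidation: local dip at 531 nm, 570 nm untouched
    r = r - 0.05 * model.xanthophyll_deepoxidation * _gauss(wl, 531.0, 10.0)

    # SWIR water absorption features and the gentle decline past the plateau
    r = r - 0.18 * _gauss(wl, 1450.0, 45.0) - 0.28 * _gauss(wl, 1940.0, 70.0)
    r = r - 0.10 / (1.0 + np.exp(-(wl - 2200.0) / 120.0))

    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        r = r + rng.normal(0.0, model.noise_sd, size=wl.size)
    return Spectrum(wl, np.clip(r, 0.0, 1.0), role="endmember")


def generate_background_spectrum(
    grid: Optional[np.ndarray] = None,
    level: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Low flat reflectance of the non-reflective black box coating."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    vals = np.full(wl.size, level)
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0.0, noise_sd, wl.size)
    return Spectrum(wl, np.clip(vals, 0.0, 1.0), role="background")


def mix_measurement(
    endmember: Spectrum,
    background: Spectrum,
    c1: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Linear two-surface mixture I = c1*R1 + (1-c1)*R2 (+ noise)."""
    if not 0.0 <= c1 <= 1.0:
        raise ValueError(f"coverage fraction {c1} outside [0, 1]")
    if not np.array_equal(endmember.wavelengths, background.wavelengths):
        raise ValueError("endmember and background grids differ")
    vals = c1 * endmember.values + (1.0 - c1) * background.values
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0.0, noise_sd, vals.size)
    return Spectrum(endmember.wavelengths, vals, role="measured",
                    metadata={"c_seedling_true": c1})


# ---------------------------------------------------------------------------
# fluorescence

@dataclass(frozen=True)
class FluorescenceTruth:
    """Known phase-level fluorescence levels (arbitrary units)."""

    F0: float = 0.20
    FM: float = 1.00
    FP: float = 0.90
    FM_L: tuple[float, ...] = (0.75, 0.72, 0.70, 0.69, 0.68)
    Ft_L: tuple[float, ...] = (0.45, 0.40, 0.37, 0.35, 0.34)
    FM_D: tuple[float, ...] = (0.78, 0.85, 0.90)
    Ft_D: tuple[float, ...] = (0.30, 0.28, 0.26)
    F0_Lss: float = 0.17
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.FM >= self.F0 > 0:
            raise ValueError("need FM >= F0 > 0")
        if not self.FM >= self.FP >= self.F0:
            raise ValueError("need FM >= FP >= F0")
        if self.F0_Lss <= 0:
            raise ValueError("F0_Lss must be positive")
        for fm, ft in zip(self.FM_L, self.Ft_L):
            if not (fm >= ft > 0 and self.FP >= ft):
                raise ValueError("light phases need FM_Ln >= Ft_Ln > 0 and FP >= Ft_Ln")
        for fm, ft in zip(self.FM_D, self.Ft_D):
            if not fm >= ft > 0:
                raise ValueError("dark phases need FM_Dn >= Ft_Dn > 0")
        if self.FM < self.FM_L[-1]:
            raise ValueError("need FM >= FM_Lss")

    def features(self) -> FluorescenceFeatures:
        return FluorescenceFeatures(
            self.F0, self.FM, self.FP, tuple(self.FM_L), tuple(self.Ft_L),
            tuple(self.FM_D), tuple(self.Ft_D), self.F0_Lss,
        )


def generate_fluorescence_trace(
    truth: FluorescenceTruth,
    protocol: Optional[QuenchingProtocol] = None,
    sample_hz: float = 20.0,
) -> FluorescenceTrace:
    """Piecewise-linear trace whose annotated windows equal the truth levels.

    Sample times include every anchor point, so the feature extractor
    recovers the truth exactly at zero noise.
    """
    protocol = protocol or default_protocol()
    if len(truth.FM_L) != len(protocol.light_phases):
        raise ValueError("truth has wrong number of light phases for protocol")
    if len(truth.FM_D) != len(protocol.dark_phases):
        raise ValueError("truth has wrong number of dark phases for protocol")

    eps = 1e-6
    anchors: list[tuple[float, float]] = []

    init = protocol.initial_dark
    anchors += [(init.start, truth.F0), (init.pulse_start - eps, truth.F0),
                (init.pulse_start, truth.FM), (init.pulse_end, truth.FM),
                (init.pulse_end + eps, truth.F0)]

    n_dark = 0
    i_light = 0
    for ph in protocol.phases[1:]:
        if ph.kind == "light":
            fm, ft = truth.FM_L[i_light], truth.Ft_L[i_light]
            tail_lo = ph.tail_window[0]
            if i_light == 0:
                peak_t = ph.start + 0.15 * ph.duration
                anchors += [(ph.start, truth.F0), (peak_t, truth.FP),
                            (tail_lo, ft)]
            else:
                anchors += [(tail_lo, ft)]
            anchors += [(ph.pulse_start - eps, ft), (ph.pulse_start, fm),
                        (ph.pulse_end, fm), (ph.pulse_end + eps, ft)]
            i_light += 1
        else:
            fm, ft = truth.FM_D[n_dark], truth.Ft_D[n_dark]
            tail_lo = ph.tail_window[0]
            win = protocol.f0lss_window
            if win is not None and ph.start <= win[0] < ph.end:
                anchors += [(win[0], truth.F0_Lss), (win[1] - eps, truth.F0_Lss),
                            (win[1], truth.F0_Lss)]
            anchors += [(tail_lo, ft), (ph.pulse_start - eps, ft),
                        (ph.pulse_start, fm), (ph.pulse_end, fm),
                        (ph.pulse_end + eps, ft)]
            n_dark += 1
    anchors.append((protocol.phases[-1].end, truth.Ft_D[-1]))

    anchor_t = np.array([a[0] for a in anchors])
    anchor_v = np.array([a[1] for a in anchors])
    order = np.argsort(anchor_t, kind="stable")
    anchor_t, anchor_v = anchor_t[order], anchor_v[order]

    grid = np.arange(0.0, protocol.total_duration + 0.5 / sample_hz, 1.0 / sample_hz)
    # round to 0.1 us so CSV round trips cannot collapse two samples
    t = np.unique(np.round(np.concatenate([grid, anchor_t]), 7))
    f = np.interp(t, anchor_t, anchor_v)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        f = f + rng.normal(0.0, truth.noise_sd, f.size)
    return FluorescenceTrace(t, np.maximum(f, 0.0))


# ---------------------------------------------------------------------------
# trait tables

def _check_sum_zero(arr: np.ndarray, name: str, axis=None) -> None:
    s = arr.sum(axis=axis)
    if not np.all(np.abs(s) < 1e-8):
        raise ValueError(f"{name} effects must sum to zero within each factor")


@dataclass(frozen=True)
class TraitEffectSpec:
    """Generating model for the repeated-measures trait table.

    A sum-to-zero-coded factorial of ecotype (2) x treatment (3) x DAT
    (T) with a block x DAT random intercept (sd ``block_dat_sd``) and,
    per seedling across DATs, heterogeneous-AR1 residuals: correlation
    ``ar1_rho``^|i-j| scaled by per-DAT standard deviations.
    """

    grand_mean: float = 10.0
    ecotype_effects: tuple[float, float] = (0.0, 0.0)
    treatment_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dat_effects: tuple[float, ...] = (0.0, 0.0)
    ecotype_treatment: Optional[np.ndarray] = None   # (2, 3)
    treatment_dat: Optional[np.ndarray] = None        # (3, T)
    ecotype_dat: Optional[np.ndarray] = None          # (2, T)
    ecotype_treatment_dat: Optional[np.ndarray] = None  # (2, 3, T)
    block_dat_sd: float = 0.5
    ar1_rho: float = 0.6
    per_dat_sd: Optional[tuple[float, ...]] = None
    n_blocks: int = 5
    n_per_cell: int = 15
    seed: int = 0
    trait: str = "trait"

    @property
    def n_dats(self) -> int:
        return len(self.dat_effects)

    @property
    def sigma_d(self) -> np.ndarray:
        if self.per_dat_sd is None:
            return np.ones(self.n_dats)
        return np.asarray(self.per_dat_sd, dtype=float)

    def __post_init__(self):
        T = self.n_dats
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if T < 2 and self.ar1_rho != 0.0:
            raise ValueError("need at least 2 DATs for a non-zero AR1 correlation")
        if self.block_dat_sd < 0 or np.any(self.sigma_d < 0):
            raise ValueError("standard deviations must be non-negative")
        if self.sigma_d.size != T:
            raise ValueError("per_dat_sd length must equal the number of DATs")
        _check_sum_zero(np.asarray(self.ecotype_effects), "ecotype")
        _check_sum_zero(np.asarray(self.treatment_effects), "treatment")
        _check_sum_zero(np.asarray(self.dat_effects), "dat")
        for name, arr, shape in [
            ("ecotype x treatment", self.ecotype_treatment, (2, 3)),
            ("treatment x dat", self.treatment_dat, (3, T)),
            ("ecotype x dat", self.ecotype_dat, (2, T)),
            ("ecotype x treatment x dat", self.ecotype_treatment_dat, (2, 3, T)),
        ]:
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} effects must have shape {shape}")
            for ax in range(arr.ndim):
                _check_sum_zero(arr, name, axis=ax)

    def cell_mean(self, i_eco: int, i_trt: int, i_dat: int) -> float:
        m = (self.grand_mean + self.ecotype_effects[i_eco]
             + self.treatment_effects[i_trt] + self.dat_effects[i_dat])
        if self.ecotype_treatment is not None:
            m += self.ecotype_treatment[i_eco, i_trt]
        if self.treatment_dat is not None:
            m += self.treatment_dat[i_trt, i_dat]
        if self.ecotype_dat is not None:
            m += self.ecotype_dat[i_eco, i_dat]
        if self.ecotype_treatment_dat is not None:
            m += self.ecotype_treatment_dat[i_eco, i_trt, i_dat]
        return float(m)


def _ar1_corr(rho: float, T: int) -> np.ndarray:
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_trait_dataset(spec: TraitEffectSpec) -> pd.DataFrame:
    """Simulate the long-format trait table under the mixed model.

    Seedlings are assigned to blocks round-robin within each ecotype x
    treatment cell; each seedling is observed at every DAT.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_dats
    D = np.diag(spec.sigma_d)
    R = D @ _ar1_corr(spec.ar1_rho, T) @ D
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:  # degenerate (zero-variance) residuals
        L = np.linalg.cholesky(R + 1e-30 * np.eye(T))
    u_bd = rng.normal(0.0, spec.block_dat_sd, size=(spec.n_blocks, T))

    rows = []
    sid = 0
    for i_eco, eco in enumerate(ECOTYPES):
        for i_trt, trt in enumerate(TREATMENTS):
            for j in range(spec.n_per_cell):
                block = j % spec.n_blocks
                e = L @ rng.standard_normal(T)
                for i_dat in range(T):
                    rows.append((
                        f"S{sid:03d}", eco, trt, block, i_dat + 1, spec.trait,
                        spec.cell_mean(i_eco, i_trt, i_dat)
                        + u_bd[block, i_dat] + e[i_dat],
                    ))
                sid += 1
    return pd.DataFrame(
        rows,
        columns=["seedling_id", "ecotype", "treatment", "block", "dat",
                 "trait", "value"],
    )


# ---------------------------------------------------------------------------
# soil drying

@dataclass
class SoilDryingData:
    """Synthetic drying-down experiment with injected sensor truth."""

    calibration: pd.DataFrame       # columns: time_d, raw, vwc
    retention: pd.DataFrame         # columns: vwc, potential_mpa
    truth: dict


def generate_soil_drying(
    seed: int = 0,
    n_samples: int = 120,
    vwc_sat: float = 0.60,
    vwc_res: float = 0.04,
    tau_days: float = 18.0,
    sensor_gain: float = 1400.0,
    sensor_offset: float = 80.0,
    vwc_pwp: float = 0.204,
    noise_sd: float = 0.0,
) -> SoilDryingData:
    """Exponential drying of a saturated substrate under periodic weighing.

    Raw sensor output is linear in VWC (gain/offset in arbitrary
    electrical units); soil water potential follows a log-linear
    retention curve pinned to -1.5 MPa at ``vwc_pwp`` (default the
    study's 0.204 VWC fraction).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 4.0 * tau_days, n_samples)
    vwc = vwc_res + (vwc_sat - vwc_res) * np.exp(-t / tau_days)
    raw = sensor_offset + sensor_gain * vwc
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd * sensor_gain, raw.size)
    potential = -1.5 * np.exp(25.0 * (vwc_pwp - vwc))
    return SoilDryingData(
        calibration=pd.DataFrame({"time_d": t, "raw": raw, "vwc": vwc}),
        retention=pd.DataFrame({"vwc": vwc, "potential_mpa": potential}),
        truth={
            "cal_slope": 1.0 / sensor_gain,
            "cal_intercept": -sensor_offset / sensor_gain,
            "vwc_pwp": vwc_pwp,
        },
    )
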