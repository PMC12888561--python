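"""Quenching-protocol chlorophyll fluorescence analysis.

Models the 192-s imaging-fluorometer quenching sequence (dark adaptation
with a first saturation pulse, five actinic light phases and three dark
relaxation phases, each closed by a saturation pulse), extracts the
phase-level fluorescence levels from a trace, and computes the standard
quenching parameters (QY_max = Fv/Fm, light- and dark-phase quantum
yields, steady-state NPQ and the Rfd vitality index).

Window conventions (configurable on the protocol):

* F0 is the mean of the dark-adapted segment before the first pulse.
* FM is the maximum inside the first saturation pulse.
* FP is the induction maximum of the first light phase outside pulses.
* FM_Ln / FM_Dn are the maxima inside the n-th phase's pulse window.
* Ft_* are means of the pre-pulse tail (last 10 % of the phase before
  the pulse).
* Steady state ("Lss") is the last actinic light phase.
* F0_Lss comes from a dedicated far-red window at the start of the first
  relaxation phase when the protocol defines one; otherwise it is
  approximated as F0 * FM_Lss / FM and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "QuenchingProtocol",
    "FluorescenceTrace",
    "FluorescenceFeatures",
    "FluorescenceParameters",
    "default_protocol",
    "extract_features",
    "compute_parameters",
]

TAIL_FRACTION = 0.10  # pre-pulse tail used for Ft_* means


@dataclass(frozen=True)
class Phase:
    """One protocol phase with its saturation-pulse window (absolute s)."""

    kind: str  # initial_dark | light | dark
    start: float
    duration: float
    pulse_start: float
    pulse_duration: float = 0.8

    def __post_init__(self):
        if self.kind not in ("initial_dark", "light", "dark"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        end = self.start + self.duration
        if not (self.start <= self.pulse_start
                and self.pulse_start + self.pulse_duration <= end + 1e-9):
            raise ValueError("saturation pulse window outside its phase")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def pulse_end(self) -> float:
        return self.pulse_start + self.pulse_duration

    @property
    def tail_window(self) -> tuple[float, float]:
        """Pre-pulse tail: last TAIL_FRACTION of the phase before the pulse."""
        lo = max(self.start, self.pulse_start - TAIL_FRACTION * self.duration)
        return lo, self.pulse_start


@dataclass(frozen=True)
class QuenchingProtocol:
    """Ordered phase schedule of the quenching measurement.

    The study protocol lasts 192 s with one initial dark phase, five
    actinic light phases and three dark relaxation phases; the pulse
    wavelength (455 nm) and intensity (4,900 umol photons m-2 s-1) are
    recorded for provenance only.
    """

    phases: tuple[Phase, ...]
    f0lss_window: Optional[tuple[float, float]] = None
    pulse_wavelength_nm: float = 455.0
    pulse_intensity_umol: float = 4900.0

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))
        t = self.phases[0].start
        for ph in self.phases:
            if abs(ph.start - t) > 1e-9:
                raise ValueError("phases must be contiguous")
            t = ph.end

    @property
    def total_duration(self) -> float:
        return self.phases[-1].end - self.phases[0].start

    @property
    def light_phases(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.kind == "light")

    @property
    def dark_phases(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.kind == "dark")

    @property
    def initial_dark(self) -> Phase:
        return self.phases[0]


def default_protocol() -> QuenchingProtocol:
    """192-s schedule: 32 s initial dark, 5 x 20 s light, 3 x 20 s dark.

    Exact phase durations are an instrument configuration; these defaults
    reproduce the total length and phase counts of the study protocol.
    Every phase ends with a saturation pulse; a 1-s far-red window at the
    start of the first relaxation phase provides F0_Lss.
    """
    phases = [Phase("initial_dark", 0.0, 32.0, pulse_start=30.0)]
    t = 32.0
    for _ in range(5):
        phases.append(Phase("light", t, 20.0, pulse_start=t + 19.0))
        t += 20.0
    for _ in range(3):
        phases.append(Phase("dark", t, 20.0, pulse_start=t + 19.0))
        t += 20.0
    assert t == 192.0
    return QuenchingProtocol(tuple(phases), f0lss_window=(132.0, 133.0))


@dataclass(frozen=True)
class FluorescenceTrace:
    """Sampled fluorescence induction trace (arbitrary units)."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    phase_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise ValueError("time and fluorescence lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluorescence values must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fluorescence", f)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.time_s, "fluorescence": self.fluorescence})
        if self.phase_labels is not None:
            df["phase_label"] = self.phase_labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        labels = df["phase_label"].to_numpy() if "phase_label" in df else None
        return cls(df["time_s"].to_numpy(), df["fluorescence"].to_numpy(), labels)


@dataclass
class FluorescenceFeatures:
    """Phase-level fluorescence levels extracted from a trace."""

    F0: float
    FM: float
    FP: float
    FM_L: tuple[float, ...]
    Ft_L: tuple[float, ...]
    FM_D: tuple[float, ...]
    Ft_D: tuple[float, ...]
    F0_Lss: float
    f0lss_approximated: bool = False

    @property
    def FM_Lss(self) -> float:
        return self.FM_L[-1]

    @property
    def Ft_Lss(self) -> float:
        return self.Ft_L[-1]

    def scaled(self, c: float) -> "FluorescenceFeatures":
        return FluorescenceFeatures(
            c * self.F0, c * self.FM, c * self.FP,
            tuple(c * v for v in self.FM_L), tuple(c * v for v in self.Ft_L),
            tuple(c * v for v in self.FM_D), tuple(c * v for v in self.Ft_D),
            c * self.F0_Lss, self.f0lss_approximated,
        )


@dataclass
class FluorescenceParameters:
    """Quenching parameters; all are unit-free ratios of feature levels."""

    QY_max: float
    FvFm_Ln: tuple[float, ...]
    FvFm_Lss: float
    FvFm_Dn: tuple[float, ...]
    QY_Ln: tuple[float, ...]
    QY_Lss: float
    QY_Dn: tuple[float, ...]
    NPQ_Lss: float
    Rfd_Lss: float

    def as_dict(self) -> dict[str, float]:
        out = {"QY_max": self.QY_max, "FvFm_Lss": self.FvFm_Lss,
               "QY_Lss": self.QY_Lss, "NPQ_Lss": self.NPQ_Lss,
               "Rfd_Lss": self.Rfd_Lss}
        for i, v in enumerate(self.FvFm_Ln, 1):
            out[f"FvFm_L{i}"] = v
        for i, v in enumerate(self.FvFm_Dn, 1):
            out[f"FvFm_D{i}"] = v
        for i, v in enumerate(self.QY_Ln, 1):
            out[f"QY_L{i}"] = v
        for i, v in enumerate(self.QY_Dn, 1):
            out[f"QY_D{i}"] = v
        return out


def _window_values(
    trace: FluorescenceTrace, lo: float, hi: float, what: str, closed: bool = False
) -> np.ndarray:
    """Samples in [lo, hi] (closed, for pulse maxima) or [lo, hi) (means)."""
    sel = trace.time_s >= lo - 1e-9
    if closed:
        sel &= trace.time_s <= hi + 1e-9
    else:
        sel &= trace.time_s < hi - 1e-9
    vals = trace.fluorescence[sel]
    if vals.size == 0:
        raise ValueError(f"no trace samples inside the {what} window [{lo}, {hi}] s")
    return vals


def extract_features(
    trace: FluorescenceTrace, protocol: QuenchingProtocol
) -> FluorescenceFeatures:
    """Extract the phase-level fluorescence levels defined by ``protocol``."""
    if trace.time_s[-1] < protocol.total_duration - 1e-6:
        raise ValueError(
            f"trace ends at {trace.time_s[-1]:.1f} s, shorter than the "
            f"{protocol.total_duration:.0f} s protocol"
        )
    init = protocol.initial_dark
    f0 = float(np.mean(_window_values(trace, init.start, init.pulse_start, "F0")))
    fm = float(np.max(
        _window_values(trace, init.pulse_start, init.pulse_end, "FM pulse", closed=True)
    ))

    first_light = protocol.light_phases[0]
    sel = ((trace.time_s >= first_light.start)
           & (trace.time_s < first_light.pulse_start))
    if not np.any(sel):
        raise ValueError("no samples in the first light phase outside its pulse")
    fp = float(np.max(trace.fluorescence[sel]))

    def pulse_max(ph: Phase) -> float:
        return float(np.max(
            _window_values(trace, ph.pulse_start, ph.pulse_end, "pulse", closed=True)
        ))

    def tail_mean(ph: Phase) -> float:
        lo, hi = ph.tail_window
        return float(np.mean(_window_values(trace, lo, hi, "tail")))

    fm_l = tuple(pulse_max(p) for p in protocol.light_phases)
    ft_l = tuple(tail_mean(p) for p in protocol.light_phases)
    fm_d = tuple(pulse_max(p) for p in protocol.dark_phases)
    ft_d = tuple(tail_mean(p) for p in protocol.dark_phases)

    if protocol.f0lss_window is not None:
        lo, hi = protocol.f0lss_window
        f0_lss = float(np.mean(_window_values(trace, lo, hi, "F0_Lss")))
        approx = False
    else:
        f0_lss = f0 * fm_l[-1] / fm
        approx = True

    return FluorescenceFeatures(f0, fm, fp, fm_l, ft_l, fm_d, ft_d, f0_lss, approx)


def _ratio(num: float, den: float, name: str) -> float:
    if den <= 0:
        raise ZeroDivisionError(f"{name} undefined: denominator {den} <= 0")
    return num / den


def compute_parameters(f: FluorescenceFeatures) -> FluorescenceParameters:
    """Apply the nine quenching-parameter formulas to extracted levels.

    QY_max = (FM - F0)/FM; FvFm_Ln = (FM_Ln - F0_Lss)/FM_Ln;
    FvFm_Lss = (FM_Lss - F0_Lss)/FM_Lss; FvFm_Dn = (FM_Dn - F0_Lss)/FM_Dn;
    QY_Ln = (FM_Ln - Ft_Ln)/FM_Ln; QY_Lss = (FM_Lss - Ft_Lss)/FM_Lss;
    QY_Dn = (FM_Dn - Ft_Dn)/FM_Dn; NPQ_Lss = (FM - FM_Lss)/FM_Lss;
    Rfd_Lss = (FP - Ft_Lss)/Ft_Lss.
    """
    qy_max = _ratio(f.FM - f.F0, f.FM, "QY_max")
    fvfm_ln = tuple(
        _ratio(fm - f.F0_Lss, fm, f"FvFm_L{i}") for i, fm in enumerate(f.FM_L, 1)
    )
    fvfm_lss = _ratio(f.FM_Lss - f.F0_Lss, f.FM_Lss, "FvFm_Lss")
    fvfm_dn = tuple(
        _ratio(fm - f.F0_Lss, fm, f"FvFm_D{i}") for i, fm in enumerate(f.FM_D, 1)
    )
    qy_ln = tuple(
        _ratio(fm - ft, fm, f"QY_L{i}")
        for i, (fm, ft) in enumerate(zip(f.FM_L, f.Ft_L), 1)
    )
    qy_lss = _ratio(f.FM_Lss - f.Ft_Lss, f.FM_Lss, "QY_Lss")
    qy_dn = tuple(
        _ratio(fm - ft, fm, f"QY_D{i}")
        for i, (fm, ft) in enumerate(zip(f.FM_D, f.Ft_D), 1)
    )
    npq = _ratio(f.FM - f.FM_Lss, f.FM_Lss, "NPQ_Lss")
    rfd = _ratio(f.FP - f.Ft_Lss, f.Ft_Lss, "Rfd_Lss")
    return FluorescenceParameters(
        qy_max, fvfm_ln, fvfm_lss, fvfm_dn, qy_ln, qy_lss, qy_dn, npq, rfd
    )
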