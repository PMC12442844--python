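"""Raw-signal to whole-fruit ethanol concentration, per assay method.

Three field methods are supported:

* **MOS** — a metal-oxide-semiconductor gas sensor read over the headspace
  of diluted fruit slurry; its response is log-linear in concentration, so
  the calibration line predicts log concentration and the back-transform is
  exponential, followed by dilution scaling.
* **GC** — a portable gas chromatograph producing a voltage trace; the
  ethanol peak (onset expected 50-54 s after injection) is integrated
  trapezoidally above a baseline estimated from the pre-peak signal, with
  the peak end taken where the signal returns to within 1.2 mV of baseline.
  Areas (mV*min) are converted through an identity-transform calibration.
* **Cr2** — dichromate colorimetry of slurry supernatant at 580 nm; the
  calibrated supernatant concentration is scaled back to the whole fruit by
  the dilution factor and by one minus the dry-mass fraction of the pellet.

All concentrations are % w/w; negative predictions clamp to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationFit, predict_concentration
from .errors import (
    InconsistentMeasurementError,
    InvalidArgumentError,
    MethodMismatchError,
)

GC_WINDOW_START = 50.0  #: s after injection, earliest expected peak onset
GC_WINDOW_END = 54.0  #: s after injection, latest expected peak onset
GC_RETURN_THRESHOLD = 1.2  #: mV above baseline, peak start/end criterion


@dataclass(frozen=True)
class MosReading:
    sample_id: str
    voltage: float
    dilution_factor: float = 1.0
    temperature: float | None = None  # recorded only, not modelled
    equilibration_time: float | None = None  # hours, recorded only

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise InvalidArgumentError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class GcTrace:
    """A chromatogram: signal (mV) sampled at strictly increasing times (s)."""

    sample_id: str
    times: np.ndarray
    signal: np.ndarray
    injection_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.size < 2:
            raise InvalidArgumentError("trace needs >= 2 samples")
        if s.shape != t.shape:
            raise InvalidArgumentError("times and signal lengths differ")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")


@dataclass(frozen=True)
class Cr2Reading:
    sample_id: str
    absorbance: float  # optical absorbance at 580 nm
    dilution_factor: float = 2.0
    dry_mass_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise InvalidArgumentError("dilution_factor must be >= 1")
        if not 0.0 <= self.dry_mass_fraction < 1.0:
            raise InvalidArgumentError("dry_mass_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PeakIntegration:
    start_time: float
    end_time: float
    baseline: float
    area: float  # mV*min, >= 0

    def __post_init__(self) -> None:
        if self.start_time >= self.end_time:
            raise InvalidArgumentError("start_time must precede end_time")
        if self.area < 0:
            raise InvalidArgumentError("area must be nonnegative")


def mos_to_concentration(reading: MosReading, fit: CalibrationFit) -> float:
    """exp(slope*voltage + intercept) scaled by the dilution factor."""
    if fit.transform != "log_concentration":
        raise MethodMismatchError("MOS conversion requires a log_concentration fit")
    return predict_concentration(fit, reading.voltage, reading.dilution_factor)


def gc_integrate_peak(
    trace: GcTrace,
    window_start: float = GC_WINDOW_START,
    window_end: float = GC_WINDOW_END,
    return_threshold: float = GC_RETURN_THRESHOLD,
) -> PeakIntegration:
    """Locate and integrate the ethanol peak of a chromatogram.

    The baseline is the median signal over [0, window_start - 5) s (times
    relative to injection).  The peak starts at the first time within
    [window_start, window_end] where the signal exceeds baseline +
    return_threshold, falling back to the window start if it never does;
    it ends at the first sample after the peak maximum where the signal has
    returned to baseline + return_threshold or below (trace end if never).
    The area is the trapezoidal integral of (signal - baseline) over
    [start, end], clamped at zero and reported in mV*min.
    """
    t = trace.times - trace.injection_time
    s = trace.signal
    if t[-1] <= window_end:
        raise InvalidArgumentError("trace ends before the peak-onset window")

    pre = s[(t >= 0) & (t < window_start - 5.0)]
    if pre.size == 0:
        raise InvalidArgumentError("no pre-window samples to estimate baseline")
    baseline = float(np.median(pre))
    thresh = baseline + return_threshold

    in_window = np.flatnonzero((t >= window_start) & (t <= window_end))
    if in_window.size == 0:
        raise InvalidArgumentError("no samples inside the peak-onset window")
    above = in_window[s[in_window] > thresh]
    i_start = int(above[0]) if above.size else int(in_window[0])

    i_max = i_start + int(np.argmax(s[i_start:]))
    after = np.flatnonzero(s[i_max:] <= thresh)
    i_end = i_max + int(after[0]) if after.size else s.size - 1
    if i_end <= i_start:
        i_end = min(i_start + 1, s.size - 1)

    seg = slice(i_start, i_end + 1)
    area_mv_s = float(np.trapezoid(s[seg] - baseline, t[seg]))
    return PeakIntegration(
        start_time=float(t[i_start]),
        end_time=float(t[i_end]),
        baseline=baseline,
        area=max(0.0, area_mv_s) / 60.0,
    )


def gc_to_concentration(
    integration: PeakIntegration,
    fit: CalibrationFit,
    dilution_factor: float = 1.0,
) -> float:
    """max(0, slope*area + intercept), optionally scaled by dilution.

    GC samples are typically run undiluted (slurry water content suffices),
    so the default dilution factor is 1.
    """
    if fit.transform != "identity":
        raise MethodMismatchError("GC conversion requires an identity-transform fit")
    if integration.area < 0:
        raise InvalidArgumentError("negative peak area")
    return predict_concentration(fit, integration.area, dilution_factor)


def dry_mass_fraction(
    pellet_dry_mass: float, total_centrifuged_mass: float, dilution_factor: float
) -> float:
    """Dry-mass fraction of the fruit: (pellet / total mass) * dilution.

    The centrifuged slurry was diluted, so the pellet's share of the
    original fruit is the measured mass ratio scaled back up by the
    dilution factor.  Must come out below 1.
    """
    if total_centrifuged_mass <= 0:
        raise InvalidArgumentError("total_centrifuged_mass must be > 0")
    if not 0 <= pellet_dry_mass <= total_centrifuged_mass:
        raise InvalidArgumentError("pellet mass must lie in [0, total mass]")
    if dilution_factor < 1:
        raise InvalidArgumentError("dilution_factor must be >= 1")
    frac = pellet_dry_mass / total_centrifuged_mass * dilution_factor
    if frac >= 1.0:
        raise InconsistentMeasurementError(
            f"dry mass fraction {frac:.3f} >= 1: masses and dilution inconsistent"
        )
    return frac


def cr2_to_concentration(reading: Cr2Reading, fit: CalibrationFit) -> float:
    """Supernatant concentration scaled to the whole fruit.

    max(0, slope*absorbance + intercept) * dilution * (1 - dry mass).
    """
    if fit.transform != "identity":
        raise MethodMismatchError("Cr2 conversion requires an identity-transform fit")
    supernatant = predict_concentration(fit, reading.absorbance, 1.0)
    return supernatant * reading.dilution_factor * (1.0 - reading.dry_mass_fraction)
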