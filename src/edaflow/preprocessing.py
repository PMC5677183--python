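"""Low-pass FIR filtering of the raw EDA recording.

EDA carries no useful information above ~1.5 Hz (the upper edge of the
phasic band), so the raw 10 Hz device signal is cleaned with a 1.5 Hz
cut-off linear-phase FIR filter of order 32, applied as a causal discrete
convolution

    y_hat[n] = sum_{i=0}^{N} C_i * y[n-i]

The design method is a Hamming-windowed sinc normalised to unity DC gain;
edge handling is causal with zero pre-padding, so the first N output
samples are a start-up transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .acquisition import EDARecording

__all__ = ["FIRFilter", "design_lowpass", "apply_filter"]


@dataclass(frozen=True)
class FIRFilter:
    """A linear-phase FIR low-pass filter.

    ``coefficients`` has length ``order + 1``, is symmetric, and sums to 1
    (unity DC gain).
    """

    coefficients: np.ndarray
    order: int
    cutoff: float
    fs: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)
        if len(c) != self.order + 1:
            raise ValueError("coefficient length must equal order + 1")
        if not np.allclose(c, c[::-1], atol=1e-12):
            raise ValueError("coefficients must be symmetric (linear phase)")
        if abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("coefficients must sum to 1 (unity DC gain)")

    @property
    def group_delay_samples(self) -> float:
        return self.order / 2.0

    def response_at(self, freqs_hz: np.ndarray | float) -> np.ndarray:
        """Complex frequency response at the given frequencies (Hz)."""
        _, h = sps.freqz(self.coefficients, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return h

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "cutoff": self.cutoff,
            "fs": self.fs,
            "taps": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FIRFilter":
        return cls(np.asarray(d["taps"], dtype=float), d["order"], d["cutoff"], d["fs"])


def design_lowpass(order: int = 32, cutoff: float = 1.5, fs: float = 10.0) -> FIRFilter:
    """Design the default Hamming-windowed-sinc low-pass filter.

    Parameters mirror the device pipeline: order 32, 1.5 Hz cut-off at a
    10 Hz sampling rate.  Taps are renormalised so they sum exactly to 1.
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    taps = sps.firwin(order + 1, cutoff, window="hamming", fs=fs)
    taps = taps / taps.sum()
    return FIRFilter(coefficients=taps, order=order, cutoff=cutoff, fs=fs)


def apply_filter(rec: EDARecording, filt: FIRFilter, compensate_delay: bool = True) -> EDARecording:
    """Apply the FIR filter as a causal convolution with zero pre-padding.

    The output is aligned to the input timebase and has the same length.
    With ``compensate_delay`` (the default) the constant group delay of
    N/2 samples — 1.6 s for the order-32 filter at 10 Hz — is removed by
    shifting the output forward (the tail is held at the last value).
    Compensation matters downstream: the +1 to +6 s SCR windows are
    defined in stimulus time, and an uncompensated 1.6 s lag pushes the
    response peak to the window edge, where the baseline spline absorbs
    it.  Set it to False to reproduce strictly causal output.

    For conductance recordings the output is floored at 0 μS: the filter's
    negative side lobes can push the start-up transient marginally below
    zero, which is not physical.
    """
    if len(rec) <= filt.order:
        raise ValueError(
            f"recording length {len(rec)} must exceed filter order {filt.order}"
        )
    y = sps.lfilter(filt.coefficients, [1.0], rec.samples)
    if compensate_delay:
        shift = filt.order // 2
        y = np.concatenate([y[shift:], np.full(shift, y[-1])])
    unit = rec.unit if rec.unit != "adc_code" else "adc_code"
    return EDARecording(samples=np.maximum(y, 0.0) if rec.unit == "microsiemens" else y,
                        fs=rec.fs, unit=unit,
                        subject_id=rec.subject_id, condition=rec.condition)
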