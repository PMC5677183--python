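"""Temporal, morphological and frequency features of the phasic (SCR) series.

Features are computed per condition segment (the 70 s block of one
condition), on the deconvolved driver r[n]:

temporal
    MSC, SDSC         mean and standard deviation of r
    MASC, MISC, DRSC  maximum, minimum and dynamic range (MASC - MISC)
    FMSC, FDSC        mean / std of the first difference
    SMSC, SSDSC       mean / std of the second difference (renamed from the
                      source acronyms, which reuse SDSC for both the signal
                      and the second-derivative std)
morphological / statistical
    ALSC              arc length, sum of sqrt(1 + (r[n]-r[n-1])^2)
    INSC              integral, sum of |r[n]|
    APSC              normalised average power, mean of r^2
    RMSC              root mean square, sqrt(APSC)
    ILSC, ELSC        area-perimeter INSC/ALSC and energy-perimeter RMSC/ALSC
    SKSC, KUSC        skewness and (non-excess) kurtosis
    MOSC              central moment of configurable order (default 3)
frequency
    F1SC, F2SC, F3SC  periodogram power in [0.1,0.2), [0.2,0.3), [0.3,0.4) Hz

Derivatives are plain first differences in per-sample units by default;
``derivative_scale="per_second"`` multiplies them by fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Literal, Optional

import numpy as np

__all__ = ["Segment", "FeatureVector", "FEATURE_NAMES",
           "temporal_features", "arc_length", "amplitude_features",
           "perimeter_ratios", "shape_statistics", "band_powers",
           "extract_all"]

FEATURE_NAMES = (
    "MSC", "SDSC", "MASC", "MISC", "DRSC", "FMSC", "FDSC", "SMSC", "SSDSC",
    "ALSC", "INSC", "APSC", "RMSC", "ILSC", "ELSC", "SKSC", "KUSC", "MOSC",
    "F1SC", "F2SC", "F3SC",
)

#: Frequency bands (Hz, half-open) for the spectral features.
BANDS = {"F1SC": (0.1, 0.2), "F2SC": (0.2, 0.3), "F3SC": (0.3, 0.4)}


@dataclass
class Segment:
    """Phasic samples of one condition block, uniformly sampled."""

    samples: np.ndarray
    fs: float
    condition: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("segment needs at least 2 samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class FeatureVector:
    MSC: float = math.nan
    SDSC: float = math.nan
    MASC: float = math.nan
    MISC: float = math.nan
    DRSC: float = math.nan
    FMSC: float = math.nan
    FDSC: float = math.nan
    SMSC: float = math.nan
    SSDSC: float = math.nan
    ALSC: float = math.nan
    INSC: float = math.nan
    APSC: float = math.nan
    RMSC: float = math.nan
    ILSC: float = math.nan
    ELSC: float = math.nan
    SKSC: float = math.nan
    KUSC: float = math.nan
    MOSC: float = math.nan
    F1SC: float = math.nan
    F2SC: float = math.nan
    F3SC: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVector":
        return cls(**{k: float(v) for k, v in d.items() if k in FEATURE_NAMES})


def _diffs(seg: Segment, scale: str) -> tuple[np.ndarray, np.ndarray]:
    d1 = np.diff(seg.samples)
    d2 = np.diff(seg.samples, n=2)
    if scale == "per_second":
        d1 = d1 * seg.fs
        d2 = d2 * seg.fs ** 2
    elif scale != "per_sample":
        raise ValueError("derivative_scale must be 'per_sample' or 'per_second'")
    return d1, d2


def temporal_features(
    seg: Segment,
    derivative_scale: Literal["per_sample", "per_second"] = "per_sample",
) -> dict[str, float]:
    """Mean/std/extrema of r and of its first and second differences."""
    r = seg.samples
    if len(r) < 3:
        raise ValueError("segment too short: need N >= 3 for the second difference")
    d1, d2 = _diffs(seg, derivative_scale)
    return {
        "MSC": float(np.mean(r)),
        "SDSC": float(np.std(r)),
        "MASC": float(np.max(r)),
        "MISC": float(np.min(r)),
        "DRSC": float(np.max(r) - np.min(r)),
        "FMSC": float(np.mean(d1)),
        "FDSC": float(np.std(d1)),
        "SMSC": float(np.mean(d2)),
        "SSDSC": float(np.std(d2)),
    }


def arc_length(seg: Segment) -> float:
    """Arc length with unit sample spacing: sum of sqrt(1 + diff^2).

    Bounded below by N-1, so it is a safe denominator for the perimeter
    ratios.
    """
    d = np.diff(seg.samples)
    return float(np.sum(np.sqrt(1.0 + d * d)))


def amplitude_features(seg: Segment) -> dict[str, float]:
    """Integral (L1), normalised average power, and root mean square."""
    r = seg.samples
    apsc = float(np.mean(r * r))
    return {"INSC": float(np.sum(np.abs(r))), "APSC": apsc, "RMSC": math.sqrt(apsc)}


def perimeter_ratios(
    seg: Segment,
    elsc_numerator: Literal["rmsc", "apsc"] = "rmsc",
) -> dict[str, float]:
    """Area-perimeter ILSC = INSC/ALSC and energy-perimeter ELSC.

    ELSC divides RMSC by the arc length on the literal reading;
    ``elsc_numerator="apsc"`` switches to the mean-square "energy" reading.
    """
    alsc = arc_length(seg)
    amp = amplitude_features(seg)
    num = amp["RMSC"] if elsc_numerator == "rmsc" else amp["APSC"]
    return {"ILSC": amp["INSC"] / alsc, "ELSC": num / alsc}


def shape_statistics(seg: Segment, moment_order: int = 3) -> dict[str, float]:
    """Skewness, non-excess kurtosis, and a central moment of given order.

    On a zero-variance segment the standardised moments are undefined and
    reported as NaN rather than 0.
    """
    r = seg.samples
    mu = np.mean(r)
    centered = r - mu
    var = np.mean(centered ** 2)
    mosc = float(np.mean(centered ** moment_order))
    if var == 0:
        return {"SKSC": math.nan, "KUSC": math.nan, "MOSC": mosc}
    sd = math.sqrt(var)
    return {
        "SKSC": float(np.mean(centered ** 3) / sd ** 3),
        "KUSC": float(np.mean(centered ** 4) / sd ** 4),
        "MOSC": mosc,
    }


def periodogram(seg: Segment) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT periodogram normalised so the bin powers sum to mean(r^2)."""
    r = seg.samples
    n = len(r)
    spec = np.fft.rfft(r)
    p = np.abs(spec) ** 2 / n ** 2
    # double the interior bins so the one-sided sum equals the mean square
    if n % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / seg.fs)
    return freqs, p


def band_powers(seg: Segment, bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, float]:
    """Periodogram power summed over half-open [low, high) bands in Hz."""
    nyq = seg.fs / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band {name} [{lo}, {hi}) outside [0, Nyquist]")
    if len(seg) < 2 * seg.fs:
        raise ValueError("segment too short for the configured bands (need >= 2 s)")
    freqs, p = periodogram(seg)
    return {name: float(np.sum(p[(freqs >= lo) & (freqs < hi)]))
            for name, (lo, hi) in bands.items()}


def extract_all(
    seg: Segment,
    derivative_scale: Literal["per_sample", "per_second"] = "per_sample",
    elsc_numerator: Literal["rmsc", "apsc"] = "rmsc",
    moment_order: int = 3,
) -> FeatureVector:
    """All 21 SCR features of one condition segment."""
    out: dict[str, float] = {}
    out.update(temporal_features(seg, derivative_scale))
    out["ALSC"] = arc_length(seg)
    out.update(amplitude_features(seg))
    out.update(perimeter_ratios(seg, elsc_numerator))
    out.update(shape_statistics(seg, moment_order))
    out.update(band_powers(seg))
    return FeatureVector(**out)
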