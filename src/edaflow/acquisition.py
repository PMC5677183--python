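"""Forward and inverse model of the DC-exosomatic EDA sensor front-end.

The wearable injects a small constant current into the stratum corneum
through a pair of 10 mm Ag/AgCl disc electrodes.  A reference resistor
``Rref`` in the constant-current source fixes the skin current at

    I_skin = (1/2) * VDD / Rref

and the output voltage of the front-end maps back to skin resistance as

    R_skin = (1 - 2 * Vout / VDD) * Rref

whose reciprocal is the skin conductance.  These two relations are all the
downstream pipeline needs: the amplifier/filter stages are folded into a
single linear gain (default 1.0), since only the overall transfer function
matters for the rendered signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "SensorConfig",
    "EDARecording",
    "SaturationError",
    "skin_current",
    "current_density",
    "skin_resistance",
    "skin_conductance",
    "conductance_to_voltage",
    "quantize",
    "dequantize",
    "CURRENT_DENSITY_LIMIT_UA_CM2",
]

#: Maximum safe current density through the sweat-gland ducts (μA/cm²).
CURRENT_DENSITY_LIMIT_UA_CM2 = 10.0


class SaturationError(ValueError):
    """Raised when a front-end voltage implies a non-positive skin resistance."""


@dataclass(frozen=True)
class SensorConfig:
    """Electrical configuration of the EDA front-end.

    Parameters
    ----------
    vdd : float
        Supply voltage in volts.
    rref : float
        Reference resistance of the current source, in ohms.
    electrode_diameter : float
        Contact diameter of one disc electrode, in metres.
    adc_bits : int
        ADC resolution in bits.
    adc_vref : float, optional
        ADC full-scale voltage.  Defaults to ``vdd`` (the ADC is referenced
        to the 3.3 V rail).
    fs : float
        Sampling rate in Hz.
    gain : float
        Linear gain of the amplifier/filter chain between the sensing node
        and the ADC input.
    """

    vdd: float = 3.3
    rref: float = 825e3
    electrode_diameter: float = 0.010
    adc_bits: int = 12
    adc_vref: Optional[float] = None
    fs: float = 10.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.vdd < 0:
            raise ValueError("vdd must be non-negative")
        if self.rref <= 0:
            raise ValueError("rref must be positive")
        if self.electrode_diameter <= 0:
            raise ValueError("electrode_diameter must be positive")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.adc_vref is None:
            object.__setattr__(self, "adc_vref", self.vdd)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SensorConfig":
        return cls(**d)


@dataclass
class EDARecording:
    """A uniformly sampled EDA series.

    ``unit`` is one of ``adc_code``, ``volts`` or ``microsiemens``.
    """

    samples: np.ndarray
    fs: float
    unit: str = "microsiemens"
    subject_id: Optional[str] = None
    condition: Optional[str] = None

    _UNITS = ("adc_code", "volts", "microsiemens")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.unit not in self._UNITS:
            raise ValueError(f"unit must be one of {self._UNITS}")
        if self.unit == "microsiemens" and np.any(self.samples < 0):
            raise ValueError("conductance values must be non-negative")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        """Duration from first to last sample, (N-1)/fs."""
        return (len(self.samples) - 1) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def skin_current(cfg: SensorConfig) -> float:
    """Current injected into the skin, in amperes: ``(1/2) VDD / Rref``."""
    if cfg.rref <= 0:
        raise ValueError("rref must be positive")
    return 0.5 * cfg.vdd / cfg.rref


def current_density(cfg: SensorConfig) -> tuple[float, bool]:
    """Current density through one electrode in μA/cm², with a safety flag.

    The skin current flows through a circular contact of the configured
    diameter.  The flag is True when the density stays below the
    10 μA/cm² limit for sweat-gland safety.
    """
    if cfg.electrode_diameter <= 0:
        raise ValueError("electrode_diameter must be positive")
    area_cm2 = np.pi * (cfg.electrode_diameter * 100.0 / 2.0) ** 2
    density = skin_current(cfg) * 1e6 / area_cm2
    return density, bool(density <= CURRENT_DENSITY_LIMIT_UA_CM2)


def skin_resistance(vout: float | np.ndarray, cfg: SensorConfig) -> float | np.ndarray:
    """Skin resistance in ohms from the front-end output voltage.

    ``R_skin = (1 - 2 Vout / VDD) * Rref``.  Voltages above ``VDD/2``
    would imply negative resistance (a sensor fault); such values are
    clamped to zero with a warning so the fault is loud but non-fatal.
    """
    vout = np.asarray(vout, dtype=float)
    r = (1.0 - 2.0 * vout / cfg.vdd) * cfg.rref
    bad = (vout < 0) | (vout > cfg.vdd / 2.0)
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} output voltage(s) outside [0, VDD/2]; "
            "negative resistances clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, 0.0, None)
    if r.ndim == 0:
        return float(r)
    return r


def skin_conductance(vout: float | np.ndarray, cfg: SensorConfig) -> float | np.ndarray:
    """Skin conductance in μS: reciprocal of :func:`skin_resistance`."""
    r = np.asarray(skin_resistance(vout, cfg), dtype=float)
    if np.any(r <= 0):
        raise SaturationError("skin resistance <= 0: sensor saturated")
    g = 1e6 / r
    if g.ndim == 0:
        return float(g)
    return g


def conductance_to_voltage(g_us: float | np.ndarray, cfg: SensorConfig) -> float | np.ndarray:
    """Inverse map: front-end output voltage for a conductance in μS.

    Inverts ``G = 1 / ((1 - 2 Vout/VDD) Rref)`` to
    ``Vout = (VDD/2) (1 - 1/(G Rref))``.
    """
    g = np.asarray(g_us, dtype=float) * 1e-6
    if np.any(g <= 0):
        raise ValueError("conductance must be positive")
    v = 0.5 * cfg.vdd * (1.0 - 1.0 / (g * cfg.rref))
    if v.ndim == 0:
        return float(v)
    return v


def quantize(voltages: np.ndarray, cfg: SensorConfig) -> tuple[EDARecording, int]:
    """Quantize a voltage series to ADC codes (uniform mid-rise).

    Returns the recording (unit ``adc_code``) and the number of samples
    clipped at either rail.
    """
    v = np.asarray(voltages, dtype=float)
    levels = 2 ** cfg.adc_bits
    lsb = cfg.adc_vref / levels
    codes = np.floor(v / lsb)
    n_clipped = int(np.sum((codes < 0) | (codes > levels - 1)))
    codes = np.clip(codes, 0, levels - 1)
    return EDARecording(samples=codes, fs=cfg.fs, unit="adc_code"), n_clipped


def dequantize(rec: EDARecording, cfg: SensorConfig) -> EDARecording:
    """Map ADC codes back to reconstruction voltages (code centres)."""
    if rec.unit != "adc_code":
        raise ValueError("recording unit must be adc_code")
    lsb = cfg.adc_vref / 2 ** cfg.adc_bits
    v = (rec.samples + 0.5) * lsb
    return EDARecording(samples=v, fs=rec.fs, unit="volts",
                        subject_id=rec.subject_id, condition=rec.condition)
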