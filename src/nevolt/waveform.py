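"""Scan protocol, applied-voltage synthesis, and cycle segmentation.

The acquisition applies a triangular waveform, by default sweeping from a
-0.4 V hold up to +1.3 V and back at 400 V/s, repeated at 10 Hz with the
electrode held at -0.4 V between sweeps.  Each 8.5-ms sweep is the unit of
analysis: the rising (anodic) limb oxidizes the analyte, the falling
(cathodic) limb reduces it.  This module builds the voltage template for a
protocol and slices a continuous (time, voltage, current) recording into a
per-cycle matrix of sweep currents with a shared voltage axis.

Conventions: time is seconds from acquisition start; cycle index is 0-based;
the "time of a cycle" is its sweep start; windows are half-open
[t_start, t_end).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Below this many samples per sweep an oxidation peak cannot be resolved
#: even in principle; between this and RECOMMENDED_SWEEP_SAMPLES we warn.
MIN_SWEEP_SAMPLES = 4
RECOMMENDED_SWEEP_SAMPLES = 32


@dataclass(frozen=True)
class ScanProtocol:
    """Parameters of the triangular-waveform scan.

    Parameters
    ----------
    v_hold : float
        Holding potential between sweeps (V).
    v_peak : float
        Switching potential at the sweep apex (V).
    scan_rate : float
        Sweep rate (V/s), applied on both limbs.
    cycle_freq : float
        Sweep repetition rate (Hz).
    sample_rate : float
        Acquisition rate (Hz).  The instrument archives at 1 kHz; the
        simulator defaults to a finer grid so that within-sweep peak
        geometry is resolvable (see package docs).
    n_cycles : int
        Number of sweeps in the recording.
    """

    v_hold: float = -0.4
    v_peak: float = 1.3
    scan_rate: float = 400.0
    cycle_freq: float = 10.0
    sample_rate: float = 50_000.0
    n_cycles: int = 10

    def __post_init__(self) -> None:
        if not self.v_peak > self.v_hold:
            raise ConfigurationError(
                f"v_peak ({self.v_peak} V) must exceed v_hold ({self.v_hold} V): "
                "zero- or negative-span sweep"
            )
        if self.scan_rate <= 0:
            raise ConfigurationError(f"scan_rate must be > 0, got {self.scan_rate}")
        if self.cycle_freq <= 0:
            raise ConfigurationError(f"cycle_freq must be > 0, got {self.cycle_freq}")
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.n_cycles < 1:
            raise ConfigurationError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if not self.sweep_duration < self.cycle_period:
            raise ConfigurationError(
                f"sweep duration {self.sweep_duration * 1e3:.3f} ms does not fit in "
                f"the {self.cycle_period * 1e3:.3f} ms cycle period"
            )
        n_sweep = self.sample_rate * self.sweep_duration
        if n_sweep < MIN_SWEEP_SAMPLES:
            raise ConfigurationError(
                f"only {n_sweep:.1f} samples per sweep at {self.sample_rate} Hz; "
                f"need at least {MIN_SWEEP_SAMPLES} to resolve a peak"
            )
        if n_sweep < RECOMMENDED_SWEEP_SAMPLES:
            warnings.warn(
                f"low within-sweep resolution: {n_sweep:.1f} samples per sweep at "
                f"{self.sample_rate} Hz (recommended >= {RECOMMENDED_SWEEP_SAMPLES})",
                stacklevel=2,
            )

    @property
    def sweep_span(self) -> float:
        """Voltage span of one limb (V)."""
        return self.v_peak - self.v_hold

    @property
    def rise_duration(self) -> float:
        """Duration of the anodic (rising) limb (s)."""
        return self.sweep_span / self.scan_rate

    @property
    def sweep_duration(self) -> float:
        """Duration of the full triangular sweep (s)."""
        return 2.0 * self.sweep_span / self.scan_rate

    @property
    def hold_duration(self) -> float:
        """Duration of the hold at v_hold between sweeps (s)."""
        return self.cycle_period - self.sweep_duration

    @property
    def cycle_period(self) -> float:
        return 1.0 / self.cycle_freq

    @property
    def duration(self) -> float:
        return self.n_cycles / self.cycle_freq

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.sample_rate / self.cycle_freq))

    @property
    def n_sweep_samples(self) -> int:
        """Samples falling strictly inside the sweep of each cycle."""
        return int(np.floor(self.sweep_duration * self.sample_rate - 1e-9)) + 1

    @property
    def n_anodic_samples(self) -> int:
        """Sweep samples on the rising limb (voltage still increasing)."""
        return int(np.floor(self.rise_duration * self.sample_rate - 1e-9)) + 1

    @property
    def voltage_step(self) -> float:
        """Voltage change per sample during a sweep (V)."""
        return self.scan_rate / self.sample_rate

    def cycle_start_index(self, k: int | np.ndarray) -> np.ndarray:
        """Sample index of the sweep start of cycle ``k``."""
        return np.asarray(
            np.round(np.asarray(k) * self.sample_rate / self.cycle_freq), dtype=int
        )

    def _phase(self, t: np.ndarray) -> np.ndarray:
        """Time since the current cycle's sweep start, robust to float
        round-off at exact cycle boundaries (plain mod can return ~period)."""
        t = np.asarray(t, dtype=float)
        k = np.floor(t * self.cycle_freq + 1e-9)
        return np.maximum(t - k * self.cycle_period, 0.0)

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        """Applied voltage at absolute times ``t`` (vectorized)."""
        tau = self._phase(t)
        v = np.full_like(tau, self.v_hold)
        rising = tau < self.rise_duration
        falling = ~rising & (tau < self.sweep_duration)
        v[rising] = self.v_hold + self.scan_rate * tau[rising]
        v[falling] = self.v_peak - self.scan_rate * (tau[falling] - self.rise_duration)
        return v

    def sweep_voltages(self) -> np.ndarray:
        """Shared per-sample voltage vector of one sweep (anodic then cathodic)."""
        j = np.arange(self.n_sweep_samples)
        return self.voltage_at(j / self.sample_rate)

    def dv_dt_at(self, t: np.ndarray) -> np.ndarray:
        """Voltage slew rate at absolute times ``t`` (V/s): +scan_rate on the
        anodic limb, -scan_rate on the cathodic limb, 0 during the hold."""
        tau = self._phase(t)
        out = np.zeros_like(tau)
        out[tau < self.rise_duration] = self.scan_rate
        out[(tau >= self.rise_duration) & (tau < self.sweep_duration)] = -self.scan_rate
        return out


@dataclass(frozen=True)
class Event:
    """A labelled experimental event: an NE bolus, a stimulation train, ..."""

    label: str
    onset_s: float
    descriptor: dict = field(default_factory=dict)


@dataclass
class VoltammetryRecording:
    """A continuous acquisition: uniform time grid, applied voltage, current."""

    time: np.ndarray          # s, uniform at protocol.sample_rate
    applied_voltage: np.ndarray  # V
    current: np.ndarray       # nA
    protocol: ScanProtocol
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.applied_voltage = np.asarray(self.applied_voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (self.time.shape == self.applied_voltage.shape == self.current.shape):
            raise FormatError("time, voltage and current must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise FormatError("time axis must be strictly increasing")
            step = 1.0 / self.protocol.sample_rate
            if np.max(np.abs(dt - step)) > 0.01 * step:
                raise FormatError(
                    "time axis is not uniform at the protocol sample rate"
                )
        for ev in self.events:
            if not (0.0 <= ev.onset_s < self.duration):
                raise FormatError(
                    f"event '{ev.label}' onset {ev.onset_s} s outside [0, "
                    f"{self.duration:.3f}) s"
                )

    @property
    def duration(self) -> float:
        return self.time.size / self.protocol.sample_rate


@dataclass
class CycleMatrix:
    """Per-cycle sweep currents on a shared voltage axis.

    ``currents`` has one row per cycle and one column per sweep sample;
    columns ``[:n_anodic]`` form the anodic limb (strictly increasing
    voltage), the rest the cathodic limb.
    """

    start_times: np.ndarray      # s, sweep start of each cycle
    currents: np.ndarray         # (n_cycles, n_sweep) nA
    voltages: np.ndarray         # (n_sweep,) V
    n_anodic: int
    protocol: ScanProtocol
    voltage_residuals: np.ndarray | None = None  # per-cycle max |V_obs - V_template|

    @property
    def n_cycles(self) -> int:
        return self.currents.shape[0]

    @property
    def anodic_slice(self) -> slice:
        return slice(0, self.n_anodic)


def make_waveform(protocol: ScanProtocol) -> VoltammetryRecording:
    """Synthesize the applied-voltage series for ``protocol`` with zero current.

    Each cycle is a linear ramp v_hold -> v_peak at +scan_rate, a ramp back
    at -scan_rate, then a hold at v_hold until the next cycle start; total
    duration is n_cycles / cycle_freq.
    """
    t = np.arange(protocol.n_samples) / protocol.sample_rate
    v = protocol.voltage_at(t)
    return VoltammetryRecording(
        time=t, applied_voltage=v, current=np.zeros_like(t), protocol=protocol
    )


def segment_cycles(
    recording: VoltammetryRecording,
    voltage_tolerance_V: float = 1e-3,
) -> CycleMatrix:
    """Slice a continuous recording into per-cycle sweep currents.

    The observed voltage is checked against the protocol template; a
    worst-case deviation beyond ``voltage_tolerance_V`` raises
    :class:`FormatError` (the sidecar protocol does not match the data).
    A trailing partial cycle is dropped with a logged warning.
    """
    proto = recording.protocol
    n_full = int(np.floor(recording.duration * proto.cycle_freq + 1e-9))
    n_full = min(n_full, proto.n_cycles) if proto.n_cycles else n_full
    # Recompute from actual sample count: the final cycle must contain its
    # full sweep to be usable.
    starts = proto.cycle_start_index(np.arange(n_full))
    keep = starts + proto.n_sweep_samples <= recording.time.size
    if not np.all(keep):
        logger.warning(
            "dropping %d trailing partial cycle(s)", int(np.sum(~keep))
        )
        starts = starts[keep]
    if starts.size == 0:
        raise FormatError("recording shorter than one full sweep")

    template = proto.voltage_at(recording.time)
    resid_all = np.abs(recording.applied_voltage - template)
    worst = float(np.max(resid_all))
    if worst > voltage_tolerance_V:
        raise FormatError(
            f"applied voltage deviates from protocol template by up to "
            f"{worst * 1e3:.2f} mV (tolerance {voltage_tolerance_V * 1e3:.2f} mV); "
            "wrong protocol sidecar or corrupted stream"
        )

    idx = starts[:, None] + np.arange(proto.n_sweep_samples)[None, :]
    currents = recording.current[idx]
    residuals = resid_all[idx].max(axis=1)
    return CycleMatrix(
        start_times=starts / proto.sample_rate,
        currents=currents,
        voltages=proto.sweep_voltages(),
        n_anodic=proto.n_anodic_samples,
        protocol=proto,
        voltage_residuals=residuals,
    )
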