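"""Background subtraction and smoothing of segmented voltammograms.

The raw sweep current is dominated by the non-faradaic double-layer
charging current, which is (nearly) identical from cycle to cycle.  It is
removed by subtracting a background template: the per-sample mean current
over cycles in a quiet window preceding the event of interest.  The
subtracted sweeps are then smoothed with a centered moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .errors import AnalysisError
from .waveform import CycleMatrix

#: Minimum number of cycles required to form a background template.
MIN_BACKGROUND_CYCLES = 5


@dataclass(frozen=True)
class BackgroundSpec:
    """Where to estimate the background, relative to the event onset.

    The default window [-15, -5) s averages ~100 cycles at 10 Hz and stops
    5 s short of the event so that injection artifacts never leak into the
    template.
    """

    mode: str = "pre_event_mean"
    t_from: float = -15.0
    t_to: float = -5.0

    def __post_init__(self) -> None:
        if self.mode != "pre_event_mean":
            raise AnalysisError(f"unknown background mode '{self.mode}'")
        if not self.t_from < self.t_to <= 0.0:
            raise AnalysisError(
                f"background window [{self.t_from}, {self.t_to}) must precede the event"
            )


@dataclass
class SubtractedCycleMatrix(CycleMatrix):
    """A :class:`CycleMatrix` whose currents are background-subtracted
    (and typically smoothed), with the template retained for QC."""

    background_template: np.ndarray | None = None
    n_background_cycles: int = 0

    @property
    def template_rms_nA(self) -> float:
        return float(np.sqrt(np.mean(self.background_template**2)))


def background_cycle_mask(
    cycles: CycleMatrix, event_time: float, spec: BackgroundSpec
) -> np.ndarray:
    t = cycles.start_times
    return (t >= event_time + spec.t_from) & (t < event_time + spec.t_to)


def background_subtract(
    cycles: CycleMatrix,
    event_time: float,
    spec: BackgroundSpec = BackgroundSpec(),
) -> SubtractedCycleMatrix:
    """Subtract the mean pre-event sweep from every cycle.

    Raises :class:`AnalysisError` when the window holds fewer than
    ``MIN_BACKGROUND_CYCLES`` cycles (event too early, or window outside
    the recording).
    """
    mask = background_cycle_mask(cycles, event_time, spec)
    n_bg = int(np.sum(mask))
    if n_bg < MIN_BACKGROUND_CYCLES:
        raise AnalysisError(
            f"background window [{event_time + spec.t_from:.1f}, "
            f"{event_time + spec.t_to:.1f}) s contains {n_bg} cycles; "
            f"need at least {MIN_BACKGROUND_CYCLES}"
        )
    template = cycles.currents[mask].mean(axis=0)
    return SubtractedCycleMatrix(
        start_times=cycles.start_times,
        currents=cycles.currents - template[None, :],
        voltages=cycles.voltages,
        n_anodic=cycles.n_anodic,
        protocol=cycles.protocol,
        voltage_residuals=cycles.voltage_residuals,
        background_template=template,
        n_background_cycles=n_bg,
    )


def smooth(
    series: np.ndarray, duration_s: float = 0.005, sample_rate: float = 1000.0
) -> np.ndarray:
    """Centered moving average of ``round(duration_s * sample_rate)`` samples.

    The window length is forced odd so the filter is zero-phase.  Edges use
    shrinking windows (the mean over the available samples); no padding
    values are invented.  Works on a 1-D series or row-wise on a 2-D
    cycle-by-sample matrix.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(duration_s * sample_rate))
    if w < 1:
        raise AnalysisError(
            f"smoothing window of {duration_s * 1e3:.3f} ms at {sample_rate} Hz "
            "spans less than one sample"
        )
    if w % 2 == 0:
        w += 1
    n = x.shape[-1]
    if w > n:
        raise AnalysisError(f"smoothing window ({w} samples) longer than series ({n})")
    if w == 1:
        return x.copy()
    h = w // 2
    # Shrinking-window mean via cumulative sums: window at i is
    # [max(0, i-h), min(n, i+h+1)).
    cs = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    i = np.arange(n)
    lo = np.maximum(0, i - h)
    hi = np.minimum(n, i + h + 1)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def smooth_cycles(
    cycles: SubtractedCycleMatrix, duration_s: float
) -> SubtractedCycleMatrix:
    """Apply :func:`smooth` along each cycle's within-sweep current trace."""
    sm = smooth(cycles.currents, duration_s, cycles.protocol.sample_rate)
    return _dc_replace(cycles, currents=sm)


def preprocess_cycles(
    cycles: CycleMatrix,
    event_time: float,
    background: BackgroundSpec = BackgroundSpec(),
    smooth_duration_s: float = 0.0002,
    smooth_first: bool = False,
) -> SubtractedCycleMatrix:
    """Standard pipeline: background-subtract then smooth (order switchable).

    The default within-sweep smoothing span is 0.2 ms: the instrument's
    5-sample archival-rate filter carried onto the simulator's finer grid.
    A literal 5-ms kernel would span most of the 8.5-ms sweep, mix the
    anodic and cathodic limbs and destroy peak geometry (see methods note).
    """
    if smooth_first:
        sm = smooth(
            np.asarray(cycles.currents, dtype=float),
            smooth_duration_s,
            cycles.protocol.sample_rate,
        )
        pre = CycleMatrix(
            start_times=cycles.start_times,
            currents=sm,
            voltages=cycles.voltages,
            n_anodic=cycles.n_anodic,
            protocol=cycles.protocol,
            voltage_residuals=cycles.voltage_residuals,
        )
        return background_subtract(pre, event_time, background)
    sub = background_subtract(cycles, event_time, background)
    return smooth_cycles(sub, smooth_duration_s)
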