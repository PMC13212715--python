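"""Per-trial scalar outcomes: hold-phase means, fascicle amplitudes/rates,
and torque steadiness.

Fascicle traces arrive at their native ultrasound frame rate (~34 Hz)
and are never upsampled; window statistics are computed on the native
grid. The lengthening-speed derivative is estimated by central
differences after light low-pass smoothing (dual-pass, 2nd order,
corrected 5 Hz) to suppress frame-to-frame tracking jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .protocol import ValidityVerdict
from .signal_processing import (
    FilterSpec,
    TimeSeriesChannel,
    WindowError,
    dual_pass_butterworth,
)

__all__ = [
    "FascicleTrace",
    "TrialMetrics",
    "ConditionSummary",
    "NoValidTrialsError",
    "hold_means",
    "shortening_amplitude",
    "lengthening_amplitude",
    "max_lengthening_speed",
    "steadiness_cv",
    "condition_average",
]

FASCICLE_SMOOTH_CUTOFF = 5.0  # Hz, derivative pre-smoothing


class NoValidTrialsError(ValueError):
    """A condition has no valid trials and must be excluded."""


@dataclass(frozen=True)
class FascicleTrace:
    """Tracked (or simulated) absolute fascicle lengths in mm."""

    times: np.ndarray  # s
    lengths: np.ndarray  # mm, > 0
    source: str = "tracked"  # tracked | simulated
    drift_flag: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        l = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lengths", l)
        if t.shape != l.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times and lengths must be matching 1-D arrays, length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("fascicle times must be strictly increasing")
        if np.any(l <= 0) or not np.all(np.isfinite(l)):
            raise ValueError("fascicle lengths must be positive and finite")

    @property
    def frame_rate(self) -> float:
        return float(1.0 / np.median(np.diff(self.times)))

    def window(self, t_start: float, t_end: float, min_samples: int = 2) -> np.ndarray:
        """Lengths with times in the closed window [t_start, t_end]."""
        if t_start < self.times[0] - 1e-9 or t_end > self.times[-1] + 1e-9:
            raise WindowError(
                f"fascicle window [{t_start:.3f}, {t_end:.3f}] s outside trace span "
                f"[{self.times[0]:.3f}, {self.times[-1]:.3f}] s"
            )
        mask = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        vals = self.lengths[mask]
        if vals.size < min_samples:
            raise WindowError(
                f"fascicle window [{t_start:.3f}, {t_end:.3f}] s holds "
                f"{vals.size} sample(s); >= {min_samples} required"
            )
        return vals

    def as_channel(self) -> TimeSeriesChannel:
        """Uniform-rate view for filtering (frame rate from median interval)."""
        return TimeSeriesChannel(
            name="fascicle",
            sampling_rate=self.frame_rate,
            values=self.lengths,
            t0=float(self.times[0]),
            units="mm",
        )


def hold_means(channel: TimeSeriesChannel, window: tuple[float, float]) -> float:
    """Arithmetic mean over a closed time window (>= 2 samples required)."""
    vals = channel.window_slice(window[0], window[1])
    if vals.size < 2:
        raise WindowError(f"window {window} holds {vals.size} sample(s); >= 2 required")
    return float(np.mean(vals))


def shortening_amplitude(fascicle: FascicleTrace, onset: float, hold2_start: float) -> float:
    """Fascicle shortening amplitude: length range (max - min) from 0.5 s
    before contraction onset until the start of Hold 2, in mm."""
    vals = fascicle.window(onset - 0.5, hold2_start)
    return float(np.max(vals) - np.min(vals))


def lengthening_amplitude(
    fascicle: FascicleTrace, hold1_end: float, hold2_start: float
) -> tuple[float, float]:
    """Peak-to-peak fascicle length change between Hold-1 end and Hold-2 start.

    Returns ``(amplitude_mm, amplitude_pct)`` where the percentage is
    relative to the length at the end of Hold 1 (the pre-lengthening
    length; first sample in the window).
    """
    vals = fascicle.window(hold1_end, hold2_start)
    amp = float(np.max(vals) - np.min(vals))
    pre = float(vals[0])
    return amp, amp / pre * 100.0


def max_lengthening_speed(
    fascicle: FascicleTrace,
    hold1_end: float,
    hold2_start: float,
    smooth_cutoff: float = FASCICLE_SMOOTH_CUTOFF,
) -> float:
    """Maximum first time-derivative of fascicle length between Hold-1 end
    and Hold-2 start (mm/s, lengthening positive).

    The whole trace is low-pass smoothed before central differencing;
    set ``smooth_cutoff`` to None to differentiate the raw trace.
    """
    fascicle.window(hold1_end, hold2_start)  # validates coverage
    lengths = fascicle.lengths
    if smooth_cutoff is not None:
        ch = fascicle.as_channel()
        spec = FilterSpec("low-pass", (smooth_cutoff,), order_per_pass=2)
        lengths = dual_pass_butterworth(ch, spec).values
    deriv = np.gradient(lengths, fascicle.times)
    mask = (fascicle.times >= hold1_end - 1e-9) & (fascicle.times <= hold2_start + 1e-9)
    return float(np.max(deriv[mask]))


def steadiness_cv(active_torque: TimeSeriesChannel, hold2_window: tuple[float, float]) -> float:
    """Coefficient of variation of active torque over Hold 2, in percent.

    Sample standard deviation (ddof=1) divided by the window mean.
    """
    vals = active_torque.window_slice(hold2_window[0], hold2_window[1])
    if vals.size < 2:
        raise WindowError("Hold-2 window holds < 2 samples")
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError(f"CV undefined: non-positive Hold-2 mean ({mean:.4g})")
    return float(np.std(vals, ddof=1) / mean * 100.0)


_NUMERIC_METRIC_FIELDS = (
    "hold1_torque",
    "hold2_torque",
    "hold1_emg",
    "hold2_emg",
    "hold1_length",
    "hold2_length",
    "shortening_amplitude",
    "lengthening_amplitude",
    "lengthening_amplitude_pct",
    "max_lengthening_speed",
    "steadiness_cv",
    "matching_error",
)


@dataclass(frozen=True)
class TrialMetrics:
    """All per-trial scalar outcomes. Fascicle fields are None when no
    usable fascicle trace accompanies the trial."""

    subject: str
    condition: str
    trial_id: str
    hold1_torque: float  # % MVT
    hold2_torque: float  # % MVT
    hold1_emg: Optional[float]  # % MVC
    hold2_emg: Optional[float]  # % MVC
    hold1_length: Optional[float]  # mm
    hold2_length: Optional[float]  # mm
    shortening_amplitude: Optional[float]  # mm
    lengthening_amplitude: Optional[float]  # mm
    lengthening_amplitude_pct: Optional[float]  # % pre-lengthening length
    max_lengthening_speed: Optional[float]  # mm/s
    steadiness_cv: float  # %
    matching_error: float  # % MVT
    verdict: Optional[ValidityVerdict] = None

    @property
    def valid(self) -> bool:
        return bool(self.verdict.valid) if self.verdict is not None else True


@dataclass(frozen=True)
class ConditionSummary:
    """Per-field mean of the valid trials of one (subject, condition) cell."""

    subject: str
    condition: str
    n_valid: int
    n_total: int
    means: dict


def condition_average(
    metrics: Sequence[TrialMetrics], valid_only: bool = True
) -> ConditionSummary:
    """Average TrialMetrics fields over (valid) trials of one condition.

    Raises
    ------
    NoValidTrialsError
        When no trial survives the validity gate; callers exclude the
        (subject, condition) cell and log the reason.
    """
    if not metrics:
        raise ValueError("metrics list is empty")
    subjects = {m.subject for m in metrics}
    conditions = {m.condition for m in metrics}
    if len(subjects) != 1 or len(conditions) != 1:
        raise ValueError("condition_average expects one (subject, condition) cell")
    pool = [m for m in metrics if m.valid] if valid_only else list(metrics)
    if not pool:
        raise NoValidTrialsError(
            f"subject {next(iter(subjects))!r}, condition {next(iter(conditions))!r}: "
            f"0 of {len(metrics)} trials valid"
        )
    means = {}
    for name in _NUMERIC_METRIC_FIELDS:
        vals = [getattr(m, name) for m in pool if getattr(m, name) is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return ConditionSummary(
        subject=next(iter(subjects)),
        condition=next(iter(conditions)),
        n_valid=len(pool) if valid_only else sum(m.valid for m in pool),
        n_total=len(metrics),
        means=means,
    )
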