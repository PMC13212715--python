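"""Conditioning of raw torque, angle, and EMG signals.

All filtering uses dual-pass (forward-backward, zero-phase) Butterworth
filters whose design cut-offs are corrected so that the *cascaded* filter
attenuates -3 dB at the desired cut-off frequency. Torque is low-pass
filtered at 20 Hz, crank-arm angle at 6 Hz; the EMG amplitude (linear
envelope) is band-pass 20-400 Hz -> mean-bias removal -> full-wave
rectification -> low-pass 10 Hz, in exactly that order.

Internal computation is in SI units (Nm, s, Hz, mm, V); percent
conversions happen only at reporting boundaries via :func:`normalize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeriesChannel",
    "FilterSpec",
    "NormalizationContext",
    "InvalidFilterError",
    "SignalLengthError",
    "WindowError",
    "corrected_cutoff",
    "dual_pass_butterworth",
    "baseline_torque",
    "active_torque",
    "emg_envelope",
    "mvc_reference_value",
    "normalize",
]


class InvalidFilterError(ValueError):
    """Filter specification cannot be realized at the channel's sampling rate."""


class SignalLengthError(ValueError):
    """Signal too short for the requested operation."""


class WindowError(ValueError):
    """A requested time window is not fully covered by the channel."""


@dataclass(frozen=True)
class TimeSeriesChannel:
    """A uniformly sampled, finite, named signal.

    Parameters
    ----------
    name : str
        Channel label (e.g. ``"torque"``).
    sampling_rate : float
        Sampling rate in Hz, > 0.
    values : numpy.ndarray
        Ordered real samples, length >= 2, all finite.
    t0 : float
        Acquisition-clock time of the first sample, seconds.
    units : str
        Unit label (``"Nm"``, ``"degrees"``, ``"V"``, ``"mm"``, ``"%"``...).
    """

    name: str
    sampling_rate: float
    values: np.ndarray
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if vals.ndim != 1 or vals.size < 2:
            raise SignalLengthError(
                f"channel {self.name!r} needs >= 2 samples, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"channel {self.name!r} contains non-finite samples")

    # -- convenience -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (no bounds check)."""
        return int(round((t - self.t0) * self.sampling_rate))

    def window_slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples with ``t_start <= t <= t_end`` (closed window).

        Raises
        ------
        WindowError
            If the window is not fully inside the channel span or holds
            fewer than one sample.
        """
        if t_end < t_start:
            raise WindowError(f"empty window [{t_start}, {t_end}]")
        eps = 0.5 / self.sampling_rate
        if t_start < self.t0 - eps or t_end > self.t_end + eps:
            raise WindowError(
                f"window [{t_start:.4f}, {t_end:.4f}] s outside channel "
                f"{self.name!r} span [{self.t0:.4f}, {self.t_end:.4f}] s"
            )
        i0 = int(np.ceil((t_start - self.t0) * self.sampling_rate - 1e-9))
        i1 = int(np.floor((t_end - self.t0) * self.sampling_rate + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n - 1)
        if i1 < i0:
            raise WindowError(f"window [{t_start}, {t_end}] contains no samples")
        return self.values[i0 : i1 + 1]

    def with_values(self, values: np.ndarray, **kw) -> "TimeSeriesChannel":
        return replace(self, values=np.asarray(values, dtype=float), **kw)


@dataclass(frozen=True)
class FilterSpec:
    """Dual-pass Butterworth filter specification.

    ``desired_cutoffs`` are the frequencies at which the *composed*
    (multi-pass) filter should attenuate -3 dB; the design cut-offs are
    derived via :func:`corrected_cutoff`.
    """

    kind: Literal["low-pass", "band-pass"]
    desired_cutoffs: tuple[float, ...]
    order_per_pass: int = 2
    passes: int = 2

    def __post_init__(self) -> None:
        cut = tuple(float(c) for c in np.atleast_1d(self.desired_cutoffs))
        object.__setattr__(self, "desired_cutoffs", cut)
        if self.order_per_pass < 1:
            raise InvalidFilterError("order_per_pass must be >= 1")
        if self.passes < 1:
            raise InvalidFilterError("passes must be >= 1")
        if self.kind == "low-pass":
            if len(cut) != 1:
                raise InvalidFilterError("low-pass takes exactly one cutoff")
        elif self.kind == "band-pass":
            if len(cut) != 2 or not cut[0] < cut[1]:
                raise InvalidFilterError("band-pass needs cutoffs (low < high)")
        else:
            raise InvalidFilterError(f"unknown filter kind {self.kind!r}")
        if any(c <= 0 for c in cut):
            raise InvalidFilterError("cutoffs must be > 0")

    def design_cutoffs(self) -> tuple[float, ...]:
        """Corrected design cut-offs for the single-pass prototype.

        The low-pass-like (upper) edge is raised, the high-pass-like
        (lower) edge of a band-pass is lowered, so each edge of the
        cascade lands at -3 dB at the desired frequency.
        """
        c = _correction_factor(self.order_per_pass, self.passes)
        if self.kind == "low-pass":
            return (self.desired_cutoffs[0] / c,)
        lo, hi = self.desired_cutoffs
        return (lo * c, hi / c)


def _correction_factor(order_per_pass: int, passes: int) -> float:
    return (2.0 ** (1.0 / passes) - 1.0) ** (1.0 / (2.0 * order_per_pass))


def corrected_cutoff(desired_cutoff: float, order_per_pass: int = 2, passes: int = 2) -> float:
    """Design cut-off giving -3 dB at ``desired_cutoff`` after ``passes`` passes.

    f_design = f_desired / C with C = (2**(1/passes) - 1)**(1/(2*order)).
    For a single pass C = 1 and no correction is applied.
    """
    if desired_cutoff <= 0:
        raise InvalidFilterError("desired_cutoff must be > 0")
    if passes < 1 or order_per_pass < 1:
        raise InvalidFilterError("passes and order_per_pass must be >= 1")
    return desired_cutoff / _correction_factor(order_per_pass, passes)


def _butter_ba(spec: FilterSpec, fs: float):
    cut = spec.design_cutoffs()
    nyq = fs / 2.0
    if any(c >= nyq for c in cut):
        raise InvalidFilterError(
            f"corrected cutoff(s) {cut} Hz at or above Nyquist ({nyq} Hz)"
        )
    btype = "lowpass" if spec.kind == "low-pass" else "bandpass"
    wn = cut[0] if spec.kind == "low-pass" else list(cut)
    return sps.butter(spec.order_per_pass, wn, btype=btype, fs=fs)


def _padlen(spec: FilterSpec, n: int) -> int:
    # reflective padding: max(3 * order * 2, 1% of signal), capped below n
    return max(3 * spec.order_per_pass * 2, int(0.01 * n))


def dual_pass_butterworth(channel: TimeSeriesChannel, spec: FilterSpec) -> TimeSeriesChannel:
    """Zero-phase forward-backward Butterworth filtering.

    Output has the same length and sampling rate as the input; low-pass
    DC gain is exactly 1. Edge transients are suppressed with reflective
    padding (``padtype='even'``).
    """
    if spec.passes != 2:
        raise InvalidFilterError("dual_pass_butterworth implements passes == 2")
    b, a = _butter_ba(spec, channel.sampling_rate)
    padlen = _padlen(spec, channel.n)
    if channel.n <= padlen:
        raise SignalLengthError(
            f"channel {channel.name!r} has {channel.n} samples; "
            f">{padlen} required for stable dual-pass filtering"
        )
    out = sps.filtfilt(b, a, channel.values, padtype="even", padlen=padlen)
    return channel.with_values(out)


def baseline_torque(
    filtered_torque: TimeSeriesChannel, onset_time: float, window: float
) -> float:
    """Mean filtered recorded torque over [onset - window, onset).

    ``window`` is 1 s for submaximal contractions, 0.5 s / 0.25 s for the
    MVC trials of the two experiments.
    """
    if window <= 0:
        raise WindowError("baseline window must be > 0")
    start = onset_time - window
    if start < filtered_torque.t0 - 0.5 / filtered_torque.sampling_rate:
        raise WindowError(
            f"insufficient pre-onset data: need {window:.3f} s before "
            f"onset {onset_time:.3f} s but channel starts at {filtered_torque.t0:.3f} s "
            f"(shortfall {filtered_torque.t0 - start:.3f} s)"
        )
    # half-open [start, onset): drop the sample exactly at onset
    vals = filtered_torque.window_slice(start, onset_time)
    i_onset = filtered_torque.index_at(onset_time)
    t_last = filtered_torque.t0 + i_onset / filtered_torque.sampling_rate
    if vals.size > 1 and abs(t_last - onset_time) < 0.5 / filtered_torque.sampling_rate:
        vals = vals[:-1]
    return float(np.mean(vals))


def active_torque(filtered_torque: TimeSeriesChannel, baseline: float) -> TimeSeriesChannel:
    """Subtract the baseline torque, pointwise."""
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    return filtered_torque.with_values(filtered_torque.values - baseline, name="active_torque")


def emg_envelope(
    raw_emg: TimeSeriesChannel,
    band: tuple[float, float] = (20.0, 400.0),
    smooth_cutoff: float = 10.0,
    order_per_pass: int = 2,
) -> TimeSeriesChannel:
    """EMG amplitude (linear envelope).

    Fixed stage order: band-pass (corrected edges) -> subtract the mean
    bias of the band-passed signal -> full-wave rectify -> low-pass
    smooth at the corrected cut-off. Note the zero-phase low-pass of a
    rectified signal may undershoot zero sample-wise; no non-negativity
    is enforced.
    """
    bp = FilterSpec("band-pass", band, order_per_pass=order_per_pass)
    lp = FilterSpec("low-pass", (smooth_cutoff,), order_per_pass=order_per_pass)
    bandpassed = dual_pass_butterworth(raw_emg, bp)
    debiased = bandpassed.values - np.mean(bandpassed.values)
    rectified = np.abs(debiased)
    smoothed = dual_pass_butterworth(
        raw_emg.with_values(rectified, name="emg_rectified"), lp
    )
    return smoothed.with_values(smoothed.values, name="emg_envelope")


@dataclass(frozen=True)
class NormalizationContext:
    """MVC-derived reference values used for percent normalization.

    ``mvt`` is the mean filtered active torque over a 0.5-s window
    centered on its maximum in the best MVC trial; ``mvc_emg_amplitude``
    is the analogous envelope reference.
    """

    mvt: float
    mvc_emg_amplitude: float
    mvc_window: float = 0.5

    def __post_init__(self) -> None:
        if not (self.mvt > 0):
            raise ValueError("mvt must be > 0")
        if not (self.mvc_emg_amplitude > 0):
            raise ValueError("mvc_emg_amplitude must be > 0")


def mvc_reference_value(channel: TimeSeriesChannel, window: float = 0.5) -> float:
    """Mean over a window centered on the channel maximum.

    The window must lie fully inside the trial; truncation/clamping at
    the edges is an error.
    """
    i_max = int(np.argmax(channel.values))
    t_max = channel.t0 + i_max / channel.sampling_rate
    t_start, t_end = t_max - window / 2.0, t_max + window / 2.0
    if t_start < channel.t0 or t_end > channel.t_end:
        raise WindowError(
            f"{window:.3f}-s MVC window centered on max at {t_max:.3f} s extends "
            f"beyond channel {channel.name!r} span "
            f"[{channel.t0:.3f}, {channel.t_end:.3f}] s"
        )
    return float(np.mean(channel.window_slice(t_start, t_end)))


def normalize(
    value, context: NormalizationContext, kind: Literal["torque", "emg"]
):
    """Express a value (scalar or channel) in % MVT or % MVC."""
    if kind == "torque":
        ref = context.mvt
        units = "% MVT"
    elif kind == "emg":
        ref = context.mvc_emg_amplitude
        units = "% MVC"
    else:
        raise ValueError(f"kind must be 'torque' or 'emg', got {kind!r}")
    if isinstance(value, TimeSeriesChannel):
        return value.with_values(value.values / ref * 100.0, units=units)
    return float(value) / ref * 100.0
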