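"""Designed torque traces, onset detection, matching error, and validity gating.

Each contraction follows a piecewise-linear normalized active-torque
profile: ramp up at 20 % MVT/s to Hold 1, descend to Hold 2, hold to the
end of the contraction (13.5 s total in Experiment 1, 15 s in
Experiment 2). Reference conditions are single-plateau profiles whose
analysis phase boundaries are time-matched to the test conditions.

Trial validity requires a torque matching error (max |active - desired|
from onset to the end of Hold 2, in % MVT) not exceeding 10 % MVT, and
no dip of the active torque between Hold 1 and Hold 2 of more than the
experiment's dip threshold below the Hold-2 mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal_processing import TimeSeriesChannel, WindowError

__all__ = [
    "ProtocolSpec",
    "DesiredTrace",
    "ValidityRules",
    "ValidityVerdict",
    "InfeasibleProtocolError",
    "OnsetNotFoundError",
    "build_desired_trace",
    "detect_contraction_onset",
    "torque_matching_error",
    "dip_threshold_from_pilot",
    "validate_trial",
    "hold_windows",
    "get_protocol",
    "list_conditions",
    "EXP1_CONDITIONS",
    "EXP2_CONDITIONS",
    "HOLD_WINDOW_PRESETS",
]

ASCEND_RATE_DEFAULT = 20.0  # % MVT / s, both experiments


class InfeasibleProtocolError(ValueError):
    """Protocol durations/levels cannot be reconciled."""


class OnsetNotFoundError(ValueError):
    """No sustained supra-threshold activity found in the trace."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Designed-contraction parameterization.

    Times are relative to contraction onset (ramp start = 0 s). The
    Hold-1 duration is solved from the closure
    ``total = ascend + hold1 + descend + hold2``. For single-plateau
    reference conditions (``hold1_level == hold2_level``) the analysis
    phase boundaries are supplied explicitly via ``ref_hold1_end`` /
    ``ref_hold2_start`` so that metrics stay time-matched with the
    paired test conditions.
    """

    experiment: int
    condition_id: str
    hold1_level: float  # % MVT
    hold2_level: float  # % MVT
    descend_duration: float  # s
    total_duration: float  # s
    hold2_duration: Optional[float] = None  # s; solved if None
    ascend_rate: float = ASCEND_RATE_DEFAULT  # % MVT / s
    trace_band_halfwidth: float = 3.0  # % MVT
    ref_hold1_end: Optional[float] = None
    ref_hold2_start: Optional[float] = None

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if not (0 <= self.hold2_level <= self.hold1_level <= 100):
            raise ValueError("require 0 <= hold2_level <= hold1_level <= 100")
        if self.descend_duration < 0:
            raise ValueError("descend_duration must be >= 0")
        if self.trace_band_halfwidth <= 0:
            raise ValueError("trace_band_halfwidth must be > 0")

    @property
    def is_reference(self) -> bool:
        return self.hold1_level == self.hold2_level

    @property
    def ascend_duration(self) -> float:
        return self.hold1_level / self.ascend_rate


@dataclass(frozen=True)
class DesiredTrace:
    """Sampled piecewise-linear desired normalized torque profile.

    ``times`` includes the segment breakpoints so that trapezoidal
    integrals are exact at any sampling rate. Phase boundaries are in
    seconds from contraction onset (= 0).
    """

    times: np.ndarray
    levels: np.ndarray  # % MVT
    onset: float
    hold1_start: float
    hold1_end: float
    hold2_start: float
    hold2_end: float

    def __post_init__(self) -> None:
        bounds = (self.onset, self.hold1_start, self.hold1_end, self.hold2_start, self.hold2_end)
        if not all(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"phase boundaries must be non-decreasing: {bounds}")
        if np.any(np.asarray(self.levels) < -1e-12) or np.any(np.asarray(self.levels) > 100 + 1e-12):
            raise ValueError("levels must lie within [0, 100] % MVT")

    def level_at(self, t) -> np.ndarray:
        """Piecewise-linear interpolation of the desired level (0 outside)."""
        return np.interp(t, self.times, self.levels, left=0.0, right=float(self.levels[-1]))

    def integral(self) -> float:
        """Exact integral of the sampled trace (% MVT * s)."""
        return float(np.trapezoid(self.levels, self.times))


def _exp1_hold2_duration(descend: float) -> float:
    # Printed Hold-2 span "between 4.25 s and 5.1 s"; mapped linearly onto
    # the descend-duration range 0.25..2 s (shortest descend -> longest hold).
    return 5.1 + (descend - 0.25) * (4.25 - 5.1) / (2.0 - 0.25)


def build_desired_trace(spec: ProtocolSpec, sampling_rate: float = 2000.0) -> DesiredTrace:
    """Construct the sampled desired trace and its phase boundaries."""
    ascend = spec.ascend_duration
    descend = spec.descend_duration
    hold2 = spec.hold2_duration
    if hold2 is None:
        hold2 = spec.total_duration - ascend - descend  # plateau reference
        if not spec.is_reference:
            raise InfeasibleProtocolError(
                f"{spec.condition_id!r}: hold2_duration required for a test condition"
            )
        hold1 = 0.0
    else:
        hold1 = spec.total_duration - ascend - descend - hold2
    if hold1 < -1e-9 or hold2 < -1e-9:
        raise InfeasibleProtocolError(
            f"{spec.condition_id!r}: solved hold durations negative "
            f"(hold1={hold1:.3f} s, hold2={hold2:.3f} s)"
        )

    if spec.is_reference:
        knot_t = [0.0, ascend, spec.total_duration]
        knot_v = [0.0, spec.hold1_level, spec.hold2_level]
        h1_end = spec.ref_hold1_end
        h2_start = spec.ref_hold2_start
        if h1_end is None or h2_start is None:
            # fall back to thirds of the plateau
            h1_end = ascend + (spec.total_duration - ascend) / 3.0
            h2_start = ascend + 2.0 * (spec.total_duration - ascend) / 3.0
    else:
        t1 = ascend
        t2 = t1 + hold1
        t3 = t2 + descend
        knot_t = [0.0, t1, t2, t3, spec.total_duration]
        knot_v = [0.0, spec.hold1_level, spec.hold1_level, spec.hold2_level, spec.hold2_level]
        if descend == 0.0:  # degenerate drop: merge coincident knots
            knot_t = [0.0, t1, spec.total_duration]
            knot_v = [0.0, spec.hold1_level, spec.hold2_level]
        h1_end, h2_start = t2, t3

    grid = np.arange(0.0, spec.total_duration + 0.5 / sampling_rate, 1.0 / sampling_rate)
    times = np.union1d(np.round(grid, 12), np.round(np.asarray(knot_t), 12))
    times = times[(times >= 0) & (times <= spec.total_duration + 1e-9)]
    levels = np.interp(times, knot_t, knot_v)
    return DesiredTrace(
        times=times,
        levels=levels,
        onset=0.0,
        hold1_start=ascend,
        hold1_end=float(h1_end),
        hold2_start=float(h2_start),
        hold2_end=spec.total_duration,
    )


# ---------------------------------------------------------------------------
# condition library
# ---------------------------------------------------------------------------

def _exp1_test(descend: float, label: str) -> ProtocolSpec:
    return ProtocolSpec(
        experiment=1,
        condition_id=label,
        hold1_level=60.0,
        hold2_level=40.0,
        descend_duration=descend,
        total_duration=13.5,
        hold2_duration=_exp1_hold2_duration(descend),
        trace_band_halfwidth=3.0,
    )


def _exp2_test(hold2_level: float, hold2_duration: float, label: str) -> ProtocolSpec:
    return ProtocolSpec(
        experiment=2,
        condition_id=label,
        hold1_level=85.0,
        hold2_level=hold2_level,
        descend_duration=(85.0 - hold2_level) / ASCEND_RATE_DEFAULT,
        total_duration=15.0,
        hold2_duration=hold2_duration,
        trace_band_halfwidth=4.0,
    )


def _exp2_ref(level: float, paired_hold2_start: float, label: str) -> ProtocolSpec:
    return ProtocolSpec(
        experiment=2,
        condition_id=label,
        hold1_level=level,
        hold2_level=level,
        descend_duration=0.0,
        total_duration=15.0,
        trace_band_halfwidth=4.0,
        ref_hold1_end=6.5,  # test conditions' Hold-1 end (4.25 + 2.25 s)
        ref_hold2_start=paired_hold2_start,
    )


EXP1_CONDITIONS: dict[str, ProtocolSpec] = {
    "reference": ProtocolSpec(
        experiment=1,
        condition_id="reference",
        hold1_level=40.0,
        hold2_level=40.0,
        descend_duration=0.0,
        total_duration=13.5,
        trace_band_halfwidth=3.0,
        # union of the test conditions' descend spans
        ref_hold1_end=7.25,
        ref_hold2_start=9.25,
    ),
    "0.25-s": _exp1_test(0.25, "0.25-s"),
    "0.5-s": _exp1_test(0.5, "0.5-s"),
    "1-s": _exp1_test(1.0, "1-s"),
    "2-s": _exp1_test(2.0, "2-s"),
}

EXP2_CONDITIONS: dict[str, ProtocolSpec] = {
    "85-15": _exp2_test(15.0, 5.0, "85-15"),
    "85-30": _exp2_test(30.0, 5.75, "85-30"),
    "85-45": _exp2_test(45.0, 6.5, "85-45"),
    "15": _exp2_ref(15.0, 10.0, "15"),
    "30": _exp2_ref(30.0, 9.25, "30"),
    "45": _exp2_ref(45.0, 8.5, "45"),
}


def get_protocol(experiment: int, condition: str) -> ProtocolSpec:
    lib = {1: EXP1_CONDITIONS, 2: EXP2_CONDITIONS}.get(experiment)
    if lib is None:
        raise ValueError("experiment must be 1 or 2")
    try:
        return lib[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r} for experiment {experiment}; "
            f"available: {sorted(lib)}"
        ) from None


def list_conditions(experiment: int) -> list[str]:
    return list({1: EXP1_CONDITIONS, 2: EXP2_CONDITIONS}[experiment])


# Representative-figure analysis windows (onset-relative), available as presets.
HOLD_WINDOW_PRESETS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "fig2": ((4.0, 7.0), (10.0, 13.0)),
    "fig4": ((5.0, 6.0), (11.0, 14.0)),
}


def hold_windows(
    trace: DesiredTrace, guard: float = 0.25, preset: Optional[str] = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Onset-relative Hold-1 / Hold-2 analysis windows.

    Default policy: the solved hold spans minus a ``guard`` after each
    phase boundary. ``preset`` selects a fixed representative window
    pair instead.
    """
    if preset is not None:
        return HOLD_WINDOW_PRESETS[preset]
    h1 = (trace.hold1_start + guard, trace.hold1_end)
    h2 = (trace.hold2_start + guard, trace.hold2_end)
    if h1[1] <= h1[0] or h2[1] <= h2[0]:
        raise InfeasibleProtocolError("guard leaves an empty hold window")
    return h1, h2


# ---------------------------------------------------------------------------
# onset / matching error / validity
# ---------------------------------------------------------------------------

def detect_contraction_onset(
    active_torque_norm: TimeSeriesChannel,
    threshold: float = 1.0,
    min_duration: float = 0.1,
) -> float:
    """First time the normalized active torque exceeds ``threshold`` % MVT
    and stays above it for at least ``min_duration`` seconds."""
    x = active_torque_norm.values
    fs = active_torque_norm.sampling_rate
    need = max(int(round(min_duration * fs)), 1)
    above = x > threshold
    # run-length scan over threshold crossings
    idx = np.flatnonzero(above)
    if idx.size:
        # boundaries of runs of consecutive indices
        splits = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], splits + 1))
        ends = np.concatenate((splits, [idx.size - 1]))
        for s, e in zip(starts, ends):
            if idx[e] - idx[s] + 1 >= need:
                return float(active_torque_norm.t0 + idx[s] / fs)
    raise OnsetNotFoundError(
        f"no crossing of {threshold} % MVT sustained >= {min_duration * 1e3:.0f} ms"
    )


def torque_matching_error(
    active_torque_norm: TimeSeriesChannel,
    desired: DesiredTrace,
    onset: float,
) -> float:
    """Max |active - desired| in % MVT over [onset, onset + hold2_end].

    The desired trace (midline of the displayed band) is aligned so its
    own onset coincides with the detected contraction onset.
    """
    t_end = onset + desired.hold2_end
    eps = 0.5 / active_torque_norm.sampling_rate
    if onset < active_torque_norm.t0 - eps or t_end > active_torque_norm.t_end + eps:
        raise WindowError(
            f"matching-error span [{onset:.3f}, {t_end:.3f}] s not covered by "
            f"channel span [{active_torque_norm.t0:.3f}, {active_torque_norm.t_end:.3f}] s"
        )
    t = active_torque_norm.times
    mask = (t >= onset - eps) & (t <= t_end + eps)
    measured = active_torque_norm.values[mask]
    target = desired.level_at(t[mask] - onset)
    return float(np.max(np.abs(measured - target)))


def dip_threshold_from_pilot(pilot_mean: float, pilot_sd: float) -> float:
    """Dip threshold: pilot mean torque variability + 2 pilot SDs (Nm)."""
    if pilot_mean < 0 or pilot_sd < 0:
        raise ValueError("pilot mean and SD must be >= 0")
    return pilot_mean + 2.0 * pilot_sd


@dataclass(frozen=True)
class ValidityRules:
    """Trial-validity thresholds."""

    max_matching_error: float = 10.0  # % MVT, strict ">" excludes
    dip_threshold: float = 0.8  # Nm; 0.8 Exp 1, 2.0 Exp 2

    def __post_init__(self) -> None:
        if self.max_matching_error <= 0 or self.dip_threshold <= 0:
            raise ValueError("validity thresholds must be > 0")

    @classmethod
    def for_experiment(cls, experiment: int) -> "ValidityRules":
        return cls(dip_threshold={1: 0.8, 2: 2.0}[experiment])


@dataclass(frozen=True)
class ValidityVerdict:
    valid: bool
    matching_error: float  # % MVT
    dip_violation: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expect = (not self.dip_violation) and not any(
            r == "matching_error" for r in self.reasons
        )
        if self.valid != expect:
            raise ValueError("inconsistent verdict fields")


def validate_trial(
    active_torque_nm: TimeSeriesChannel,
    matching_error: float,
    trace: DesiredTrace,
    onset: float,
    rules: ValidityRules,
) -> ValidityVerdict:
    """Gate a trial on matching error and the Hold1->Hold2 dip rule.

    The dip rule flags trials whose active torque between the end of
    Hold 1 and the start of Hold 2 drops more than ``rules.dip_threshold``
    Nm below the Hold-2 mean active torque.
    """
    reasons: list[str] = []
    if matching_error > rules.max_matching_error:
        reasons.append("matching_error")
    elif matching_error == rules.max_matching_error:
        warnings.warn(
            f"matching error exactly at the {rules.max_matching_error} % MVT "
            "boundary; trial kept under the strict '>' exclusion rule",
            UserWarning,
            stacklevel=2,
        )
    descend_vals = active_torque_nm.window_slice(
        onset + trace.hold1_end, onset + trace.hold2_start
    )
    hold2_vals = active_torque_nm.window_slice(
        onset + trace.hold2_start, onset + trace.hold2_end
    )
    hold2_mean = float(np.mean(hold2_vals))
    dip_violation = bool(np.min(descend_vals) < hold2_mean - rules.dip_threshold)
    if dip_violation:
        reasons.append("dip")
    return ValidityVerdict(
        valid=not reasons,
        matching_error=float(matching_error),
        dip_violation=dip_violation,
        reasons=tuple(reasons),
    )
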