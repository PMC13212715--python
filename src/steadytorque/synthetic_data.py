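"""Synthetic fixed-end contraction trials from a two-element
muscle-tendon-unit (MTU) model.

The generator reproduces the mechanistic structure the analysis assumes:
a contractile element in series with an elastic element at fixed total
length, so that force development shortens the fascicles (stretching the
series-elastic element) and an active torque reduction causes
series-elastic recoil and fascicle *lengthening*. A PI tracking
controller plays the participant, driving activation so the model torque
follows the desired trace.

Emitted channels: net torque (model force + resting baseline offset +
signal-dependent low-frequency noise) and raw EMG (amplitude-modulated
20-400 Hz interference signal tracking activation) at 2 kHz, and
fascicle length at ~34 Hz (optionally with tracking drift). Every trial
carries a ground-truth sidecar for parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from ._mtu_core import simulate_loop
from .protocol import DesiredTrace, ProtocolSpec, build_desired_trace, get_protocol, list_conditions
from .signal_processing import FilterSpec, TimeSeriesChannel, dual_pass_butterworth

__all__ = [
    "MtuParams",
    "SimConfig",
    "SimTrial",
    "GroundTruth",
    "SimulationError",
    "simulate_trial",
    "generate_mvc_trial",
    "generate_dataset",
]


class SimulationError(RuntimeError):
    """Tracking controller diverged or the model left its valid range."""


@dataclass(frozen=True)
class MtuParams:
    """Muscle-tendon-unit parameters (forces in Nm-equivalents through a
    fixed effective moment arm; lengths in mm).

    Defaults are tuned so a maximal contraction produces ~41 Nm, Hold-2
    fascicle lengths sit near 80 mm, and an 85->15 % MVT torque drop
    recoils the fascicles by ~7 mm — the magnitudes the analysis layer
    expects from adult tibialis anterior. Pennation is absorbed into the
    fixed-end length constant.
    """

    f_max: float = 43.0  # Nm-equivalent maximal isometric CE force
    l_opt: float = 80.0  # mm optimal fascicle length
    fl_width: float = 0.45  # Gaussian force-length width (fraction of l_opt)
    fv_curvature: float = 0.25  # Hill concentric curvature
    max_shortening_velocity: float = 10.0  # optimal lengths per second
    see_rest_length: float = 220.0  # mm
    see_strain_at_fmax: float = 0.07  # fraction of rest length
    activation_tau_up: float = 0.012  # s
    activation_tau_down: float = 0.025  # s
    mtu_constant_length: float = 306.0  # mm, fixed-end constraint

    def __post_init__(self) -> None:
        for name in (
            "f_max", "l_opt", "fl_width", "fv_curvature",
            "max_shortening_velocity", "see_rest_length",
            "activation_tau_up", "activation_tau_down", "mtu_constant_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.see_strain_at_fmax < 0.1):
            raise ValueError("see_strain_at_fmax must lie in (0, 0.1)")
        if not self.l_opt < self.mtu_constant_length:
            raise ValueError("l_opt must be below the fixed MTU length")

    # -- derived SEE geometry (quadratic toe to 0.2 f_max, then linear,
    #    C1-continuous at the junction) ------------------------------
    @property
    def passive_fascicle_length(self) -> float:
        return self.mtu_constant_length - self.see_rest_length

    @property
    def ext_at_fmax(self) -> float:
        return self.see_strain_at_fmax * self.see_rest_length

    @property
    def f_toe(self) -> float:
        return 0.2 * self.f_max

    @property
    def ext_toe(self) -> float:
        return self.ext_at_fmax / 3.0

    @property
    def linear_stiffness(self) -> float:
        return 1.2 * self.f_max / self.ext_at_fmax

    @property
    def vmax(self) -> float:
        return self.max_shortening_velocity * self.l_opt  # mm/s

    def see_force(self, ext: float) -> float:
        if ext <= 0:
            return 0.0
        if ext <= self.ext_toe:
            return self.f_toe * (ext / self.ext_toe) ** 2
        return self.f_toe + self.linear_stiffness * (ext - self.ext_toe)

    def see_extension(self, force: float) -> float:
        if force <= 0:
            return 0.0
        if force <= self.f_toe:
            return self.ext_toe * np.sqrt(force / self.f_toe)
        return self.ext_toe + (force - self.f_toe) / self.linear_stiffness

    def force_length(self, lf: float) -> float:
        rel = (lf - self.l_opt) / (self.fl_width * self.l_opt)
        return float(np.exp(-rel * rel))

    def static_force(self, activation: float) -> float:
        """Steady-state force at a given activation (fv = 1): solves
        F = a * fl(passive_lf - ext(F)) * f_max."""

        def residual(f):
            lf = self.passive_fascicle_length - self.see_extension(f)
            return activation * self.force_length(lf) * self.f_max - f

        hi = self.f_max
        if residual(hi) > 0:  # force-length never drops below balance
            hi = 2.0 * self.f_max
        return float(brentq(residual, 0.0, hi, xtol=1e-10))

    def mvt(self) -> float:
        """Model maximum voluntary torque: static force at full activation."""
        return self.static_force(1.0)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameterization for one experiment."""

    experiment: int = 1
    mtu: MtuParams = field(default_factory=MtuParams)
    seed: int = 0
    sampling_rate: float = 2000.0  # torque / EMG, Hz
    fascicle_rate: float = 34.0  # Hz
    lead_in: float = 2.0  # quiescent span before onset, s
    tail: float = 0.25  # extra span after the trace ends, s
    torque_noise_cv: float = 1.4  # % of instantaneous torque (low-frequency)
    torque_noise_bandwidth: float = 6.0  # Hz
    baseline_offset: float = 0.4  # Nm resting torque added to the channel
    baseline_noise_sd: float = 0.01  # Nm, activity-independent floor
    emg_noise_cv: float = 5.0  # % multiplicative envelope noise
    emg_baseline_noise: float = 0.02  # fraction of maximal amplitude
    fascicle_noise_sd: float = 0.1  # mm tracking jitter
    tracking_drift_rate: float = 0.0  # mm/s after onset
    steadiness_effect: float = 0.0  # extra CV (%) added during Hold 2
    steadiness_effect_conditions: tuple[str, ...] = ()
    controller_kp: float = 3.0
    controller_ki: float = 10.0
    controller_i_max: float = 0.3

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        for name in (
            "torque_noise_cv", "baseline_noise_sd", "emg_noise_cv",
            "emg_baseline_noise", "fascicle_noise_sd", "steadiness_effect",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free quantities the analysis pipeline should recover."""

    model_mvt: float  # Nm
    onset_time: float  # s
    condition: str
    activation: np.ndarray  # 2 kHz
    true_torque: np.ndarray  # Nm, 2 kHz, noise-free
    true_fascicle: np.ndarray  # mm at the fascicle sample times, drift-free
    fascicle_times: np.ndarray
    hold1_torque_pct: Optional[float]
    hold2_torque_pct: Optional[float]
    hold2_cv_pct: Optional[float]  # injected CV during Hold 2
    shortening_amplitude: Optional[float]  # mm
    lengthening_amplitude: Optional[float]  # mm
    max_lengthening_speed: Optional[float]  # mm/s (raw derivative of truth)

    def scalars(self) -> dict:
        out = {}
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if v is None or np.isscalar(v) or isinstance(v, str):
                out[f_.name] = v
        return out


@dataclass(frozen=True)
class SimTrial:
    subject: str
    condition: str
    experiment: int
    trial_id: str
    torque: TimeSeriesChannel
    emg: Optional[TimeSeriesChannel]
    fascicle: Optional[TimeSeriesChannel]
    ground_truth: GroundTruth
    trace: DesiredTrace


# ---------------------------------------------------------------------------
# noise helpers
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise."""
    white = rng.standard_normal(n)
    ch = TimeSeriesChannel("noise", fs, white)
    out = dual_pass_butterworth(ch, FilterSpec("low-pass", (cutoff,))).values
    sd = out.std()
    return out / sd if sd > 0 else out


def _interference_carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited (20-400 Hz) interference carrier."""
    white = rng.standard_normal(n)
    ch = TimeSeriesChannel("carrier", fs, white)
    out = dual_pass_butterworth(ch, FilterSpec("band-pass", (20.0, 400.0))).values
    rms = np.sqrt(np.mean(out ** 2))
    return out / rms if rms > 0 else out


def _trial_rng(config: SimConfig, *streams: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *streams])


_CONDITION_STREAM_SALT = 10_007


def _condition_stream(experiment: int, condition: str) -> int:
    conditions = list_conditions(experiment)
    try:
        return conditions.index(condition)
    except ValueError:
        return _CONDITION_STREAM_SALT + (hash(condition) % 1000)  # MVC etc.


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _run_model(
    config: SimConfig,
    desired_frac: np.ndarray,
    drive_mode: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = config.mtu
    dt = 1.0 / config.sampling_rate
    force, act, fas = simulate_loop(
        np.ascontiguousarray(desired_frac, dtype=np.float64),
        drive_mode,
        dt,
        m.passive_fascicle_length,
        m.f_max,
        m.l_opt,
        m.fl_width,
        m.vmax,
        m.fv_curvature,
        m.passive_fascicle_length,
        m.ext_toe,
        m.f_toe,
        m.linear_stiffness,
        m.activation_tau_up,
        m.activation_tau_down,
        config.controller_kp,
        config.controller_ki,
        config.controller_i_max,
        m.mvt(),
    )
    if not (np.all(np.isfinite(force)) and np.all(fas > 0)):
        raise SimulationError("model state left its valid range")
    return force, act, fas


def _check_tracking(config: SimConfig, desired_frac: np.ndarray, force: np.ndarray, mvt: float) -> None:
    err = np.abs(force / mvt - desired_frac)
    window = int(0.5 * config.sampling_rate)
    if window and err.size > window:
        # sustained divergence: every sample above 20 % MVT for 0.5 s
        bad = err > 0.20
        run = np.convolve(bad.astype(float), np.ones(window), mode="valid")
        if np.any(run >= window):
            raise SimulationError(
                f"controller divergence: torque error > 20 % MVT sustained 0.5 s "
                f"(max error {100 * err.max():.1f} % MVT)"
            )


def simulate_trial(
    config: SimConfig,
    condition: str,
    subject: str = "S01",
    trial_id: Optional[str] = None,
    channels: Sequence[str] = ("torque", "emg", "fascicle"),
    trial_stream: int = 0,
) -> SimTrial:
    """Simulate one closed-loop tracking trial of the given condition.

    ``channels`` selects which measurement channels are synthesized (the
    mechanical simulation always runs); dropping ``"emg"`` and/or
    ``"fascicle"`` speeds up large Monte-Carlo runs. Determinism: the
    output is a pure function of (config, condition, subject, trial_stream).
    """
    spec = get_protocol(config.experiment, condition)
    trace = build_desired_trace(spec, config.sampling_rate)
    mvt = config.mtu.mvt()
    fs = config.sampling_rate
    duration = config.lead_in + spec.total_duration + config.tail
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onset = config.lead_in

    desired_pct = trace.level_at(t - onset)  # % MVT, 0 during lead-in
    desired_frac = desired_pct / 100.0
    force, act, fas_full = _run_model(config, desired_frac, drive_mode=0)
    _check_tracking(config, desired_frac, force, mvt)

    rng = _trial_rng(
        config, _condition_stream(config.experiment, condition),
        _stable_subject_stream(subject), trial_stream,
    )

    # --- torque channel: signal-dependent low-frequency noise ---------
    cv = np.full(n, config.torque_noise_cv)
    if config.steadiness_effect and condition in config.steadiness_effect_conditions:
        in_hold2 = (t >= onset + trace.hold2_start) & (t <= onset + trace.hold2_end)
        cv[in_hold2] += config.steadiness_effect
    noise = _colored_noise(rng, n, fs, config.torque_noise_bandwidth)
    floor = rng.standard_normal(n) * config.baseline_noise_sd
    torque_vals = force + config.baseline_offset + noise * (cv / 100.0) * force + floor
    torque = TimeSeriesChannel("torque", fs, torque_vals, t0=0.0, units="Nm")

    # --- EMG channel: amplitude-modulated interference ---------------
    emg = None
    if "emg" in channels:
        carrier = _interference_carrier(rng, n, fs)
        slow = _colored_noise(rng, n, fs, 3.0)
        amplitude = act * (1.0 + config.emg_noise_cv / 100.0 * slow)
        amplitude = np.clip(amplitude, 0.0, None) + config.emg_baseline_noise
        emg = TimeSeriesChannel("emg", fs, 1e-3 * amplitude * carrier, t0=0.0, units="V")

    # --- fascicle channel at the ultrasound frame rate ---------------
    n_frames = int(np.floor((duration - 1.0 / config.fascicle_rate) * config.fascicle_rate)) + 1
    f_times = np.arange(n_frames) / config.fascicle_rate
    true_fas = np.interp(f_times, t, fas_full)
    fascicle = None
    if "fascicle" in channels:
        drift = config.tracking_drift_rate * np.clip(f_times - onset, 0.0, None)
        jitter = rng.standard_normal(n_frames) * config.fascicle_noise_sd
        fascicle = TimeSeriesChannel(
            "fascicle", config.fascicle_rate, true_fas + drift + jitter, t0=0.0, units="mm"
        )

    # --- ground truth -------------------------------------------------
    def _win_mean(x, a, b):
        m = (t >= a) & (t <= b)
        return float(np.mean(x[m]))

    h1 = (onset + trace.hold1_start + 0.25, onset + trace.hold1_end)
    h2 = (onset + trace.hold2_start + 0.25, onset + trace.hold2_end)
    fmask_short = (f_times >= onset - 0.5) & (f_times <= onset + trace.hold2_start)
    fmask_len = (f_times >= onset + trace.hold1_end) & (f_times <= onset + trace.hold2_start)
    f_len = true_fas[fmask_len]
    speed = np.gradient(true_fas, f_times)[fmask_len]
    hold2_cv = config.torque_noise_cv + (
        config.steadiness_effect if condition in config.steadiness_effect_conditions else 0.0
    )
    truth = GroundTruth(
        model_mvt=mvt,
        onset_time=onset,
        condition=condition,
        activation=act,
        true_torque=force,
        true_fascicle=true_fas,
        fascicle_times=f_times,
        hold1_torque_pct=_win_mean(force, *h1) / mvt * 100.0,
        hold2_torque_pct=_win_mean(force, *h2) / mvt * 100.0,
        hold2_cv_pct=hold2_cv,
        shortening_amplitude=float(np.ptp(true_fas[fmask_short])),
        lengthening_amplitude=float(np.ptp(f_len)) if f_len.size >= 2 else None,
        max_lengthening_speed=float(np.max(speed)) if speed.size else None,
    )
    return SimTrial(
        subject=subject,
        condition=condition,
        experiment=config.experiment,
        trial_id=trial_id or f"{subject}_{condition}_{trial_stream:02d}",
        torque=torque,
        emg=emg,
        fascicle=fascicle,
        ground_truth=truth,
        trace=trace,
    )


def _stable_subject_stream(subject: str) -> int:
    return sum((i + 1) * b for i, b in enumerate(subject.encode())) % 100_000


def generate_mvc_trial(
    config: SimConfig,
    subject: str = "S01",
    hold_duration: float = 3.0,
    channels: Sequence[str] = ("torque", "emg"),
) -> SimTrial:
    """Open-loop maximal contraction: the drive ramps to 1.0 in 0.3 s,
    holds for ``hold_duration``, then releases. Supplies the MVC trial
    from which the normalization context (MVT, 100 % MVC) is built."""
    fs = config.sampling_rate
    onset = config.lead_in
    duration = onset + 0.3 + hold_duration + 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    drive = np.interp(
        t,
        [0.0, onset, onset + 0.3, onset + 0.3 + hold_duration, onset + 0.3 + hold_duration + 0.3],
        [0.0, 0.0, 1.0, 1.0, 0.0],
    )
    force, act, fas_full = _run_model(config, drive, drive_mode=1)
    mvt = config.mtu.mvt()
    rng = _trial_rng(config, _CONDITION_STREAM_SALT - 1, _stable_subject_stream(subject))

    noise = _colored_noise(rng, n, fs, config.torque_noise_bandwidth)
    floor = rng.standard_normal(n) * config.baseline_noise_sd
    torque_vals = (
        force + config.baseline_offset + noise * (config.torque_noise_cv / 100.0) * force + floor
    )
    torque = TimeSeriesChannel("torque", fs, torque_vals, t0=0.0, units="Nm")
    emg = None
    if "emg" in channels:
        carrier = _interference_carrier(rng, n, fs)
        slow = _colored_noise(rng, n, fs, 3.0)
        amplitude = np.clip(act * (1.0 + config.emg_noise_cv / 100.0 * slow), 0.0, None)
        amplitude = amplitude + config.emg_baseline_noise
        emg = TimeSeriesChannel("emg", fs, 1e-3 * amplitude * carrier, t0=0.0, units="V")
    fascicle = None
    n_frames = int(np.floor((duration - 1.0 / config.fascicle_rate) * config.fascicle_rate)) + 1
    f_times = np.arange(n_frames) / config.fascicle_rate
    true_fas = np.interp(f_times, t, fas_full)
    if "fascicle" in channels:
        jitter = rng.standard_normal(n_frames) * config.fascicle_noise_sd
        fascicle = TimeSeriesChannel(
            "fascicle", config.fascicle_rate, true_fas + jitter, t0=0.0, units="mm"
        )
    truth = GroundTruth(
        model_mvt=mvt,
        onset_time=onset,
        condition="MVC",
        activation=act,
        true_torque=force,
        true_fascicle=true_fas,
        fascicle_times=f_times,
        hold1_torque_pct=None,
        hold2_torque_pct=None,
        hold2_cv_pct=None,
        shortening_amplitude=None,
        lengthening_amplitude=None,
        max_lengthening_speed=None,
    )
    # reuse the submaximal trace type for span bookkeeping
    plateau = (onset + 0.3, onset + 0.3 + hold_duration)
    trace = DesiredTrace(
        times=np.array([0.0, 0.3, 0.3 + hold_duration]),
        levels=np.array([0.0, 100.0, 100.0]),
        onset=0.0,
        hold1_start=0.3,
        hold1_end=0.3 + hold_duration,
        hold2_start=0.3 + hold_duration,
        hold2_end=0.3 + hold_duration,
    )
    return SimTrial(
        subject=subject,
        condition="MVC",
        experiment=config.experiment,
        trial_id=f"{subject}_MVC",
        torque=torque,
        emg=emg,
        fascicle=fascicle,
        ground_truth=truth,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

DEFAULT_SUBJECT_CVS = {"f_max": 0.20, "l_opt": 0.05, "see_strain_at_fmax": 0.12}


def _jitter_params(
    base: MtuParams, rng: np.random.Generator, cvs: dict[str, float]
) -> MtuParams:
    updates = {}
    for name, cv in cvs.items():
        value = getattr(base, name) * rng.lognormal(mean=0.0, sigma=cv)
        if name == "see_strain_at_fmax":
            value = float(np.clip(value, 0.02, 0.099))
        updates[name] = value
    return replace(base, **updates)


def generate_dataset(
    config: SimConfig,
    n_subjects: int,
    trials_per_condition: int,
    out_dir: str | Path,
    subject_cvs: Optional[dict[str, float]] = None,
    conditions: Optional[Sequence[str]] = None,
) -> Path:
    """Write a synthetic multi-subject dataset to ``out_dir``.

    Layout: one directory per subject with one CSV (+ JSON metadata
    sidecar + ground-truth JSON) per trial, a per-subject MVC trial, and
    a top-level ``manifest.tsv``. Condition order is randomized within
    each block, mirroring the experimental scheduling.
    """
    from .io_cli import write_trial  # deferred: io_cli imports this module

    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conds = list(conditions) if conditions is not None else list_conditions(config.experiment)
    cvs = DEFAULT_SUBJECT_CVS if subject_cvs is None else subject_cvs
    master = np.random.default_rng([config.seed, 999_331])
    manifest_rows = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        params = _jitter_params(config.mtu, master, cvs)
        sub_cfg = replace(config, mtu=params)
        sub_dir = out / subject
        sub_dir.mkdir(exist_ok=True)

        mvc = generate_mvc_trial(sub_cfg, subject=subject)
        path = write_trial(mvc, sub_dir)
        manifest_rows.append((subject, "MVC", -1, str(path.relative_to(out))))

        for block in range(trials_per_condition):
            order = master.permutation(len(conds))
            for idx in order:
                trial = simulate_trial(
                    sub_cfg,
                    conds[idx],
                    subject=subject,
                    trial_stream=block,
                    trial_id=f"{subject}_{conds[idx]}_b{block}",
                )
                path = write_trial(trial, sub_dir)
                manifest_rows.append(
                    (subject, conds[idx], block, str(path.relative_to(out)))
                )
    manifest = out / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("subject\tcondition\tblock\tpath\n")
        for row in manifest_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    meta = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_subjects": n_subjects,
        "trials_per_condition": trials_per_condition,
        "conditions": conds,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))
    return manifest
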