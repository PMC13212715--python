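"""End-to-end processing: filtering -> onset -> matching error ->
validity -> per-trial metrics -> per-(subject, condition) averages.

Deterministic: identical (config, data) inputs yield byte-identical
results tables. Every excluded trial or participant-condition cell is
logged with a machine-readable reason code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from ..kinematics import (
    FascicleTrace,
    NoValidTrialsError,
    TrialMetrics,
    condition_average,
    hold_means,
    lengthening_amplitude,
    max_lengthening_speed,
    shortening_amplitude,
    steadiness_cv,
)
from ..protocol import (
    ValidityRules,
    build_desired_trace,
    detect_contraction_onset,
    get_protocol,
    hold_windows,
    torque_matching_error,
    validate_trial,
)
from ..signal_processing import (
    FilterSpec,
    NormalizationContext,
    TimeSeriesChannel,
    active_torque,
    baseline_torque,
    dual_pass_butterworth,
    emg_envelope,
    mvc_reference_value,
    normalize,
)
from .io import Trial, read_trial

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "process_trial", "build_normalization"]

logger = logging.getLogger(__name__)

BASELINE_WINDOWS = {"submaximal": 1.0, "mvc_exp1": 0.5, "mvc_exp2": 0.25}


@dataclass(frozen=True)
class RunConfig:
    """Run configuration; round-trips losslessly through YAML/JSON."""

    experiment: int = 1
    torque_cutoff: float = 20.0  # Hz
    angle_cutoff: float = 6.0  # Hz
    emg_band: tuple[float, float] = (20.0, 400.0)
    emg_smooth_cutoff: float = 10.0  # Hz
    fascicle_smooth_cutoff: float = 5.0  # Hz
    onset_threshold: float = 1.0  # % MVT
    onset_min_duration: float = 0.1  # s
    hold_guard: float = 0.25  # s after each phase boundary
    hold_window_preset: Optional[str] = None  # solved windows when None
    max_matching_error: float = 10.0  # % MVT
    dip_threshold: Optional[float] = None  # Nm; per-experiment default when None
    alpha: float = 0.05

    def validity_rules(self) -> ValidityRules:
        dip = self.dip_threshold
        if dip is None:
            return ValidityRules.for_experiment(self.experiment)
        return ValidityRules(max_matching_error=self.max_matching_error, dip_threshold=dip)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["emg_band"] = list(self.emg_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "emg_band" in d:
            d["emg_band"] = tuple(d["emg_band"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ResultsBundle:
    trial_metrics: pd.DataFrame
    condition_summary: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trial_metrics.to_csv(out / "trial_metrics.tsv", sep="\t", index=False)
        self.condition_summary.to_csv(out / "condition_summary.tsv", sep="\t", index=False)
        self.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


# ---------------------------------------------------------------------------
# per-trial processing
# ---------------------------------------------------------------------------

def _filtered_active(trial: Trial, config: RunConfig):
    """Filter torque and estimate a provisional pre-contraction baseline."""
    torque = trial.channel("torque")
    lp = FilterSpec("low-pass", (config.torque_cutoff,))
    filtered = dual_pass_butterworth(torque, lp)
    # pass 1: provisional baseline from the first 0.5 s, provisional onset
    prov_base = float(np.mean(filtered.values[: max(int(0.5 * filtered.sampling_rate), 2)]))
    return filtered, prov_base


def build_normalization(mvc_trial: Trial, config: RunConfig) -> NormalizationContext:
    """Normalization context from the MVC trial with the highest active torque."""
    baseline_window = BASELINE_WINDOWS[f"mvc_exp{config.experiment}"]
    filtered, prov_base = _filtered_active(mvc_trial, config)
    prov_active = active_torque(filtered, prov_base)
    # onset on a provisional % scale: threshold at 1 % of the trial max
    prov_norm = prov_active.with_values(
        prov_active.values / max(np.max(prov_active.values), 1e-9) * 100.0
    )
    onset = detect_contraction_onset(prov_norm, config.onset_threshold, config.onset_min_duration)
    base = baseline_torque(filtered, onset, baseline_window)
    act = active_torque(filtered, base)
    mvt = mvc_reference_value(act, window=0.5)
    mvc_emg = None
    if "emg" in mvc_trial.channels:
        env = emg_envelope(
            mvc_trial.channel("emg"), band=config.emg_band,
            smooth_cutoff=config.emg_smooth_cutoff,
        )
        mvc_emg = mvc_reference_value(env, window=0.5)
    return NormalizationContext(mvt=mvt, mvc_emg_amplitude=mvc_emg if mvc_emg else 1.0)


def process_trial(
    trial: Trial, config: RunConfig, context: NormalizationContext
) -> TrialMetrics:
    """All per-trial metrics for one submaximal tracking trial."""
    spec = get_protocol(config.experiment, trial.condition)
    trace = build_desired_trace(spec)
    rules = config.validity_rules()

    filtered, prov_base = _filtered_active(trial, config)
    prov_norm = normalize(active_torque(filtered, prov_base), context, "torque")
    onset = detect_contraction_onset(prov_norm, config.onset_threshold, config.onset_min_duration)
    base = baseline_torque(filtered, onset, BASELINE_WINDOWS["submaximal"])
    act_nm = active_torque(filtered, base)
    act_norm = normalize(act_nm, context, "torque")
    onset = detect_contraction_onset(act_norm, config.onset_threshold, config.onset_min_duration)

    err = torque_matching_error(act_norm, trace, onset)
    verdict = validate_trial(act_nm, err, trace, onset, rules)

    (h1a, h1b), (h2a, h2b) = hold_windows(
        trace, guard=config.hold_guard, preset=config.hold_window_preset
    )
    h1 = (onset + h1a, onset + h1b)
    h2 = (onset + h2a, onset + h2b)

    hold1_t = hold_means(act_norm, h1)
    hold2_t = hold_means(act_norm, h2)
    cv = steadiness_cv(act_nm, h2)

    hold1_e = hold2_e = None
    if "emg" in trial.channels:
        env = emg_envelope(
            trial.channel("emg"), band=config.emg_band, smooth_cutoff=config.emg_smooth_cutoff
        )
        env_norm = normalize(env, context, "emg")
        hold1_e = hold_means(env_norm, h1)
        hold2_e = hold_means(env_norm, h2)

    hold1_l = hold2_l = short_amp = len_amp = len_pct = len_speed = None
    if "fascicle" in trial.channels:
        fch = trial.channel("fascicle")
        fas = FascicleTrace(times=fch.times, lengths=fch.values, source="tracked")
        hold1_l = hold_means(fch, h1)
        hold2_l = hold_means(fch, h2)
        short_amp = shortening_amplitude(fas, onset, onset + trace.hold2_start)
        len_amp, len_pct = lengthening_amplitude(
            fas, onset + trace.hold1_end, onset + trace.hold2_start
        )
        len_speed = max_lengthening_speed(
            fas, onset + trace.hold1_end, onset + trace.hold2_start,
            smooth_cutoff=config.fascicle_smooth_cutoff,
        )

    return TrialMetrics(
        subject=trial.subject,
        condition=trial.condition,
        trial_id=trial.trial_id,
        hold1_torque=hold1_t,
        hold2_torque=hold2_t,
        hold1_emg=hold1_e,
        hold2_emg=hold2_e,
        hold1_length=hold1_l,
        hold2_length=hold2_l,
        shortening_amplitude=short_amp,
        lengthening_amplitude=len_amp,
        lengthening_amplitude_pct=len_pct,
        max_lengthening_speed=len_speed,
        steadiness_cv=cv,
        matching_error=err,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, data_dir: str | Path) -> ResultsBundle:
    """Process a dataset directory written by the simulator (or matching
    its schema) into per-trial metrics and condition summaries."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest.tsv not found in {data_dir}")
    manifest = pd.read_csv(manifest_path, sep="\t")

    rows: list[dict] = []
    exclusions: list[dict] = []
    for subject, group in manifest.groupby("subject", sort=True):
        mvc_rows = group[group["condition"] == "MVC"]
        if mvc_rows.empty:
            exclusions.append(
                {"subject": subject, "condition": "*", "reason": "no_mvc_trial", "detail": ""}
            )
            continue
        mvc_trial = read_trial(data_dir / mvc_rows.iloc[0]["path"])
        context = build_normalization(mvc_trial, config)

        for _, rec in group[group["condition"] != "MVC"].iterrows():
            trial = read_trial(data_dir / rec["path"])
            try:
                metrics = process_trial(trial, config, context)
            except Exception as exc:  # propagate with trial identity
                raise type(exc)(f"trial {trial.trial_id!r}: {exc}") from exc
            row = {
                "subject": metrics.subject,
                "condition": metrics.condition,
                "trial_id": metrics.trial_id,
                "valid": metrics.valid,
                "reasons": ";".join(metrics.verdict.reasons) if metrics.verdict else "",
            }
            for name in (
                "hold1_torque", "hold2_torque", "hold1_emg", "hold2_emg",
                "hold1_length", "hold2_length", "shortening_amplitude",
                "lengthening_amplitude", "lengthening_amplitude_pct",
                "max_lengthening_speed", "steadiness_cv", "matching_error",
            ):
                row[name] = getattr(metrics, name)
            row["_metrics"] = metrics
            rows.append(row)
            if not metrics.valid:
                exclusions.append({
                    "subject": metrics.subject,
                    "condition": metrics.condition,
                    "reason": "invalid_trial",
                    "detail": ";".join(metrics.verdict.reasons),
                })
                logger.info(
                    "excluded trial %s (%s)", metrics.trial_id,
                    ";".join(metrics.verdict.reasons),
                )

    trial_df = pd.DataFrame([{k: v for k, v in r.items() if k != "_metrics"} for r in rows])

    summary_rows = []
    if rows:
        by_cell: dict[tuple, list] = {}
        for r in rows:
            by_cell.setdefault((r["subject"], r["condition"]), []).append(r["_metrics"])
        for (subject, condition), metrics_list in sorted(by_cell.items()):
            try:
                summ = condition_average(metrics_list, valid_only=True)
            except NoValidTrialsError as exc:
                exclusions.append({
                    "subject": subject, "condition": condition,
                    "reason": "no_valid_trials", "detail": str(exc),
                })
                logger.warning("excluded cell %s/%s: no valid trials", subject, condition)
                continue
            srow = {"subject": subject, "condition": condition,
                    "n_valid": summ.n_valid, "n_total": summ.n_total}
            srow.update(summ.means)
            summary_rows.append(srow)
    summary_df = pd.DataFrame(summary_rows)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "software_version": __version__,
        "data_dir": str(data_dir),
        "n_trials": int(len(trial_df)),
        "n_exclusions": int(len(exclusions)),
    }
    return ResultsBundle(
        trial_metrics=trial_df,
        condition_summary=summary_df,
        exclusions=pd.DataFrame(exclusions, columns=["subject", "condition", "reason", "detail"]),
        provenance=provenance,
    )
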