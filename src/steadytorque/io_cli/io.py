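"""Trial file formats.

A trial is a UTF-8 comma-separated CSV with a mandatory header row, a
``time_s`` column and named channel columns at the analog rate, plus a
JSON metadata sidecar (same stem, ``.json``) declaring sampling rates,
units and identifiers. Fascicle data live in a companion
``<stem>_fascicle.csv`` at the ultrasound frame rate. Unknown columns
are preserved in ``Trial.extra`` but ignored by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ..signal_processing import TimeSeriesChannel

__all__ = ["Trial", "SchemaError", "read_trial", "write_trial"]

EXPECTED_UNITS = {"torque": "Nm", "emg": "V", "fascicle": "mm", "angle": "degrees"}
REQUIRED_CHANNELS = ("torque",)


class SchemaError(ValueError):
    """Trial file does not match the documented schema."""


@dataclass
class Trial:
    subject: str
    condition: str
    experiment: int
    trial_id: str
    channels: dict[str, TimeSeriesChannel]
    metadata: dict = field(default_factory=dict)
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def channel(self, name: str) -> TimeSeriesChannel:
        try:
            return self.channels[name]
        except KeyError:
            raise SchemaError(f"channel {name!r} absent") from None


def _check_time_column(df: pd.DataFrame, path: Path) -> np.ndarray:
    if "time_s" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path.name}: non-monotonic time column 'time_s'")
    return t


def read_trial(csv_path: str | Path) -> Trial:
    """Read one trial (CSV + JSON sidecar + optional fascicle CSV)."""
    csv_path = Path(csv_path)
    meta_path = csv_path.with_suffix(".json")
    if not meta_path.exists():
        raise SchemaError(f"metadata sidecar {meta_path.name} not found")
    meta = json.loads(meta_path.read_text())
    for key in ("subject", "condition", "experiment", "trial_id", "channels"):
        if key not in meta:
            raise SchemaError(f"{meta_path.name}: missing metadata field {key!r}")

    df = pd.read_csv(csv_path)
    t = _check_time_column(df, csv_path)
    channels: dict[str, TimeSeriesChannel] = {}
    extra: dict[str, np.ndarray] = {}
    declared = meta["channels"]

    def build(name: str, column: str, frame: pd.DataFrame, times: np.ndarray):
        info = declared.get(name)
        if info is None:
            raise SchemaError(f"{meta_path.name}: channel {name!r} not declared")
        units = info.get("units", "")
        expected = EXPECTED_UNITS.get(name)
        if expected is not None and units != expected:
            raise SchemaError(
                f"unit mismatch for channel {name!r}: got {units!r}, expected {expected!r}"
            )
        fs = float(info["sampling_rate"])
        if times.size >= 2:
            measured = 1.0 / np.median(np.diff(times))
            if abs(measured - fs) / fs > 0.01:
                raise SchemaError(
                    f"channel {name!r}: declared rate {fs} Hz disagrees with "
                    f"time column ({measured:.2f} Hz)"
                )
        channels[name] = TimeSeriesChannel(
            name=name, sampling_rate=fs, values=frame[column].to_numpy(dtype=float),
            t0=float(times[0]), units=units,
        )

    for col in df.columns:
        if col == "time_s":
            continue
        name = col.split("_")[0]
        if name in declared:
            build(name, col, df, t)
        else:
            extra[col] = df[col].to_numpy()

    fas_path = csv_path.with_name(csv_path.stem + "_fascicle.csv")
    if fas_path.exists():
        fdf = pd.read_csv(fas_path)
        ft = _check_time_column(fdf, fas_path)
        col = [c for c in fdf.columns if c != "time_s"][0]
        build("fascicle", col, fdf, ft)

    for name in REQUIRED_CHANNELS:
        if name not in channels:
            raise SchemaError(f"channel {name!r} absent")
    return Trial(
        subject=str(meta["subject"]),
        condition=str(meta["condition"]),
        experiment=int(meta["experiment"]),
        trial_id=str(meta["trial_id"]),
        channels=channels,
        metadata=meta,
        extra=extra,
    )


def write_trial(sim_trial, out_dir: str | Path) -> Path:
    """Serialize a simulated trial (CSV + sidecars); returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = sim_trial.trial_id
    csv_path = out_dir / f"{stem}.csv"

    cols = {"time_s": sim_trial.torque.times, "torque_Nm": sim_trial.torque.values}
    declared = {
        "torque": {"sampling_rate": sim_trial.torque.sampling_rate, "units": "Nm"},
    }
    if sim_trial.emg is not None:
        cols["emg_V"] = sim_trial.emg.values
        declared["emg"] = {"sampling_rate": sim_trial.emg.sampling_rate, "units": "V"}
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.7g")

    if sim_trial.fascicle is not None:
        fdf = pd.DataFrame(
            {"time_s": sim_trial.fascicle.times, "fascicle_mm": sim_trial.fascicle.values}
        )
        fdf.to_csv(out_dir / f"{stem}_fascicle.csv", index=False, float_format="%.7g")
        declared["fascicle"] = {
            "sampling_rate": sim_trial.fascicle.sampling_rate, "units": "mm",
        }

    meta = {
        "subject": sim_trial.subject,
        "condition": sim_trial.condition,
        "experiment": sim_trial.experiment,
        "trial_id": sim_trial.trial_id,
        "channels": declared,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    (out_dir / f"{stem}_truth.json").write_text(
        json.dumps(sim_trial.ground_truth.scalars(), indent=2)
    )
    return csv_path
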