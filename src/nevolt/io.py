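"""File formats: recording CSV + metadata sidecar, truth/manifest/cohort tables.

A recording is a delimited text file with header ``time_s,voltage_V,
current_nA``, one row per sample, accompanied by a YAML sidecar
(``<name>.meta.yaml``) carrying the scan protocol and the event list.
These two files are the lingua franca between the simulator, the
extraction pipeline, and external data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .waveform import Event, ScanProtocol, VoltammetryRecording

RECORDING_COLUMNS = ["time_s", "voltage_V", "current_nA"]


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_suffix("").with_suffix(".meta.yaml") if p.suffix == ".csv" else Path(
        str(p) + ".meta.yaml"
    )


def write_recording(recording: VoltammetryRecording, csv_path: str | Path) -> None:
    """Write the sample table and its protocol/events sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "voltage_V": recording.applied_voltage,
            "current_nA": recording.current,
        }
    )
    # 10 significant digits keep the time axis uniform to well under 1% of a
    # sample interval even for minutes-long acquisitions
    df.to_csv(csv_path, index=False, float_format="%.10g")
    proto = recording.protocol
    meta = {
        "protocol": {
            "v_hold_V": proto.v_hold,
            "v_peak_V": proto.v_peak,
            "scan_rate_V_per_s": proto.scan_rate,
            "cycle_freq_hz": proto.cycle_freq,
            "sample_rate_hz": proto.sample_rate,
            "n_cycles": proto.n_cycles,
        },
        "events": [
            {"label": ev.label, "onset_s": ev.onset_s, "descriptor": ev.descriptor}
            for ev in recording.events
        ],
    }
    sidecar_path(csv_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_recording(csv_path: str | Path) -> VoltammetryRecording:
    """Read a recording CSV and its sidecar; validates header and metadata."""
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise FormatError(f"cannot parse '{csv_path}': {exc}") from exc
    if list(df.columns) != RECORDING_COLUMNS:
        raise FormatError(
            f"'{csv_path}' header {list(df.columns)} does not match expected "
            f"columns {RECORDING_COLUMNS}"
        )
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar '{side}'")
    meta = yaml.safe_load(side.read_text())
    try:
        p = meta["protocol"]
        proto = ScanProtocol(
            v_hold=p["v_hold_V"],
            v_peak=p["v_peak_V"],
            scan_rate=p["scan_rate_V_per_s"],
            cycle_freq=p["cycle_freq_hz"],
            sample_rate=p["sample_rate_hz"],
            n_cycles=p["n_cycles"],
        )
        events = [
            Event(
                label=ev["label"],
                onset_s=float(ev["onset_s"]),
                descriptor=dict(ev.get("descriptor") or {}),
            )
            for ev in meta.get("events", [])
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed sidecar '{side}': missing {exc}") from exc
    return VoltammetryRecording(
        time=df["time_s"].to_numpy(dtype=float),
        applied_voltage=df["voltage_V"].to_numpy(dtype=float),
        current=df["current_nA"].to_numpy(dtype=float),
        protocol=proto,
        events=events,
    )


def write_truth(
    path: str | Path, scenario_id: str, cycle_times: np.ndarray, conc: np.ndarray,
    append: bool = False,
) -> None:
    df = pd.DataFrame(
        {
            "scenario_id": scenario_id,
            "cycle_time_s": cycle_times,
            "concentration_ug_per_ml": conc,
        }
    )
    mode, header = ("a", False) if append and Path(path).exists() else ("w", True)
    df.to_csv(path, index=False, float_format="%.6g", mode=mode, header=header)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "qo_uC", "tnf_pg_ml"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort table '{path}' missing columns {sorted(missing)}")
    if (df["tnf_pg_ml"] < 0).any() or (df["qo_uC"] < 0).any():
        raise FormatError("cohort table contains negative TNF or Q° values")
    return df
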