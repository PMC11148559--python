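"""File formats and configuration.

Everything exchanges through plain CSV: designs, recordings (two-column
trace plus a sidecar event log), peak series and response tables, with the
response-table schema doubling as the import format for an externally
supplied stimulation-response database.  Default parameter ranges and
processing constants ship as a YAML resource; a user YAML with the same
shape overrides it.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import Design, ParameterRange, DESIGN_COLUMNS
from .ecg import RPeakSeries
from .markers import RESPONSE_COLUMNS
from .synthetic import ECGRecording

__all__ = [
    "load_default_config",
    "load_config",
    "ranges_for",
    "default_n",
    "write_design",
    "read_design",
    "write_recording",
    "read_recording",
    "write_peaks",
    "read_peaks",
    "write_responses",
    "read_response_db",
]

log = logging.getLogger("vns_chrono")


# --------------------------------------------------------------------------
# Configuration


def load_default_config() -> dict:
    """Packaged defaults: per-condition ranges and processing constants."""
    text = resources.files("vns_chrono").joinpath("config/defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, shallowly overridden per top-level key by a user YAML."""
    cfg = load_default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **val}
            else:
                cfg[key] = val
    return cfg


def ranges_for(condition: str, config: dict | None = None) -> tuple[ParameterRange, ...]:
    cfg = config or load_default_config()
    try:
        block = cfg["conditions"][condition]["ranges"]
    except KeyError as e:
        raise ValueError(f"no ranges configured for condition {condition!r}") from e
    return tuple(
        ParameterRange(
            name=name,
            lo=float(lo),
            hi=float(hi),
            kind="integer" if name == "num_pulses" else "continuous",
        )
        for name, (lo, hi) in block.items()
    )


def default_n(condition: str, config: dict | None = None) -> int:
    cfg = config or load_default_config()
    return int(cfg["conditions"][condition]["n_default"])


# --------------------------------------------------------------------------
# Designs


def write_design(design: Design, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path: str | Path, seed: int = -1) -> Design:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    sets = Design.frame_to_sets(df)
    return Design(sets=sets, seed=seed, ranges=())


# --------------------------------------------------------------------------
# Recordings and peak series


def write_recording(rec: ECGRecording, trace_path: str | Path, events_path: str | Path) -> None:
    n = len(rec.samples)
    t = np.arange(n) / rec.fs
    pd.DataFrame({"time_s": t, "ecg_mV": rec.samples}).to_csv(
        trace_path, index=False, float_format="%.6f"
    )
    pd.DataFrame(rec.stim_events, columns=["onset_s", "set_id"]).to_csv(
        events_path, index=False
    )


def read_recording(trace_path: str | Path, events_path: str | Path | None = None) -> ECGRecording:
    df = pd.read_csv(trace_path)
    if not {"time_s", "ecg_mV"} <= set(df.columns):
        raise ValueError("recording file must have columns time_s, ecg_mV")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("recording too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    events: tuple[tuple[float, int], ...] = ()
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = tuple((float(r.onset_s), int(r.set_id)) for r in ev.itertuples(index=False))
    return ECGRecording(fs=fs, samples=df["ecg_mV"].to_numpy(float), stim_events=events)


def write_peaks(peaks: RPeakSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": peaks.times, "source": peaks.source}).to_csv(path, index=False)


def read_peaks(path: str | Path, fs: float = 1000.0) -> RPeakSeries:
    df = pd.read_csv(path)
    source = str(df["source"].iloc[0]) if len(df) else "detected"
    return RPeakSeries(times=df["time_s"].to_numpy(float), fs=fs, source=source)


# --------------------------------------------------------------------------
# Response database

_REQUIRED_DB_COLUMNS = (
    "subject_id",
    "condition",
    "intensity_mA",
    "pulse_width_us",
    "num_pulses",
    "frequency_Hz",
    "delay_ms",
    "hr_bl_bpm",
    "hr_stim_bpm",
)
_NUMERIC_DB_COLUMNS = _REQUIRED_DB_COLUMNS[2:]


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RESPONSE_COLUMNS if c in responses.columns]
    cols += [c for c in responses.columns if c not in cols]
    responses[cols].to_csv(path, index=False)


def read_response_db(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a stimulation-response database CSV.

    ``column_map`` renames external headers onto the canonical schema
    (``{external_name: canonical_name}``).  Missing ``charge_uC`` or
    ``delta_hr`` are recomputed from Q = I·PW·NP and
    ΔHR = (HRbl − HRstim)/HRbl.  Malformed rows (non-numeric fields,
    non-positive baseline rate) are dropped with a logged line number;
    a missing required column is an error.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = set(_REQUIRED_DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response database missing required columns: {sorted(missing)}")

    # +2: one for the header line, one for 1-based numbering.
    lines = df.index.to_numpy() + 2
    bad = np.zeros(len(df), dtype=bool)
    for col in _NUMERIC_DB_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        nn = vals.isna().to_numpy() & df[col].notna().to_numpy()
        for ln in lines[nn & ~bad]:
            log.error("response db %s: line %d: non-numeric %s", path, ln, col)
        bad |= vals.isna().to_numpy()
        df[col] = vals
    nonpos = (~bad) & (df["hr_bl_bpm"].to_numpy(float) <= 0)
    for ln in lines[nonpos]:
        log.error("response db %s: line %d: hr_bl_bpm must be positive; row rejected", path, ln)
    bad |= nonpos
    if bad.any():
        df = df[~bad].reset_index(drop=True)

    if "charge_uC" not in df.columns:
        log.info("response db %s: charge_uC missing; recomputed as I*PW*NP*1e-3", path)
        df["charge_uC"] = (
            df["intensity_mA"] * df["pulse_width_us"] * df["num_pulses"] * 1e-3
        )
    if "delta_hr" not in df.columns:
        log.info("response db %s: delta_hr missing; recomputed from heart rates", path)
        df["delta_hr"] = (df["hr_bl_bpm"] - df["hr_stim_bpm"]) / df["hr_bl_bpm"]
    if "set_id" not in df.columns:
        df["set_id"] = df.groupby(["subject_id", "condition"]).cumcount()
    return df
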