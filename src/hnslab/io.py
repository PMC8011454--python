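"""Readers and writers for the plain-text and TIFF formats used throughout.

Waveforms and beat series travel as headed CSV, expression matrices and
call tables as TSV (probes × samples), Ct tables as CSV, and image stacks
as multi-page TIFF. Ground-truth records from the synthetic generators are
written as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .beats import BeatSeries, PressureWaveform

__all__ = [
    "read_waveform_csv", "write_waveform_csv",
    "read_beats_csv", "write_beats_csv",
    "read_expression_tsv", "write_expression_tsv",
    "read_ct_csv", "write_ct_csv",
    "read_stack_tiff", "write_stack_tiff",
    "write_json", "read_json",
]


def write_waveform_csv(path, waveform: PressureWaveform) -> None:
    df = pd.DataFrame({"time_s": waveform.time_s, "pressure_mmhg": waveform.samples})
    df.to_csv(path, index=False)


def read_waveform_csv(path) -> PressureWaveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: waveform must be uniformly sampled")
    fs = 1.0 / dt[0]
    return PressureWaveform(df["pressure_mmhg"].to_numpy(dtype=float), fs, t0=float(t[0]))


def write_beats_csv(path, beats: BeatSeries) -> None:
    pi = np.append(beats.pi_ms, np.nan)
    df = pd.DataFrame({
        "beat_time_s": beats.beat_time_s,
        "sbp_mmhg": beats.sbp_mmhg,
        "dbp_mmhg": beats.dbp_mmhg,
        "pi_ms": pi,
    })
    df.to_csv(path, index=False)


def read_beats_csv(path) -> BeatSeries:
    df = pd.read_csv(path)
    return BeatSeries(
        df["beat_time_s"].to_numpy(dtype=float),
        df["sbp_mmhg"].to_numpy(dtype=float),
        df["dbp_mmhg"].to_numpy(dtype=float),
    )


def write_expression_tsv(values_path, calls_path, values: pd.DataFrame, calls: pd.DataFrame) -> None:
    values.to_csv(values_path, sep="\t", index_label="probe_id")
    calls.to_csv(calls_path, sep="\t", index_label="probe_id")


def read_expression_tsv(values_path, calls_path):
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    calls = pd.read_csv(calls_path, sep="\t", index_col="probe_id")
    return values, calls


def write_ct_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_ct_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack_tiff(path, stack) -> None:
    """Write a (channels, z, y, x) or (z, y, x) stack as multi-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
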