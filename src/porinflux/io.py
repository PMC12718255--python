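"""Delimited-text file formats of the pipeline.

Everything on disk is plain CSV/TSV or YAML: long-format trace tables
(``condition, replicate, time_s, intensity_au`` for assays;
``concentration_uM, replicate, time_s, intensity_au`` or
``concentration_uM, peak_au`` for calibrations), YAML truth manifests
and run configs, and TSV result tables. Column order is irrelevant;
headers are required; unknown extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRACE_COLUMNS",
    "read_trace_table",
    "write_trace_table",
    "read_calibration_table",
    "read_manifest",
    "write_manifest",
]

TRACE_COLUMNS = ("condition", "replicate", "time_s", "intensity_au")


def _validate_groups(df: pd.DataFrame, group_cols: list[str], path) -> pd.DataFrame:
    if not np.isfinite(df["intensity_au"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite intensity_au values")
    df = df.sort_values(group_cols + ["time_s"], kind="stable").reset_index(drop=True)
    for key, grp in df.groupby(group_cols, sort=False):
        if np.any(np.diff(grp["time_s"].to_numpy(dtype=float)) <= 0):
            raise ValueError(f"{path}: non-monotone time axis within group {key}")
    return df


def read_trace_table(path) -> pd.DataFrame:
    """Read and validate a long-format assay trace table (CSV/TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return _validate_groups(df, ["condition", "replicate"], path)


def write_trace_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"refusing to write trace table without column(s) {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_calibration_table(path) -> tuple[pd.DataFrame, str]:
    """Read a calibration table; returns (frame, kind).

    ``kind`` is ``"traces"`` for raw time series (columns
    concentration_uM, replicate, time_s, intensity_au) or ``"peaks"``
    for pre-extrapolated peaks (concentration_uM, peak_au).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if "concentration_uM" not in df.columns:
        raise ValueError(f"{path}: missing required column ['concentration_uM']")
    if "peak_au" in df.columns:
        return df, "peaks"
    missing = [c for c in ("replicate", "time_s", "intensity_au") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return _validate_groups(df, ["concentration_uM", "replicate"], path), "traces"


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
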