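"""Tab-separated readers and writers for the pipeline's tabular formats.

All tables are TSV with a header line.  Coordinates are 1-based inclusive
except BED input (0-based half-open, converted on read by
:func:`cnacohort.regions.read_bed`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GROUPS

CALL_TSV_CODES = {-1: "L", 0: "N", 1: "G"}
CALL_TSV_VALUES = {v: k for k, v in CALL_TSV_CODES.items()}


def read_probe_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": np.int64})
    missing = {"probe_id", "chrom", "pos"} - set(pm.columns)
    if missing:
        raise ValueError(f"probe map {path} lacks columns {sorted(missing)}")
    if pm["probe_id"].duplicated().any():
        raise ValueError(f"probe map {path} has duplicate probe_ids")
    for c, grp in pm.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on chromosome {c}")
    return pm


def write_probe_map(pm: pd.DataFrame, path) -> None:
    pm.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def write_matrix(matrix: pd.DataFrame, path, float_format: str | None = "%.6g") -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(design.columns)
    if missing:
        raise ValueError(f"design {path} lacks columns {sorted(missing)}")
    bad = set(design["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"design {path} has unknown groups {sorted(bad)}")
    if design["sample_id"].duplicated().any():
        raise ValueError(f"design {path} has duplicate sample_ids")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a call matrix with L/N/G symbols."""
    values = calls.to_numpy()
    sym = np.empty(values.shape, dtype=object)
    for code, letter in CALL_TSV_CODES.items():
        sym[values == code] = letter
    pd.DataFrame(sym, index=calls.index, columns=calls.columns).to_csv(
        path, sep="\t", index_label="probe_id"
    )


def read_calls(path) -> pd.DataFrame:
    sym = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = sym.to_numpy()
    bad = set(np.unique(values)) - set(CALL_TSV_VALUES)
    if bad:
        raise ValueError(f"call matrix {path} has unknown symbols {sorted(bad)}")
    codes = np.zeros(values.shape, dtype=np.int8)
    for letter, code in CALL_TSV_VALUES.items():
        codes[values == letter] = code
    return pd.DataFrame(codes, index=sym.index, columns=sym.columns)


def write_segments(segments: pd.DataFrame, path) -> None:
    """SEG-like per-sample segment table."""
    segments.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_truth_segments(truth: pd.DataFrame, probe_map: pd.DataFrame, path) -> None:
    """Ground-truth altered spans as a SEG-like TSV (sample, chrom, start, end, true_copies)."""
    chrom = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    rows = []
    values = truth.to_numpy()
    for j, sample_id in enumerate(truth.columns):
        col = values[:, j]
        for c in pd.unique(chrom):
            sel = np.flatnonzero(chrom == c)
            v = col[sel]
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            stops = np.concatenate((change, [len(v)]))
            for a, b in zip(starts, stops):
                if v[a] == 2:
                    continue
                rows.append(
                    (sample_id, c, int(pos[sel[a]]), int(pos[sel[b - 1]]), int(v[a]))
                )
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_pos", "end_pos", "true_copies"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
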