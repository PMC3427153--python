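"""Trichotomous gain/loss/normal calling with a minimum-run rule.

A probe is called a gain when its copy estimate exceeds 2.8 copies and a
loss when it falls below 1.2 copies (strict inequalities); calls are only
retained when they form a run of at least 3 consecutive probes on one
chromosome, otherwise they revert to normal.  Per-sample alteration burden
counts the maximal altered runs that survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOSS, NORMAL, GAIN = -1, 0, 1
STATE_LABELS = {LOSS: "loss", NORMAL: "normal", GAIN: "gain"}
STATE_CODES = {v: k for k, v in STATE_LABELS.items()}


@dataclass(frozen=True)
class CallingParams:
    gain_threshold: float = 2.8
    loss_threshold: float = 1.2
    min_run: int = 3

    def __post_init__(self) -> None:
        if not (self.loss_threshold < 2 < self.gain_threshold):
            raise ValueError("need loss_threshold < 2 < gain_threshold")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal value as (start, stop, value), stop exclusive."""
    if len(codes) == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(codes)]))
    return [(int(a), int(b), int(codes[a])) for a, b in zip(starts, stops)]


def enforce_min_run(codes: np.ndarray, min_run: int) -> np.ndarray:
    """Reset maximal gain/loss runs shorter than ``min_run`` to normal."""
    out = codes.copy()
    for a, b, v in _runs(codes):
        if v != NORMAL and (b - a) < min_run:
            out[a:b] = NORMAL
    return out


def call_states(
    copies: pd.DataFrame,
    probe_map: pd.DataFrame,
    params: CallingParams = CallingParams(),
) -> pd.DataFrame:
    """Threshold copy estimates and enforce the minimum-run rule per chromosome.

    Returns a probes x samples int8 matrix with values ``LOSS``/``NORMAL``/
    ``GAIN`` (-1/0/1).  Runs never span chromosome boundaries; gain and
    loss runs are enforced independently (a gain run abutting a loss run is
    two runs).
    """
    if list(copies.index) != list(probe_map["probe_id"]):
        raise ValueError("copy matrix rows do not match the probe map")
    values = copies.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("copy estimates must be finite")
    codes = np.where(
        values > params.gain_threshold,
        GAIN,
        np.where(values < params.loss_threshold, LOSS, NORMAL),
    ).astype(np.int8)
    chrom = probe_map["chrom"].to_numpy()
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        for j in range(codes.shape[1]):
            codes[sel, j] = enforce_min_run(codes[sel, j], params.min_run)
    return pd.DataFrame(codes, index=copies.index, columns=copies.columns)


def segments_from_calls(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    copies: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per maximal altered run per sample.

    Columns: sample_id, chrom, start_pos, end_pos (positions of the first
    and last probe in the run), n_probes, state ("gain"/"loss"),
    mean_copies (NaN when no copy matrix is supplied).
    """
    chrom = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    values = calls.to_numpy()
    cvals = copies.to_numpy(dtype=float) if copies is not None else None
    rows = []
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        for j, sample_id in enumerate(calls.columns):
            for a, b, v in _runs(values[sel, j]):
                if v == NORMAL:
                    continue
                probes = sel[a:b]
                rows.append(
                    (
                        sample_id,
                        c,
                        int(pos[probes[0]]),
                        int(pos[probes[-1]]),
                        len(probes),
                        STATE_LABELS[v],
                        float(cvals[probes, j].mean()) if cvals is not None else np.nan,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "start_pos",
            "end_pos",
            "n_probes",
            "state",
            "mean_copies",
        ],
    )


def sample_burden(calls: pd.DataFrame, probe_map: pd.DataFrame) -> pd.Series:
    """Alteration burden: number of maximal altered runs per sample."""
    chrom = probe_map["chrom"].to_numpy()
    values = calls.to_numpy()
    counts = np.zeros(calls.shape[1], dtype=int)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        for j in range(values.shape[1]):
            counts[j] += sum(1 for _, _, v in _runs(values[sel, j]) if v != NORMAL)
    return pd.Series(counts, index=calls.columns, name="burden")
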