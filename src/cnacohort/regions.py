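"""Recurrent altered regions across the cohort and annotation overlap.

A recurrent region is a maximal run of at least ``min_probes`` consecutive
probes, each altered in the same direction in at least ``min_fraction`` of
tumor samples (defaults 3 probes, 15%).  Region sizes in Mb follow the
truncation (floor) convention at two decimals.  Annotation tracks (e.g.
common fragile sites or cytobands) are read from BED and held 1-based
closed internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import GAIN, LOSS, STATE_CODES


@dataclass(frozen=True)
class RecurrenceParams:
    min_fraction: float = 0.15
    min_probes: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


def alteration_frequency(calls: pd.DataFrame, direction: str) -> pd.Series:
    """Fraction of tumor samples altered in ``direction`` at each probe."""
    if calls.shape[1] < 1:
        raise ValueError("need at least one tumor sample")
    code = STATE_CODES[direction]
    if code not in (GAIN, LOSS):
        raise ValueError("direction must be 'gain' or 'loss'")
    frac = (calls.to_numpy() == code).mean(axis=1)
    return pd.Series(frac, index=calls.index, name=f"freq_{direction}")


def region_size_mb(start_pos: int, end_pos: int) -> float:
    """Region span in Mb, truncated (not rounded) to two decimals."""
    if end_pos < start_pos:
        raise ValueError("end_pos must be >= start_pos")
    # integer arithmetic: floor((end-start)/1e6 * 100) / 100 without fp error
    return ((int(end_pos) - int(start_pos)) * 100 // 1_000_000) / 100


def find_recurrent_regions(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    params: RecurrenceParams = RecurrenceParams(),
) -> pd.DataFrame:
    """Maximal qualifying runs per direction, bounded by probe positions.

    Columns: chrom, start_pos, end_pos, n_probes, direction, frequency
    (the maximum per-probe altered fraction inside the region), size_mb.
    """
    chrom = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    rows = []
    for direction in ("gain", "loss"):
        freq = alteration_frequency(calls, direction).to_numpy()
        qualifies = freq >= params.min_fraction
        for c in pd.unique(chrom):
            sel = np.flatnonzero(chrom == c)
            q = qualifies[sel]
            change = np.flatnonzero(np.diff(q.astype(np.int8))) + 1
            starts = np.concatenate(([0], change))
            stops = np.concatenate((change, [len(q)]))
            for a, b in zip(starts, stops):
                if not q[a] or (b - a) < params.min_probes:
                    continue
                probes = sel[a:b]
                rows.append(
                    (
                        c,
                        int(pos[probes[0]]),
                        int(pos[probes[-1]]),
                        int(b - a),
                        direction,
                        float(freq[probes].max()),
                        region_size_mb(int(pos[probes[0]]), int(pos[probes[-1]])),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_pos", "end_pos", "n_probes", "direction", "frequency", "size_mb"],
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED annotation track into a 1-based closed interval table.

    BED is 0-based half-open; intervals are converted on read.  Returns
    columns chrom, start, end, name (name defaults to ``chrom:start-end``).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise ValueError(f"invalid BED interval {chrom}:{start0}-{end0}")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0 + 1}-{end0}"
            rows.append((chrom.removeprefix("chr"), start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def overlaps_annotation(region, track: pd.DataFrame) -> bool:
    """True iff the region shares >= 1 bp with any same-chromosome interval.

    ``region`` is any mapping-like with chrom, start_pos, end_pos (1-based
    closed), e.g. a row of a segment or region table.
    """
    chrom = str(region["chrom"]).removeprefix("chr")
    start, end = int(region["start_pos"]), int(region["end_pos"])
    same = track[track["chrom"].astype(str) == chrom]
    if same.empty:
        return False
    return bool(((same["start"] <= end) & (same["end"] >= start)).any())
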