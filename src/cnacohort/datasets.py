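"""Bundled reference tables from the motivating exposure study.

The motivating cohort compared SNP-array copy-number profiles of 26
exposure-positive and 17 exposure-negative breast tumors (betel-quid
chewing as the exposure) and published per-region gain counts, genomic
coordinates and truncated p-values for the twelve regions whose gain
frequency differed between the groups.  Those printed counts and
coordinates are inputs here: they let the exact conditional test, the
truncation reporting rule and the Mb-size convention be exercised against
known output without any raw arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_EXPOSED = 26
N_UNEXPOSED = 17

_ROWS = [
    # region, chrom, gains_exposed, gains_unexposed, start, end, size_mb, p_reported
    ("3p26.3", "3", 7, 0, 653_347, 2_264_798, 1.61, 0.03),
    ("3q26.1-3q27.2", "3", 13, 3, 165_409_849, 167_801_377, 2.39, 0.05),
    ("4p16.1", "4", 12, 2, 10_760_950, 11_857_265, 1.09, 0.02),
    ("5q11.2-5q12.1", "5", 7, 0, 57_466_589, 58_659_721, 1.19, 0.03),
    ("6q25.3", "6", 12, 2, 155_713_132, 157_738_990, 2.02, 0.02),
    ("7q33", "7", 16, 3, 133_281_372, 135_010_987, 1.72, 0.005),
    ("21q22.13", "21", 15, 3, 37_974_454, 40_484_883, 2.51, 0.01),
    ("16p13.12-16p11.2", "16", 2, 6, 10_529_386, 33_498_455, 22.96, 0.04),
    ("17q11.2", "17", 2, 6, 22_436_842, 23_092_917, 0.65, 0.04),
    ("19p13.3-19p12", "19", 3, 9, 3_542_590, 17_471_210, 13.92, 0.005),
    ("19q13.32-19q13.43", "19", 4, 8, 51_160_543, 63_437_743, 12.27, 0.03),
    ("20q11.22", "20", 1, 8, 31_982_015, 35_933_409, 3.95, 0.001),
]


def exposure_study_regions() -> pd.DataFrame:
    """The twelve exposure-differential gain regions with published counts.

    Columns: region (cytoband label), chrom, gains_exposed (of 26),
    gains_unexposed (of 17), start_pos, end_pos (1-based bp), size_mb and
    p_reported as published.  Losses in these regions were not reported
    and are taken as zero.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "region",
            "chrom",
            "gains_exposed",
            "gains_unexposed",
            "start_pos",
            "end_pos",
            "size_mb",
            "p_reported",
        ],
    )


def exposure_study_tables() -> list[tuple[str, np.ndarray]]:
    """Per-region 3x2 tables (gain/loss/normal x exposed/unexposed)."""
    out = []
    for _, row in exposure_study_regions().iterrows():
        e, u = int(row["gains_exposed"]), int(row["gains_unexposed"])
        tbl = np.array([[e, u], [0, 0], [N_EXPOSED - e, N_UNEXPOSED - u]])
        out.append((row["region"], tbl))
    return out
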