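"""Baseline selection, invariant-set normalization and copy-ratio formation.

Arrays are made comparable by normalizing every array to a single baseline
array (the one with median overall signal) through a rank-invariant probe
set: probes whose within-array ranks agree between target and baseline are
unlikely to differ biologically, so a running-median curve fitted over them
maps the target's intensity scale onto the baseline's.  Copy ratios are then
taken against the trimmed mean of the normalized germline reference pool,
on the convention that a diploid locus has ratio 1 and copy number
``2 x ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, trim_mean


@dataclass(frozen=True)
class InvariantSetParams:
    rank_threshold: float = 0.02
    min_set_size: int = 100
    max_iterations: int = 30
    curve_window_frac: float = 0.01
    #: trim fraction per side when pooling reference arrays
    reference_trim: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.rank_threshold < 1.0):
            raise ValueError("rank_threshold must be in (0, 1)")
        if self.min_set_size < 10:
            raise ValueError("min_set_size must be >= 10")


def select_baseline(matrix: pd.DataFrame) -> int:
    """Index of the array with median mean intensity (lower-middle if even).

    The baseline array is the sample whose per-array mean signal sits at the
    median of the cohort; with an even number of arrays the lower of the two
    middle arrays is taken so the baseline is always a real array.
    """
    if matrix.shape[1] < 1:
        raise ValueError("intensity matrix has no samples")
    means = matrix.to_numpy(dtype=float).mean(axis=0)
    order = np.argsort(means, kind="stable")
    return int(order[(len(order) - 1) // 2])


def invariant_set(
    target: np.ndarray,
    baseline: np.ndarray,
    params: InvariantSetParams = InvariantSetParams(),
) -> np.ndarray:
    """Iteratively select probes whose ranks agree between the two arrays.

    Starting from all probes, ranks are recomputed within the surviving set
    and probes with normalized rank difference
    ``|rank_target - rank_baseline| / set_size >= rank_threshold`` are
    dropped, until the set shrinks by less than 1% in an iteration or the
    minimum size or iteration cap is reached.  Returns probe indices into
    the input vectors.
    """
    target = np.asarray(target, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if target.shape != baseline.shape or target.ndim != 1:
        raise ValueError("target and baseline must be equal-length vectors")
    if len(target) < params.min_set_size:
        raise ValueError(
            f"need at least min_set_size={params.min_set_size} probes, got {len(target)}"
        )
    idx = np.arange(len(target))
    for _ in range(params.max_iterations):
        rt = rankdata(target[idx])
        rb = rankdata(baseline[idx])
        keep = np.abs(rt - rb) / len(idx) < params.rank_threshold
        new_idx = idx[keep]
        if len(new_idx) <= params.min_set_size:
            return new_idx if len(new_idx) > 0 else idx
        if len(new_idx) >= 0.99 * len(idx):
            return new_idx
        idx = new_idx
    return idx


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with symmetric edge truncation.

    The window shrinks symmetrically near the edges so it stays centered
    on the current point; on a monotone sequence the median is then always
    the point itself, which keeps noise-free normalization exact.
    """
    n = len(values)
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - h : i + h + 1])
    return out


def normalize_to_baseline(
    target: np.ndarray,
    baseline: np.ndarray,
    inv_set: np.ndarray,
    params: InvariantSetParams = InvariantSetParams(),
) -> np.ndarray:
    """Map target intensities onto the baseline scale via the invariant set.

    A running-median curve of baseline-vs-target over the invariant set
    (window = ``curve_window_frac`` of the set size, minimum 3, ordered by
    target intensity) defines the normalization; other probes are mapped by
    piecewise-linear interpolation, with constant-ratio extrapolation
    beyond the curve's ends.
    """
    target = np.asarray(target, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    inv_set = np.asarray(inv_set, dtype=int)
    if len(inv_set) < 3:
        raise ValueError("invariant set must contain at least 3 probes")
    t = target[inv_set]
    b = baseline[inv_set]
    order = np.argsort(t, kind="stable")
    t_sorted, b_sorted = t[order], b[order]
    # collapse duplicate target values to the median baseline value so the
    # curve is a function of target intensity (exact on discrete data)
    ts, first = np.unique(t_sorted, return_index=True)
    bounds = np.append(first, len(t_sorted))
    bs = np.array(
        [np.median(b_sorted[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    window = max(3, int(round(params.curve_window_frac * len(ts))))
    curve = _running_median(bs, window)

    out = np.empty_like(target)
    inside = (target >= ts[0]) & (target <= ts[-1])
    out[inside] = np.interp(target[inside], ts, curve)
    low = target < ts[0]
    high = target > ts[-1]
    out[low] = target[low] * (curve[0] / ts[0])
    out[high] = target[high] * (curve[-1] / ts[-1])
    return out


def normalize_cohort(
    matrix: pd.DataFrame,
    params: InvariantSetParams = InvariantSetParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize every array to the cohort baseline array.

    Returns the normalized probes x samples matrix and a per-array report
    (baseline flag, invariant-set size, pre- and post-normalization median
    ratio to baseline).
    """
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("intensity matrix must be strictly positive")
    b_idx = select_baseline(matrix)
    baseline = values[:, b_idx]
    out = np.empty_like(values)
    report_rows = []
    for j in range(values.shape[1]):
        if j == b_idx:
            out[:, j] = baseline
            report_rows.append((matrix.columns[j], True, len(baseline), 1.0, 1.0))
            continue
        target = values[:, j]
        inv = invariant_set(target, baseline, params)
        out[:, j] = normalize_to_baseline(target, baseline, inv, params)
        report_rows.append(
            (
                matrix.columns[j],
                False,
                len(inv),
                float(np.median(target / baseline)),
                float(np.median(out[:, j] / baseline)),
            )
        )
    normalized = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    report = pd.DataFrame(
        report_rows,
        columns=[
            "sample_id",
            "is_baseline",
            "invariant_set_size",
            "median_ratio_raw",
            "median_ratio_normalized",
        ],
    )
    return normalized, report


def copy_ratio(
    tumors: pd.DataFrame,
    references: pd.DataFrame,
    trim: float = 0.10,
) -> pd.DataFrame:
    """Raw copy estimates ``2 x tumor / trimmed-mean(reference pool)``.

    The reference denominator is the per-probe trimmed mean (``trim``
    fraction cut from each side) over the normalized germline arrays.
    """
    if references.shape[1] < 2:
        raise ValueError("need at least 2 reference arrays")
    denom = trim_mean(references.to_numpy(dtype=float), trim, axis=1)
    if (denom <= 0).any():
        raise ValueError("reference pool has non-positive trimmed mean at some probe")
    values = 2.0 * tumors.to_numpy(dtype=float) / denom[:, None]
    return pd.DataFrame(values, index=tumors.index, columns=tumors.columns)
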