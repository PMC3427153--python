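"""Exposure-group association tests, FDR control and burden comparisons.

Each recurrent region yields a 3x2 contingency table (rows: samples with
gain, loss or normal copy number in the region; columns: exposed and
unexposed groups).  Association is assessed with the exact conditional
test: conditioning on both margins, table probabilities follow the
multivariate hypergeometric distribution, and the two-sided p-value is the
minimum-likelihood rule — the total probability of all margin-compatible
tables no more probable than the observed one.  With a zero row margin
this reduces exactly to the classical two-sided 2x2 hypergeometric
(Fisher) test.  Probabilities are computed in exact rational arithmetic so
ties are handled without floating-point slack.

Reported p-values are truncated (floored), not rounded, to a fixed number
of decimals; full precision is always retained alongside.  Multiplicity is
controlled with Benjamini-Hochberg step-up adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, floor, isfinite

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calling import GAIN, LOSS
from .regions import overlaps_annotation
from .simulate import GROUP_EXPOSED, GROUP_UNEXPOSED


@dataclass(frozen=True)
class SignificanceParams:
    alpha: float = 0.05
    fdr_note_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def _validated_margins(table) -> tuple[list[int], list[int], int, int]:
    """Validate an r x 2 table; return positive row margins, observed
    first-column counts for those rows, grand total and first-column total."""
    tbl = np.asarray(table)
    if tbl.ndim != 2 or tbl.shape[1] != 2:
        raise ValueError("table must be r x 2")
    if not np.issubdtype(tbl.dtype, np.integer):
        as_int = tbl.astype(int)
        if not (as_int == tbl).all():
            raise ValueError("table entries must be integers")
        tbl = as_int
    if (tbl < 0).any():
        raise ValueError("table entries must be non-negative")
    if tbl.sum() == 0:
        raise ValueError("table is all zero")
    col = tbl.sum(axis=0)
    if (col == 0).any():
        raise ValueError("both column sums must be positive")
    keep = tbl.sum(axis=1) > 0  # zero-margin rows admit only a_i = 0 and drop out
    return (
        tbl.sum(axis=1)[keep].tolist(),
        tbl[keep, 0].tolist(),
        int(tbl.sum()),
        int(col[0]),
    )


def _margin_tables(rows: list[int], c1: int):
    """Yield every first-column count vector compatible with the margins."""
    r = len(rows)
    stack = [([], c1)]
    while stack:
        prefix, rem = stack.pop()
        i = len(prefix)
        if i == r - 1:
            if 0 <= rem <= rows[i]:
                yield prefix + [rem]
            continue
        tail = sum(rows[i + 1 :])
        for ai in range(max(0, rem - tail), min(rows[i], rem) + 1):
            stack.append((prefix + [ai], rem - ai))


def margin_table_probabilities(table) -> list[Fraction]:
    """Exact conditional probabilities of all tables sharing the margins.

    The distribution over margin-fixed tables is multivariate
    hypergeometric: ``P = prod_i C(R_i, a_i) / C(N, C_1)``.  Returned as
    exact rationals; they sum to exactly 1.
    """
    rows, _, n_total, c1 = _validated_margins(table)
    denom = comb(n_total, c1)
    out = []
    for a in _margin_tables(rows, c1):
        num = 1
        for r, ai in zip(rows, a):
            num *= comb(r, ai)
        out.append(Fraction(num, denom))
    return out


def exact_conditional_test(table) -> float:
    """Two-sided exact conditional p-value for an r x 2 contingency table.

    Enumerates every table with the observed row and column margins; each
    has conditional probability ``prod_i C(R_i, a_i) / C(N, C_1)`` where
    ``a_i`` is the first-column count in row i.  The p-value sums the
    probabilities of all tables whose probability does not exceed the
    observed table's (minimum-likelihood two-sided rule).  Arithmetic is
    exact (rational), so equal-probability ties are included exactly.
    """
    rows, a_obs, n_total, c1 = _validated_margins(table)
    denom = comb(n_total, c1)

    def prob(a: list[int]) -> Fraction:
        num = 1
        for r, ai in zip(rows, a):
            num *= comb(r, ai)
        return Fraction(num, denom)

    p_obs = prob(a_obs)
    total = Fraction(0)
    for a in _margin_tables(rows, c1):
        p = prob(a)
        if p <= p_obs:
            total += p
    return float(total)


def truncate_p(p: float, decimals: int) -> float:
    """Truncate (floor) a p-value to ``decimals`` decimal places.

    Values are first snapped to 9 decimals so that binary representations
    of decimal p-values (e.g. 0.29 stored as 0.28999...96) truncate as the
    decimal they denote.
    """
    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    return floor(round(p * 10**decimals, 9)) / 10**decimals


def report_p(p: float) -> float:
    """Truncate for display: three decimals when p < 0.01, else two."""
    return truncate_p(p, 3 if p < 0.01 else 2)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sample_runs(codes: np.ndarray, target: int, min_run: int) -> bool:
    best = 0
    run = 0
    for v in codes:
        run = run + 1 if v == target else 0
        best = max(best, run)
    return best >= min_run


def region_sample_state(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    region,
    min_run: int = 3,
) -> pd.Series:
    """Classify each sample as gain/loss/normal within one region.

    A sample is gain (loss) in the region when it carries at least
    ``min_run`` consecutive gain (loss) probes inside it; if it qualifies
    for both, the direction with more called probes in the region wins
    (tie goes to gain); otherwise normal.
    """
    chrom = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    sel = np.flatnonzero(
        (chrom == str(region["chrom"]))
        & (pos >= int(region["start_pos"]))
        & (pos <= int(region["end_pos"]))
    )
    if len(sel) == 0:
        raise ValueError("region covers no probes")
    block = calls.to_numpy()[sel, :]
    out = []
    for j in range(block.shape[1]):
        col = block[:, j]
        has_gain = _sample_runs(col, GAIN, min_run)
        has_loss = _sample_runs(col, LOSS, min_run)
        if has_gain and has_loss:
            n_gain = int((col == GAIN).sum())
            n_loss = int((col == LOSS).sum())
            out.append("loss" if n_loss > n_gain else "gain")
        elif has_gain:
            out.append("gain")
        elif has_loss:
            out.append("loss")
        else:
            out.append("normal")
    return pd.Series(out, index=calls.columns, name="region_state")


def contingency_table(states: pd.Series, design: pd.DataFrame) -> np.ndarray:
    """3x2 table (rows gain/loss/normal, columns exposed/unexposed)."""
    groups = design.set_index("sample_id")["group"]
    tbl = np.zeros((3, 2), dtype=int)
    row_of = {"gain": 0, "loss": 1, "normal": 2}
    col_of = {GROUP_EXPOSED: 0, GROUP_UNEXPOSED: 1}
    for sample_id, state in states.items():
        g = groups.get(sample_id)
        if g in col_of:
            tbl[row_of[state], col_of[g]] += 1
    return tbl


def test_regions(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    regions: pd.DataFrame,
    design: pd.DataFrame,
    min_run: int = 3,
) -> pd.DataFrame:
    """Exact conditional test plus BH FDR for every recurrent region.

    Returns the region table extended with per-group gain/loss counts,
    p_value (full precision), p_reported (truncated) and q_value (BH).
    """
    rows = []
    for _, region in regions.iterrows():
        states = region_sample_state(calls, probe_map, region, min_run)
        tbl = contingency_table(states, design)
        p = exact_conditional_test(tbl)
        rows.append(
            dict(
                region,
                gain_exposed=int(tbl[0, 0]),
                gain_unexposed=int(tbl[0, 1]),
                loss_exposed=int(tbl[1, 0]),
                loss_unexposed=int(tbl[1, 1]),
                p_value=p,
                p_reported=report_p(p),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out = pd.DataFrame(
            columns=list(regions.columns)
            + [
                "gain_exposed",
                "gain_unexposed",
                "loss_exposed",
                "loss_unexposed",
                "p_value",
                "p_reported",
                "q_value",
            ]
        )
    return out


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample comparison with per-group descriptives."""

    t: float
    p: float
    mean_exposed: float
    sd_exposed: float
    mean_unexposed: float
    sd_unexposed: float

    def __str__(self) -> str:
        return (
            f"exposed {self.mean_exposed:.1f}±{self.sd_exposed:.1f} vs "
            f"unexposed {self.mean_unexposed:.1f}±{self.sd_unexposed:.1f} "
            f"(t={self.t:.3f}, p={self.p:.4g})"
        )


def _welch(x: np.ndarray, y: np.ndarray) -> WelchResult:
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx, sy = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    if sx == 0.0 and sy == 0.0:
        # degenerate zero-variance case: perfect separation or identity
        if mx == my:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mx - my)) * float("inf"), 0.0
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if not isfinite(p):
            p = 0.0
    return WelchResult(t, p, mx, sx, my, sy)


def burden_ttest(burdens: pd.Series, design: pd.DataFrame) -> WelchResult:
    """Welch t-test of per-sample alteration burden, exposed vs unexposed."""
    groups = design.set_index("sample_id")["group"]
    x = burdens[[s for s in burdens.index if groups.get(s) == GROUP_EXPOSED]]
    y = burdens[[s for s in burdens.index if groups.get(s) == GROUP_UNEXPOSED]]
    return _welch(x.to_numpy(dtype=float), y.to_numpy(dtype=float))


def fragile_site_gain_incidence(
    segments: pd.DataFrame,
    track: pd.DataFrame,
    design: pd.DataFrame,
) -> tuple[pd.Series, WelchResult]:
    """Per-sample % of gain segments overlapping an annotation track.

    For each tumor sample, incidence = 100 x (gain segments overlapping
    any track interval) / (gain segments); samples without gains score 0.
    Returns the per-sample incidences and the Welch group comparison.
    """
    if track.empty:
        raise ValueError("annotation track is empty")
    groups = design.set_index("sample_id")["group"]
    tumor_ids = [s for s in groups.index if groups[s] in (GROUP_EXPOSED, GROUP_UNEXPOSED)]
    gains = segments[segments["state"] == "gain"]
    incidence = {}
    for sample_id in tumor_ids:
        segs = gains[gains["sample_id"] == sample_id]
        if len(segs) == 0:
            incidence[sample_id] = 0.0
            continue
        hits = sum(overlaps_annotation(row, track) for _, row in segs.iterrows())
        incidence[sample_id] = 100.0 * hits / len(segs)
    series = pd.Series(incidence, name="fragile_site_gain_pct")
    x = series[[s for s in series.index if groups[s] == GROUP_EXPOSED]]
    y = series[[s for s in series.index if groups[s] == GROUP_UNEXPOSED]]
    return series, _welch(x.to_numpy(dtype=float), y.to_numpy(dtype=float))
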