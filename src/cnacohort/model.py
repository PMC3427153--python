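"""Cohort copy-number model: a fit-once object tying the stages together.

:class:`CnaCohortModel` holds the raw data (intensity matrix, probe map,
cohort design) and the stage parameters; :meth:`CnaCohortModel.fit` runs
normalization, copy-ratio formation, HMM decoding, calling, recurrent
region detection and per-region exposure-group testing, returning a
:class:`CnaCohortResults` that carries every intermediate matrix, the
region test table and summary methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calling import CallingParams, call_states, sample_burden, segments_from_calls
from .hmm import HmmParams, infer_copy_numbers
from .normalize import InvariantSetParams, copy_ratio, normalize_cohort
from .regions import RecurrenceParams, find_recurrent_regions
from .simulate import (
    GROUP_EXPOSED,
    GROUP_REFERENCE,
    GROUP_UNEXPOSED,
    SimulatedCohort,
    simulate_cohort,
)
from .stats import (
    SignificanceParams,
    WelchResult,
    burden_ttest,
    fragile_site_gain_incidence,
    test_regions,
)


def _validate_inputs(
    intensities: pd.DataFrame, probe_map: pd.DataFrame, design: pd.DataFrame
) -> None:
    if list(intensities.index) != list(probe_map["probe_id"]):
        raise ValueError("intensity matrix rows do not match the probe map")
    if set(intensities.columns) != set(design["sample_id"]):
        raise ValueError("intensity matrix samples do not match the cohort design")
    counts = design["group"].value_counts()
    if counts.get(GROUP_REFERENCE, 0) < 2:
        raise ValueError("need at least 2 reference samples")
    for g in (GROUP_EXPOSED, GROUP_UNEXPOSED):
        if counts.get(g, 0) < 1:
            raise ValueError(f"design has no {g} tumor samples")


class CnaCohortModel:
    """SNP-array copy-number cohort analysis model.

    Parameters
    ----------
    intensities : DataFrame
        Raw probe x sample intensity matrix (strictly positive), rows in
        probe-map order.
    probe_map : DataFrame
        probe_id / chrom / pos, positions strictly increasing per chromosome.
    design : DataFrame
        sample_id / group with groups exposed, unexposed, reference.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        probe_map: pd.DataFrame,
        design: pd.DataFrame,
        *,
        inv_params: InvariantSetParams | None = None,
        hmm_params: HmmParams | None = None,
        calling_params: CallingParams | None = None,
        recurrence_params: RecurrenceParams | None = None,
        significance_params: SignificanceParams | None = None,
    ) -> None:
        _validate_inputs(intensities, probe_map, design)
        self.intensities = intensities
        self.probe_map = probe_map.reset_index(drop=True)
        self.design = design.reset_index(drop=True)
        self.inv_params = inv_params or InvariantSetParams()
        self.hmm_params = hmm_params or HmmParams()
        self.calling_params = calling_params or CallingParams()
        self.recurrence_params = recurrence_params or RecurrenceParams()
        self.significance_params = significance_params or SignificanceParams()
        self.truth: pd.DataFrame | None = None  # ground truth when simulated

    @classmethod
    def from_tsv(cls, intensities_path, probe_map_path, design_path, **kwargs):
        from .io import read_design, read_matrix, read_probe_map

        return cls(
            read_matrix(intensities_path),
            read_probe_map(probe_map_path),
            read_design(design_path),
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, seed: int = 0, **kwargs) -> "CnaCohortModel":
        """Build a model from a freshly simulated default cohort.

        Simulation keyword arguments (n_probes, cohort_sizes, segments,
        noise, chrom_lengths) are passed through; parameter objects are
        taken from the remaining keywords.
        """
        sim_keys = {"n_probes", "chrom_lengths", "cohort_sizes", "segments", "noise"}
        sim_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in sim_keys}
        cohort = simulate_cohort(seed=seed, **sim_kwargs)
        model = cls(cohort.intensities, cohort.probe_map, cohort.design, **kwargs)
        model.truth = cohort.truth
        model.planted_segments = cohort.segments
        return model

    @property
    def tumor_ids(self) -> list[str]:
        g = self.design.set_index("sample_id")["group"]
        return [s for s in g.index if g[s] in (GROUP_EXPOSED, GROUP_UNEXPOSED)]

    @property
    def reference_ids(self) -> list[str]:
        g = self.design.set_index("sample_id")["group"]
        return [s for s in g.index if g[s] == GROUP_REFERENCE]

    def fit(self, decode: str = "posterior") -> "CnaCohortResults":
        """Run the full pipeline and return the fitted results."""
        normalized, report = normalize_cohort(self.intensities, self.inv_params)
        raw = copy_ratio(
            normalized[self.tumor_ids],
            normalized[self.reference_ids],
            trim=self.inv_params.reference_trim,
        )
        copies = infer_copy_numbers(raw, self.probe_map, self.hmm_params, decode=decode)
        calls = call_states(copies, self.probe_map, self.calling_params)
        segments = segments_from_calls(calls, self.probe_map, copies)
        burden = sample_burden(calls, self.probe_map)
        regions = find_recurrent_regions(calls, self.probe_map, self.recurrence_params)
        region_tests = test_regions(
            calls, self.probe_map, regions, self.design, self.calling_params.min_run
        )
        prevalence = self._prevalence(calls)
        return CnaCohortResults(
            model=self,
            normalized=normalized,
            normalization_report=report,
            raw_copies=raw,
            copy_numbers=copies,
            calls=calls,
            segments=segments,
            burden=burden,
            recurrent_regions=regions,
            region_tests=region_tests,
            prevalence=prevalence,
            decode=decode,
        )

    def _prevalence(self, calls: pd.DataFrame) -> pd.DataFrame:
        """Per-probe fraction of samples with gain/loss, per exposure group."""
        g = self.design.set_index("sample_id")["group"]
        out = {"probe_id": self.probe_map["probe_id"], "chrom": self.probe_map["chrom"],
               "pos": self.probe_map["pos"]}
        for group in (GROUP_EXPOSED, GROUP_UNEXPOSED):
            ids = [s for s in calls.columns if g.get(s) == group]
            block = calls[ids].to_numpy()
            out[f"gain_frac_{group}"] = (block == 1).mean(axis=1)
            out[f"loss_frac_{group}"] = (block == -1).mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class CnaCohortResults:
    """Fitted cohort analysis: matrices, segments, regions and tests."""

    model: CnaCohortModel
    normalized: pd.DataFrame
    normalization_report: pd.DataFrame
    raw_copies: pd.DataFrame
    copy_numbers: pd.DataFrame
    calls: pd.DataFrame
    segments: pd.DataFrame
    burden: pd.Series
    recurrent_regions: pd.DataFrame
    region_tests: pd.DataFrame
    prevalence: pd.DataFrame
    decode: str = "posterior"
    _burden_test: Optional[WelchResult] = field(default=None, repr=False)

    def significant_regions(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.model.significance_params.alpha if alpha is None else alpha
        if self.region_tests.empty:
            return self.region_tests
        return self.region_tests[self.region_tests["p_value"] < alpha]

    def burden_test(self) -> WelchResult:
        if self._burden_test is None:
            self._burden_test = burden_ttest(self.burden, self.model.design)
        return self._burden_test

    def fragile_site_test(self, track: pd.DataFrame) -> tuple[pd.Series, WelchResult]:
        return fragile_site_gain_incidence(self.segments, track, self.model.design)

    def summary(self) -> str:
        """Plain-text summary of the fitted cohort analysis."""
        m = self.model
        counts = m.design["group"].value_counts()
        sig = self.significant_regions()
        lines = [
            "Copy-number cohort analysis",
            "=" * 60,
            f"cnacohort {__version__}   decode={self.decode}",
            f"Samples: {counts.get(GROUP_EXPOSED, 0)} exposed, "
            f"{counts.get(GROUP_UNEXPOSED, 0)} unexposed, "
            f"{counts.get(GROUP_REFERENCE, 0)} reference",
            f"Probes: {len(m.probe_map)} on "
            f"{m.probe_map['chrom'].nunique()} chromosomes",
            f"Calling: gain > {m.calling_params.gain_threshold}, "
            f"loss < {m.calling_params.loss_threshold}, "
            f"min run {m.calling_params.min_run} SNPs",
            f"Recurrence: >= {m.recurrence_params.min_fraction:.0%} of samples, "
            f">= {m.recurrence_params.min_probes} SNPs",
            "-" * 60,
            f"Altered segments: {len(self.segments)}  "
            f"(burden {str(self.burden_test())})",
            f"Recurrent regions: {len(self.recurrent_regions)}  "
            f"({int((self.recurrent_regions['direction'] == 'gain').sum()) if len(self.recurrent_regions) else 0} gain)",
            f"Regions with p < {m.significance_params.alpha}: {len(sig)}",
        ]
        if len(sig):
            lines.append("-" * 60)
            lines.append("chrom  start        end          dir    gainE  gainU  p        q")
            for _, r in sig.iterrows():
                lines.append(
                    f"{r['chrom']:<6s} {int(r['start_pos']):<12d} {int(r['end_pos']):<12d} "
                    f"{r['direction']:<6s} {int(r['gain_exposed']):<6d} "
                    f"{int(r['gain_unexposed']):<6d} {r['p_value']:<8.4g} {r['q_value']:.3g}"
                )
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> dict[str, str]:
        """Write the standard output set; returns {artifact: path}."""
        from .io import ensure_dir, write_calls, write_matrix, write_segments

        out = ensure_dir(out_dir)
        paths = {}

        def _save(name, fn):
            p = out / name
            fn(p)
            paths[name] = str(p)

        _save("normalized.tsv", lambda p: write_matrix(self.normalized, p))
        _save("normalization_report.tsv",
              lambda p: self.normalization_report.to_csv(p, sep="\t", index=False))
        _save("copy_numbers.tsv", lambda p: write_matrix(self.copy_numbers, p))
        _save("calls.tsv", lambda p: write_calls(self.calls, p))
        _save("segments.seg.tsv", lambda p: write_segments(self.segments, p))
        _save("burden.tsv",
              lambda p: self.burden.rename_axis("sample_id").to_csv(p, sep="\t"))
        _save("recurrent_regions.tsv",
              lambda p: self.recurrent_regions.to_csv(p, sep="\t", index=False))
        _save("region_tests.tsv",
              lambda p: self.region_tests.to_csv(p, sep="\t", index=False,
                                                 float_format="%.6g"))
        _save("prevalence.tsv",
              lambda p: self.prevalence.to_csv(p, sep="\t", index=False,
                                               float_format="%.6g"))
        return paths
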