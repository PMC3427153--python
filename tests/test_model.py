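import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import cnacohort as cc
from cnacohort.cli import main as cli_main
from conftest import SMALL_CHROMS, small_model

SMALL_CONFIG = {
    "seed": 7,
    "simulate": {
        "n_probes": 300,
        "chrom_lengths": SMALL_CHROMS,
        "cohort": {"exposed": 8, "unexposed": 6, "reference": 4},
        "segments": [
            {
                "chrom": "1",
                "start_pos": 5_000_000,
                "end_pos": 15_000_000,
                "true_copies": 3,
                "carrier_freq_exposed": 0.9,
                "carrier_freq_unexposed": 0.1,
            }
        ],
    },
}


class TestModelValidation:
    def test_missing_exposed_group_rejected(self):
        cohort = cc.simulate_cohort(
            seed=0, n_probes=120, chrom_lengths={"1": 5_000_000},
            cohort_sizes={"exposed": 2, "unexposed": 2, "reference": 2},
            segments=(),
        )
        design = cohort.design.copy()
        design.loc[design["group"] == "exposed", "group"] = "unexposed"
        with pytest.raises(ValueError, match="exposed"):
            cc.CnaCohortModel(cohort.intensities, cohort.probe_map, design)

    def test_sample_mismatch_rejected(self):
        cohort = cc.simulate_cohort(
            seed=0, n_probes=120, chrom_lengths={"1": 5_000_000},
            cohort_sizes={"exposed": 2, "unexposed": 2, "reference": 2},
            segments=(),
        )
        with pytest.raises(ValueError, match="samples"):
            cc.CnaCohortModel(
                cohort.intensities.iloc[:, :-1], cohort.probe_map, cohort.design
            )


class TestFittedResults:
    def test_stage_outputs_are_schema_consistent(self, small_fit):
        model, res = small_fit
        n_probes = len(model.probe_map)
        assert res.normalized.shape == model.intensities.shape
        assert (res.normalized.to_numpy() > 0).all()
        assert res.calls.shape == (n_probes, len(model.tumor_ids))
        assert set(np.unique(res.calls.to_numpy())) <= {-1, 0, 1}
        assert set(res.segments["sample_id"]) <= set(model.tumor_ids)
        assert (res.region_tests["q_value"] >= res.region_tests["p_value"] - 1e-12).all()
        assert (res.region_tests["p_reported"] <= res.region_tests["p_value"] + 1e-12).all()

    def test_prevalence_table_bounds(self, small_fit):
        _, res = small_fit
        cols = [c for c in res.prevalence.columns if c.endswith(("exposed", "unexposed"))]
        vals = res.prevalence[cols].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_summary_mentions_key_quantities(self, small_fit):
        _, res = small_fit
        text = res.summary()
        assert "Recurrent regions" in text
        assert "exposed" in text

    def test_planted_region_detected_and_associated(self, small_fit):
        model, res = small_fit
        seg = model.planted_segments[0]
        hits = res.region_tests[
            (res.region_tests["chrom"] == seg.chrom)
            & (res.region_tests["start_pos"] <= seg.end_pos)
            & (res.region_tests["end_pos"] >= seg.start_pos)
            & (res.region_tests["direction"] == "gain")
        ]
        assert len(hits) >= 1
        assert (hits["p_value"] < 0.05).any()

    def test_to_tsv_round_trip(self, small_fit, tmp_path):
        from cnacohort import io

        _, res = small_fit
        paths = res.to_tsv(tmp_path)
        calls = io.read_calls(paths["calls.tsv"])
        pd.testing.assert_frame_equal(
            calls, res.calls, check_dtype=False, check_index_type=False,
            check_names=False,
        )
        normalized = io.read_matrix(paths["normalized.tsv"])
        np.testing.assert_allclose(
            normalized.to_numpy(), res.normalized.to_numpy(), rtol=1e-4
        )


class TestCli:
    def _run(self, args):
        runner = CliRunner()
        result = runner.invoke(cli_main, args, catch_exceptions=False)
        return result

    def test_full_run_is_deterministic(self, tmp_path):
        cfg = tmp_path / "config.yaml"
        cfg.write_text(yaml.safe_dump(SMALL_CONFIG))
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        for out in (out1, out2):
            result = self._run(["run", "--config", str(cfg), "--out-dir", str(out)])
            assert result.exit_code == 0, result.output
            assert (out / "region_tests.tsv").exists()
            assert (out / "run_report.json").exists()
        for name in ("region_tests.tsv", "recurrent_regions.tsv", "calls.tsv",
                     "segments.seg.tsv", "prevalence.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_stagewise_commands_chain(self, tmp_path):
        cfg = tmp_path / "config.yaml"
        cfg.write_text(yaml.safe_dump(SMALL_CONFIG))
        sim = tmp_path / "sim"
        r = self._run(["simulate", "--config", str(cfg), "--out-dir", str(sim)])
        assert r.exit_code == 0, r.output
        norm = tmp_path / "norm"
        r = self._run(["normalize", "--intensities", str(sim / "intensities.tsv"),
                       "--out-dir", str(norm)])
        assert r.exit_code == 0, r.output
        cn = tmp_path / "cn"
        r = self._run(["callcn", "--normalized", str(norm / "normalized.tsv"),
                       "--probe-map", str(sim / "probe_map.tsv"),
                       "--design", str(sim / "design.tsv"),
                       "--out-dir", str(cn)])
        assert r.exit_code == 0, r.output
        reg = tmp_path / "reg"
        r = self._run(["regions", "--calls", str(cn / "calls.tsv"),
                       "--probe-map", str(sim / "probe_map.tsv"),
                       "--out-dir", str(reg)])
        assert r.exit_code == 0, r.output
        cmp_dir = tmp_path / "cmp"
        r = self._run(["compare", "--calls", str(cn / "calls.tsv"),
                       "--probe-map", str(sim / "probe_map.tsv"),
                       "--design", str(sim / "design.tsv"),
                       "--regions", str(reg / "recurrent_regions.tsv"),
                       "--out-dir", str(cmp_dir)])
        assert r.exit_code == 0, r.output
        tests = pd.read_csv(cmp_dir / "region_tests.tsv", sep="\t")
        assert "p_value" in tests.columns and "q_value" in tests.columns

    def test_missing_input_fails_with_path(self, tmp_path):
        r = CliRunner().invoke(
            cli_main,
            ["normalize", "--intensities", str(tmp_path / "nope.tsv"),
             "--out-dir", str(tmp_path / "out")],
        )
        assert r.exit_code != 0
        assert "nope.tsv" in r.output

    def test_reference_table_recomputes_published_pvalues(self, tmp_path):
        out = tmp_path / "table.tsv"
        r = self._run(["reference-table", "--out", str(out)])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out, sep="\t")
        assert len(table) == 12
        np.testing.assert_allclose(table["p_recomputed"], table["p_reported"])
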