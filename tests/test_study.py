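"""Study pipeline: eligibility, session policies, tables, reports, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from molarq.cli import main as cli_main
from molarq.geometry import ExclusionReason
from molarq.landmarks import CohortTable, write_annotations
from molarq.simulate import SimulatorParams, simulate_cohort
from molarq.study import (
    EruptionStudy,
    StudyConfig,
    correlation_study,
    inter_rater_study,
    intra_rater_study,
    measurement_table,
    run_eligibility,
    run_full_study,
)

from conftest import make_record


SMALL_COHORT = CohortTable({(age, sex): 3 for age in CohortTable.AGES
                            for sex in ("female", "male")})


@pytest.fixture(scope="module")
def small_dataset():
    params = SimulatorParams(cohort=SMALL_COHORT)
    return simulate_cohort(params, seed=31)


def synthetic_measurements(noise_sd: float, seed: int,
                           n_per_cell: int = 12) -> pd.DataFrame:
    """A measurement table with quotient strictly increasing in age."""
    rng = np.random.default_rng(seed)
    rows = []
    for side in (38, 48):
        for sex in ("male", "female"):
            ages = np.sort(rng.uniform(15, 26, n_per_cell))
            q_true = 0.3 + 0.6 * (ages - 15) / 11  # strictly increasing
            for i, (age, q) in enumerate(zip(ages, q_true)):
                for rater, session in (("R1", 1), ("R1", 2), ("R2", 1)):
                    rows.append({
                        "subject_id": f"{side}{sex[0]}{i}", "side": side,
                        "sex": sex, "age": age, "rater_id": rater,
                        "session": session, "d_m2": 4.5, "d_m3": 4.5 / q,
                        "quotient": q + rng.normal(0, noise_sd),
                        "units": "mm", "rounded": False,
                    })
    return pd.DataFrame(rows)


class TestRunEligibility:
    def test_all_clean_records_included(self, simple_points):
        records = [make_record(simple_points, subject_id=f"S{i}")
                   for i in range(4)]
        included, tally, results = run_eligibility(records)
        assert len(included) == 4 and tally == {}
        assert all(res.included for res in results.values())

    def test_conservation_per_reason(self, simple_points):
        good = make_record(simple_points, subject_id="G")
        missing = make_record(
            {k: v for k, v in simple_points.items() if k != "M3_MESIAL_CEJ"},
            subject_id="M")
        included, tally, _ = run_eligibility([good, missing])
        assert len(included) + sum(tally.values()) == 2
        assert tally == {ExclusionReason.MISSING_LANDMARK.value: 1}

    def test_sides_independent(self, simple_points):
        ok = make_record(simple_points, subject_id="S", side=38)
        bad = make_record(
            {k: v for k, v in simple_points.items() if k != "M2_MESIAL_CEJ"},
            subject_id="S", side=48)
        included, _, _ = run_eligibility([ok, bad])
        assert [(r.subject_id, r.side) for r in included] == [("S", 38)]


class TestCorrelationStudy:
    def test_perfect_monotone_dataset_gives_unit_rho(self):
        table = synthetic_measurements(noise_sd=0.0, seed=41)
        out = correlation_study(table)
        assert len(out) == 4
        assert out["estimable"].all()
        assert out["estimate"].to_numpy() == pytest.approx([1.0] * 4)

    def test_worked_four_point_cell(self):
        rows = [{"subject_id": f"S{i}", "side": 38, "sex": "male",
                 "age": a, "rater_id": "R1", "session": 2,
                 "d_m2": 1.0, "d_m3": 1.0, "quotient": q,
                 "units": "px", "rounded": False}
                for i, (a, q) in enumerate(zip((1, 2, 3, 4), (1, 3, 2, 4)))]
        # pad the other cells so they are flagged, not crashed
        out = correlation_study(pd.DataFrame(rows),
                                StudyConfig())
        cell = out[(out["side"] == 38) & (out["sex"] == "male")].iloc[0]
        assert cell["estimate"] == pytest.approx(0.8)
        assert not cell["estimable"]  # point estimate only: CI needs n >= 5
        empty = out[(out["side"] == 48)]
        assert not empty["estimable"].any()

    def test_session_policy_selects_rows(self):
        table = synthetic_measurements(noise_sd=0.0, seed=43)
        # corrupt every row except R2 session 1; policy must dodge them
        table.loc[table["rater_id"] != "R2", "quotient"] = \
            np.random.default_rng(0).uniform(size=(table["rater_id"] != "R2").sum())
        cfg = StudyConfig(correlation_session_policy=("R2", 1))
        out = correlation_study(table, cfg)
        assert out["estimate"].to_numpy() == pytest.approx([1.0] * 4)

    def test_null_dataset_ci_covers_zero(self):
        # quotient independent of age: CI should cover 0 in ~95% of seeds
        covered = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = [{"subject_id": f"S{i}", "side": 38, "sex": "male",
                     "age": a, "rater_id": "R1", "session": 2,
                     "d_m2": 1.0, "d_m3": 1.0, "quotient": q,
                     "units": "px", "rounded": False}
                    for i, (a, q) in enumerate(
                        zip(rng.uniform(15, 26, 40), rng.uniform(0.3, 1.0, 40)))]
            cell = correlation_study(pd.DataFrame(rows)).iloc[0]
            if cell["lcl"] <= 0.0 <= cell["ucl"]:
                covered += 1
        assert 0.90 * n_seeds <= covered <= n_seeds


class TestReliabilityStudies:
    def test_identical_sessions_give_alpha_one(self):
        table = synthetic_measurements(noise_sd=0.0, seed=47)
        cfg = StudyConfig(n_boot=50, seed=1)
        intra = intra_rater_study(table, cfg)
        inter = inter_rater_study(table, cfg)
        for out in (intra, inter):
            assert out["estimate"].to_numpy() == pytest.approx([1.0] * 4)

    def test_affine_shift_of_one_session_lowers_alpha(self):
        # interval alpha is affine invariant only when BOTH columns
        # transform; shifting one session must reduce agreement below 1
        table = synthetic_measurements(noise_sd=0.0, seed=53)
        shifted = table.copy()
        mask = (shifted["rater_id"] == "R1") & (shifted["session"] == 2)
        shifted.loc[mask, "quotient"] = 1.1 * shifted.loc[mask, "quotient"] + 0.2
        cfg = StudyConfig(n_boot=0, seed=1)
        out = intra_rater_study(shifted, cfg)
        assert (out["estimate"] < 1.0).all()

    def test_unpaired_unit_dropped_and_noted(self):
        table = synthetic_measurements(noise_sd=0.0, seed=59)
        # remove session 2 for one subject: unit has a single rating
        drop = (table["subject_id"] == "38m0") & (table["session"] == 2) \
            & (table["rater_id"] == "R1")
        table = table[~drop]
        cfg = StudyConfig(n_boot=0, seed=1)
        out = intra_rater_study(table, cfg)
        cell = out[(out["side"] == 38) & (out["sex"] == "male")].iloc[0]
        assert "dropped" in cell["note"]

    def test_missing_dual_session_rater_is_config_error(self):
        table = synthetic_measurements(noise_sd=0.0, seed=61)
        table = table[table["session"] == 1]
        with pytest.raises(ValueError, match="intra-rater"):
            intra_rater_study(table, StudyConfig(n_boot=0))

    def test_missing_second_rater_is_config_error(self):
        table = synthetic_measurements(noise_sd=0.0, seed=67)
        table = table[table["rater_id"] == "R1"]
        with pytest.raises(ValueError, match="inter-rater"):
            inter_rater_study(table, StudyConfig(n_boot=0))


class TestEndToEnd:
    def test_full_study_structure(self, small_dataset):
        records, _ = small_dataset
        cfg = StudyConfig(seed=3, n_boot=100)
        results = EruptionStudy(records, cfg).fit()
        assert results.n_records == len(records)
        included_count = results.n_included
        excluded_records = sum(
            1 for rec in records
            if not run_eligibility([rec], cfg)[0])
        assert included_count + excluded_records == len(records)
        for table in (results.correlation, results.intra_rater,
                      results.inter_rater):
            assert len(table) == 4
            est = table.loc[table["estimable"], "estimate"]
            assert (est <= 1.0).all()
        # estimates inside their own CI bounds
        for table in (results.intra_rater, results.inter_rater):
            ok = table[table["estimable"]]
            assert (ok["lcl"] <= ok["estimate"] + 1e-12).all()
            assert (ok["estimate"] <= ok["ucl"] + 1e-12).all()

    def test_report_files_and_determinism(self, small_dataset, tmp_path):
        records, _ = small_dataset
        ann = tmp_path / "ann.csv"
        write_annotations(records, ann)
        cfg = StudyConfig(seed=5, n_boot=60)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        res = run_full_study(ann, out1, config=cfg)
        run_full_study(ann, out2, config=cfg)
        assert (out1 / "report.json").read_bytes() == \
            (out2 / "report.json").read_bytes()
        for name in ("correlation", "intra_rater", "inter_rater"):
            assert (out1 / f"{name}.tsv").exists()
        payload = json.loads((out1 / "report.json").read_text())
        assert payload["counts"]["records"] == len(records)
        assert payload["provenance"]["config"]["seed"] == 5

    def test_tsv_formatting_contract(self, tmp_path):
        table = synthetic_measurements(noise_sd=0.01, seed=71)
        cfg = StudyConfig(n_boot=50, seed=2)
        from molarq.study import StudyResults, write_report
        results = StudyResults(
            config=cfg, n_records=len(table), n_included=len(table),
            exclusion_tally={}, n_measurement_failures=0,
            correlation=correlation_study(table, cfg),
            intra_rater=intra_rater_study(table, cfg),
            inter_rater=inter_rater_study(table, cfg),
        )
        paths = write_report(results, tmp_path / "rep")
        lines = paths["correlation"].read_text().splitlines()
        assert lines[0] == "tooth\tsex\trho\tlcl\tucl\tn"
        fields = lines[1].split("\t")
        assert fields[0] in ("38", "48")
        assert len(fields[2].split(".")[1]) == 3  # 3 decimal places

    def test_not_estimable_cells_marked_not_omitted(self, tmp_path):
        # single tiny cell: every other cell must still appear, marked NE
        rows = [{"subject_id": f"S{i}", "side": 38, "sex": "male",
                 "age": 15 + i, "rater_id": "R1", "session": 2,
                 "d_m2": 1.0, "d_m3": 1.0, "quotient": 0.1 * i,
                 "units": "px", "rounded": False} for i in range(6)]
        out = correlation_study(pd.DataFrame(rows))
        assert len(out) == 4
        assert out["estimable"].sum() == 1


class TestCli:
    def test_simulate_measure_study_round_trip(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "sim")
        params = tmp_path / "params.json"
        params.write_text(json.dumps({
            "landmark_noise_sd": 1.0,
            "cohort": {str(age): {"female": 2, "male": 2}
                       for age in range(15, 26)},
        }))
        res = runner.invoke(cli_main, ["simulate", "--params", str(params),
                                       "--seed", "3", "--out", prefix])
        assert res.exit_code == 0, res.output
        ann = f"{prefix}_annotations.csv"
        res = runner.invoke(cli_main, ["measure", ann, "--out",
                                       str(tmp_path / "meas.csv")])
        assert res.exit_code == 0, res.output
        config = tmp_path / "config.json"
        config.write_text(json.dumps({"n_boot": 50}))
        outdir = tmp_path / "report"
        res = runner.invoke(cli_main, ["study", "full", ann,
                                       "--config", str(config), "--seed", "3",
                                       "--out", str(outdir)])
        assert res.exit_code == 0, res.output
        assert (outdir / "report.json").exists()
        assert "Spearman rho" in res.output
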