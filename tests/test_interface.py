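"""Config I/O, data-dictionary and record CSV export, and the CLI."""

import csv

import pytest
from click.testing import CliRunner

from ttocapi import (
    SessionRecord,
    TerminationReason,
    UtilityResult,
    default_project,
    export_records,
    load_project,
    read_data_dictionary,
    save_project,
    simulate_cohort,
    write_data_dictionary,
)
from ttocapi.cli import main
from ttocapi.io import DATA_DICTIONARY_COLUMNS, ExportError


def read_rows(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


class TestProjectConfig:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, tmp_path, project, suffix):
        path = tmp_path / f"project{suffix}"
        save_project(project, path)
        assert load_project(path) == project

    def test_bad_condition_rejected_at_load(self, tmp_path, project):
        from dataclasses import replace

        broken = replace(project, queue_conditions={"mild_ad": "[mod6]<"})
        path = tmp_path / "broken.yaml"
        save_project(broken, path)
        with pytest.raises(Exception):
            load_project(path)


class TestDataDictionary:
    def test_standard_header_and_four_forms(self, tmp_path, project):
        path = tmp_path / "dict.csv"
        write_data_dictionary(project, path)
        with open(path, newline="", encoding="utf-8") as fh:
            header = next(csv.reader(fh))
        assert tuple(header) == DATA_DICTIONARY_COLUMNS
        rows = read_rows(path)
        assert {r["Form Name"] for r in rows} == {
            "preliminary", "mild_ad", "moderate_ad", "severe_ad"
        }

    def test_radio_choices_use_redcap_syntax(self, tmp_path, project):
        path = tmp_path / "dict.csv"
        write_data_dictionary(project, path)
        row = next(
            r for r in read_rows(path)
            if r["Variable / Field Name"] == "prelim_eq5d_mobility"
        )
        assert row["Choices, Calculations, OR Slider Labels"].startswith(
            "1, No problems | 2, Slight problems"
        )

    def test_round_trip_reconstructs_equivalent_project(self, tmp_path, project):
        path = tmp_path / "dict.csv"
        write_data_dictionary(project, path)
        rebuilt = read_data_dictionary(
            path,
            name=project.name,
            randomization_var=project.randomization_var,
            queue_conditions=project.queue_conditions,
            completion_flags={
                i.name: i.completion_flag_var for i in project.instruments
            },
            labels={i.name: i.label for i in project.instruments},
        )
        assert rebuilt == project


def result_for(utility, a):
    return UtilityResult(utility, a, TerminationReason.EQUIVALENCE)


class TestExportRecords:
    def test_columns_do_not_depend_on_task_order(self, tmp_path, project):
        # one respondent randomized to order 1, another to order 6
        recs = []
        for rid, mod6, done_order in [
            ("1", 1, ("mild_ad", "moderate_ad", "severe_ad")),
            ("2", 6, ("severe_ad", "moderate_ad", "mild_ad")),
        ]:
            rec = SessionRecord(record_id=rid, mod6=mod6)
            rec.completion_flags[project.preliminary.name] = 2
            for name in done_order:
                rec.completion_flags[name] = 2
                rec.utilities[name] = result_for(0.5, 15.0)
            recs.append(rec)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_records(project, [recs[0]], p1)
        export_records(project, [recs[1]], p2)
        with open(p1, newline="") as f1, open(p2, newline="") as f2:
            assert next(csv.reader(f1)) == next(csv.reader(f2))

    def test_identical_answers_export_identically_regardless_of_order(
        self, tmp_path, project
    ):
        def make(rid, mod6):
            rec = SessionRecord(record_id=rid, mod6=mod6)
            rec.completion_flags[project.preliminary.name] = 2
            rec.field_values["age"] = 46
            for name in ("mild_ad", "moderate_ad", "severe_ad"):
                rec.completion_flags[name] = 2
                rec.utilities[name] = result_for(0.25, 12.5)
            return rec

        path = tmp_path / "both.csv"
        export_records(project, [make("1", 1), make("2", 6)], path)
        rows = read_rows(path)
        a = {k: v for k, v in rows[0].items() if k not in ("record_id", "mod6")}
        b = {k: v for k, v in rows[1].items() if k not in ("record_id", "mod6")}
        assert a == b

    def test_empty_record_list_gives_header_only(self, tmp_path, project):
        path = tmp_path / "empty.csv"
        export_records(project, [], path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 1
        assert "record_id" in rows[0]

    def test_duplicate_record_id_is_an_error(self, tmp_path, project):
        recs = [SessionRecord(record_id="1"), SessionRecord(record_id="1")]
        with pytest.raises(ExportError):
            export_records(project, recs, tmp_path / "dup.csv")

    def test_selective_instrument_export(self, tmp_path, project):
        records = simulate_cohort(3, project, seed=9)
        path = tmp_path / "mild.csv"
        export_records(project, records, path, instruments=["mild_ad"])
        rows = read_rows(path)
        cols = rows[0].keys()
        assert "mild_ad_tto_indifference" in cols
        assert "part1_complete" in cols
        assert not any(c.startswith("severe_ad") for c in cols)
        assert not any(c.startswith("prelim") for c in cols)

    def test_simulated_cohort_round_trips_through_export(self, tmp_path, project):
        records = simulate_cohort(5, project, seed=4)
        path = tmp_path / "cohort.csv"
        export_records(project, records, path)
        rows = read_rows(path)
        assert len(rows) == 5
        for rec, row in zip(records, rows):
            assert row["record_id"] == rec.record_id
            assert int(row["mod6"]) == rec.mod6
            assert float(row["mild_ad_tto_utility"]) == pytest.approx(
                rec.utilities["mild_ad"].utility, abs=1e-6
            )


class TestCLI:
    def test_verify_queue_prints_six_orders(self):
        result = CliRunner().invoke(main, ["verify-queue", "--config", "default"])
        assert result.exit_code == 0
        assert result.output.count("mod6=") >= 6
        assert "OK" in result.output

    def test_simulate_is_byte_identical_for_a_seed(self, tmp_path):
        runner = CliRunner()
        outs = []
        for sub in ("a", "b"):
            outdir = tmp_path / sub
            result = runner.invoke(
                main,
                ["simulate", "--n", "10", "--seed", "7", "--out", str(outdir)],
            )
            assert result.exit_code == 0, result.output
            outs.append(
                (outdir / "cohort.csv").read_bytes()
                + (outdir / "recovery.csv").read_bytes()
            )
        assert outs[0] == outs[1]

    def test_run_with_always_equivalent_input(self, tmp_path):
        out = tmp_path / "record.csv"
        result = CliRunner().invoke(
            main,
            ["run", "--seed", "3", "--out", str(out)],
            input="3\n3\n3\n",
        )
        assert result.exit_code == 0, result.output
        row = read_rows(out)[0]
        for name in ("mild_ad", "moderate_ad", "severe_ad"):
            assert float(row[f"{name}_tto_utility"]) == pytest.approx(1.0)

    def test_export_dict_writes_file(self, tmp_path):
        out = tmp_path / "dict.csv"
        result = CliRunner().invoke(main, ["export-dict", "--out", str(out)])
        assert result.exit_code == 0
        assert out.exists()

    def test_usage_error_exits_two(self):
        result = CliRunner().invoke(main, ["simulate", "--n", "notanumber"])
        assert result.exit_code == 2
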