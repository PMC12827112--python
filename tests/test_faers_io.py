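import numpy as np
import pandas as pd
import pytest

import faerskit as fk
from faerskit import faers_io
from faerskit.errors import ConfigError, FormatError


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadAsciiTable:
    def test_parses_dollar_delimited_rows(self, tmp_path):
        path = _write(tmp_path, "demo.txt", "caseid$caseversion$fda_dt$sex\nC1$2$20240101$F\n")
        df = faers_io.read_ascii_table(path, "demo")
        assert df.iloc[0].tolist() == ["C1", "2", "20240101", "F"]

    def test_empty_file_after_header(self, tmp_path):
        path = _write(tmp_path, "reac.txt", "caseid$pt\n")
        assert faers_io.read_ascii_table(path, "reac").empty

    def test_ragged_line_reports_line_number(self, tmp_path):
        path = _write(
            tmp_path, "demo.txt",
            "caseid$caseversion$fda_dt$sex\nC1$1$20240101$F\nC2$1$20240101\n",
        )
        with pytest.raises(FormatError, match="line 3"):
            faers_io.read_ascii_table(path, "demo")

    def test_missing_mandatory_column_named(self, tmp_path):
        path = _write(tmp_path, "demo.txt", "caseid$fda_dt$sex\nC1$20240101$F\n")
        with pytest.raises(FormatError, match="caseversion"):
            faers_io.read_ascii_table(path, "demo")

    def test_unknown_columns_ignored(self, tmp_path):
        path = _write(tmp_path, "reac.txt", "caseid$pt$mystery\nC1$HEADACHE$x\n")
        df = faers_io.read_ascii_table(path, "reac")
        assert list(df.columns) == ["caseid", "pt"]

    def test_write_read_round_trip(self, tmp_path):
        tables, _ = fk.simulate_reports(fk.SimConfig(n_reports=50, seed=5))
        path = tmp_path / "demo.txt"
        faers_io.write_ascii_table(tables.demo, path)
        back = faers_io.read_ascii_table(path, "demo")
        pd.testing.assert_frame_equal(back, tables.demo.astype(str))


class TestDeduplicateCases:
    def _demo(self, rows):
        return pd.DataFrame(rows, columns=["caseid", "caseversion", "fda_dt", "sex"])

    def test_keeps_highest_version(self):
        demo = self._demo([("C1", "1", "20230101", "F"), ("C1", "2", "20230601", "F")])
        out = faers_io.deduplicate_cases(demo)
        assert out["caseversion"].tolist() == ["2"]

    def test_version_outranks_date(self):
        demo = self._demo([("C1", "2", "20230101", "F"), ("C1", "1", "20230601", "F")])
        out = faers_io.deduplicate_cases(demo)
        assert out["caseversion"].tolist() == ["2"]

    def test_idempotent(self):
        demo = self._demo(
            [("C2", "1", "20230101", "M"), ("C1", "1", "20230101", "F"),
             ("C1", "2", "20230601", "F")]
        )
        once = faers_io.deduplicate_cases(demo)
        twice = faers_io.deduplicate_cases(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_recovers_original_cases_after_duplicate_injection(self):
        cfg = fk.SimConfig(n_reports=1000, duplicate_rate=0.2, seed=11)
        tables, truth = fk.simulate_reports(cfg)
        assert len(tables.demo) == 1200
        deduped = faers_io.deduplicate_cases(tables.demo)
        assert set(deduped["caseid"]) == set(truth.case_ids)
        kept = set(zip(deduped["caseid"], deduped["caseversion"]))
        assert not kept & set(truth.duplicate_rows)


class TestNormalizeDemographics:
    def _one(self, **fields):
        base = {"caseid": "C1", "caseversion": "1", "fda_dt": "20240101", "sex": "F"}
        base.update(fields)
        return faers_io.normalize_demographics(pd.DataFrame([base])).iloc[0]

    def test_age_unit_conversions(self):
        assert self._one(age="72", age_cod="MON")["age_years"] == pytest.approx(6.0)
        assert self._one(age="5", age_cod="DEC")["age_years"] == pytest.approx(50.0)

    def test_weight_pounds_to_kg(self):
        row = self._one(wt="154.3", wt_cod="LBS")
        assert round(row["weight_kg"], 2) == 69.99

    def test_unknown_sex_code(self):
        assert self._one(sex="UNK")["sex_norm"] == "Unknown"

    @pytest.mark.parametrize(
        "age,expected",
        [("17.9", "<18"), ("18", "18-45"), ("44.9", "18-45"), ("45", "45-65"),
         ("65", ">=65"), ("", "Unknown")],
    )
    def test_age_bins_left_closed(self, age, expected):
        assert self._one(age=age, age_cod="YR")["age_bin"] == expected

    def test_bad_values_degrade_to_unknown(self):
        row = self._one(age="abc", age_cod="YR", wt="-3", wt_cod="KG")
        assert np.isnan(row["age_years"]) and np.isnan(row["weight_kg"])
        assert row["age_bin"] == "Unknown"


class TestFindExposedCases:
    def _drug(self, rows):
        return pd.DataFrame(rows, columns=["caseid", "drug_seq", "drugname", "role_cod", "route"])

    def test_secondary_suspect_not_exposed(self):
        drug = self._drug([("C1", "1", "BARICITINIB", "SS", "Oral")])
        assert faers_io.find_exposed_cases(drug, {"baricitinib"}) == set()

    def test_name_normalization_and_synonyms(self):
        drug = self._drug([("C2", "1", " olumiant ", "PS", "Oral")])
        assert faers_io.find_exposed_cases(drug, {"BARICITINIB", "OLUMIANT"}) == {"C2"}

    def test_empty_synonyms_rejected(self):
        with pytest.raises(ConfigError):
            faers_io.find_exposed_cases(self._drug([]), set())

    def test_matches_simulation_truth(self):
        tables, truth = fk.simulate_reports(fk.SimConfig(n_reports=2000, seed=3))
        got = faers_io.find_exposed_cases(tables.drug, {"baricitinib"})
        assert got == truth.exposed_ids()


class TestAssembleDataset:
    def _tables(self, event_dt="20230310", start_dt="20230301", orphan=False):
        demo = pd.DataFrame(
            [{"caseid": "C1", "caseversion": "1", "fda_dt": "20230401",
              "event_dt": event_dt, "sex": "F"}]
        )
        drug = pd.DataFrame(
            [{"caseid": "C1", "drug_seq": "1", "drugname": "STUDYDRUG",
              "role_cod": "PS", "route": "Oral"}]
        )
        reac = pd.DataFrame(
            [{"caseid": "C1", "pt": "HEADACHE"}]
            + ([{"caseid": "C9", "pt": "NAUSEA"}] if orphan else [])
        )
        ther = pd.DataFrame(
            [{"caseid": "C1", "dsg_drug_seq": "1", "start_dt": start_dt}]
            if start_dt else pd.DataFrame(columns=["caseid", "dsg_drug_seq", "start_dt"])
        )
        outc = pd.DataFrame(columns=["caseid", "outc_cod"])
        return demo, drug, reac, ther, outc

    def test_onset_days_from_dates(self):
        ds = faers_io.assemble_dataset(*self._tables(), {"studydrug"})
        assert ds.cases["onset_days"].iloc[0] == 9.0

    def test_missing_therapy_start_gives_missing_onset(self):
        ds = faers_io.assemble_dataset(*self._tables(start_dt=None), {"studydrug"})
        assert np.isnan(ds.cases["onset_days"].iloc[0])

    def test_negative_onset_treated_as_missing(self):
        ds = faers_io.assemble_dataset(
            *self._tables(event_dt="20230301", start_dt="20230310"), {"studydrug"}
        )
        assert np.isnan(ds.cases["onset_days"].iloc[0])

    def test_orphan_reaction_dropped_and_logged(self):
        ds = faers_io.assemble_dataset(*self._tables(orphan=True), {"studydrug"})
        assert set(ds.reactions["caseid"]) == {"C1"}
        assert any(e["step"] == "filter_reac" for e in ds.log)

    def test_exposure_partition_conserved(self):
        tables, _ = fk.simulate_reports(fk.SimConfig(n_reports=3000, seed=9))
        ds = faers_io.assemble_dataset(
            tables.demo, tables.drug, tables.reac, tables.ther, tables.outc,
            {"baricitinib"},
        )
        unexposed = ds.case_ids - ds.exposed
        assert len(ds.exposed) + len(unexposed) == ds.n_cases


class TestDates:
    @pytest.mark.parametrize(
        "raw,expected,approx",
        [
            ("20240131", pd.Timestamp(2024, 1, 31), False),
            ("202403", pd.Timestamp(2024, 3, 15), True),
            ("2021", pd.Timestamp(2021, 7, 1), True),
        ],
    )
    def test_partial_date_imputation(self, raw, expected, approx):
        got, got_approx = faers_io.parse_faers_date(raw)
        assert got == expected and got_approx is approx

    @pytest.mark.parametrize("raw", ["", "20231340", "notadate", "123"])
    def test_unparseable_dates_are_missing(self, raw):
        got, _ = faers_io.parse_faers_date(raw)
        assert pd.isna(got)
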