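"""Curation protocol: filtering, unit standardization, per-compound aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uqscreen.data_prep import (
    EXTENDED_RELATIONS,
    UNIT_TO_NM,
    EmptyDatasetError,
    aggregate_per_compound,
    curate,
    filter_records,
    read_activity_csv,
    standardize_records,
    standardize_value,
)

from conftest import make_record


class TestFilterRecords:
    def test_strict_mode_keeps_only_equality_relation(self):
        recs = [make_record(f"R{i}", f"C{i}") for i in range(4)]
        recs.append(make_record("R4", "C4", relation="<"))
        kept, report = filter_records(recs, "strict")
        assert len(kept) == 4
        stages = dict((s, (i, o)) for s, i, o in report.stages)
        assert stages["relation_filter"] == (5, 4)

    def test_extended_mode_keeps_inequalities(self):
        recs = [make_record(f"R{i}", f"C{i}") for i in range(4)]
        recs.append(make_record("R4", "C4", relation="<"))
        kept, _ = filter_records(recs, "extended")
        assert len(kept) == 5
        assert "<" in EXTENDED_RELATIONS

    def test_unknown_unit_dropped_at_unit_stage_not_crash(self):
        recs = [make_record("R0", "C0"), make_record("R1", "C1", unit="µg/mL")]
        kept, report = filter_records(recs)
        assert [r.record_id for r in kept] == ["R0"]
        stages = dict((s, (i, o)) for s, i, o in report.stages)
        assert stages["unit_filter"] == (2, 1)

    def test_unknown_parameter_dropped(self):
        recs = [make_record("R0", "C0"), make_record("R1", "C1", parameter="EC50")]
        kept, report = filter_records(recs)
        assert len(kept) == 1
        stages = dict((s, (i, o)) for s, i, o in report.stages)
        assert stages["parameter_filter"] == (2, 1)

    def test_empty_output_raises_explicit_signal(self):
        with pytest.raises(EmptyDatasetError):
            filter_records([make_record(relation="<")], "strict")

    def test_idempotence(self, toy_records):
        kept, _ = filter_records(toy_records, "strict")
        kept2, report2 = filter_records(kept, "strict")
        assert kept2 == kept
        assert report2.dropped == 0

    def test_count_conservation(self, toy_records):
        for mode in ("strict", "extended"):
            kept, report = filter_records(toy_records, mode)
            assert report.dropped + len(kept) == len(toy_records)
            # stages appear in protocol order and chain their counts
            for (s1, i1, o1), (s2, i2, o2) in zip(report.stages, report.stages[1:]):
                assert o1 == i2


class TestStandardizeValue:
    @pytest.mark.parametrize(
        "parameter,value,unit,expected",
        [
            ("IC50", 100.0, "nM", math.log10(50.0)),  # Ki = IC50/2 then log10
            ("Ki", 1.0, "µM", 3.0),
            ("Ki", 0.2, "nM", math.log10(0.2)),
            ("Ki", 1.0, "nM", 0.0),
            ("Ki", 1.0, "M", 9.0),
            ("Ki", 1.0, "pM", -3.0),
            ("pKi", 9.0, None, 0.0),  # pKi 9 = 1 nM
            ("pKi", 6.0, None, 3.0),
            ("pIC50", 9.0, None, -math.log10(2.0)),  # IC50 1 nM -> Ki 0.5 nM
        ],
    )
    def test_standardizes_to_log10_ki_nm(self, parameter, value, unit, expected):
        assert standardize_value(parameter, "=", value, unit) == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="log undefined"):
            standardize_value("Ki", "=", -5.0, "nM")
        with pytest.raises(ValueError, match="log undefined"):
            standardize_value("IC50", "=", 0.0, "nM")

    @pytest.mark.parametrize("parameter", ["logKi", "logIC50"])
    def test_plain_log_forms_rejected_not_guessed(self, parameter):
        with pytest.raises(ValueError, match="base/unit"):
            standardize_value(parameter, "=", 2.0, None)

    @given(
        value=st.floats(min_value=1e-6, max_value=1e6),
        unit=st.sampled_from(sorted(UNIT_TO_NM)),
    )
    @settings(max_examples=200, deadline=None)
    def test_unit_round_trip(self, value, unit):
        nm = value * UNIT_TO_NM[unit]
        back = nm / UNIT_TO_NM[unit]
        assert back == pytest.approx(value, rel=1e-12)

    def test_rejects_appear_in_standardize_records(self):
        recs = [make_record("R0", "C0"), make_record("R1", "C1", value=-1.0)]
        ok, rejected = standardize_records(recs)
        assert len(ok) == 1 and len(rejected) == 1
        assert rejected[0][0].record_id == "R1"


class TestAggregate:
    def test_two_measurements_mean_log(self):
        # Ki values 37 and 68.2 nM: label is the mean of the log10 values
        recs = [
            make_record("R0", "CHEMBL139089", value=37.0),
            make_record("R1", "CHEMBL139089", value=68.2),
        ]
        out = aggregate_per_compound(standardize_records(recs)[0])
        (c,) = out
        expected = (math.log10(37.0) + math.log10(68.2)) / 2  # ≈ 1.70098
        assert c.n_values == 2
        assert c.mean_log_activity == pytest.approx(expected, abs=1e-10)
        assert c.label == c.mean_log_activity
        assert expected == pytest.approx(1.70099, abs=1e-5)

    def test_single_measurement_has_zero_std(self):
        recs = [make_record("R0", "CHEMBL317433", value=0.2)]
        (c,) = aggregate_per_compound(standardize_records(recs)[0])
        assert c.n_values == 1
        assert c.std_log_activity == 0.0
        assert c.label == pytest.approx(math.log10(0.2))

    def test_label_between_min_and_max(self, rng):
        recs = [
            make_record(f"R{i}", "C0", value=float(v))
            for i, v in enumerate(rng.uniform(0.1, 1000.0, size=20))
        ]
        (c,) = aggregate_per_compound(standardize_records(recs)[0])
        assert min(c.log_activities) <= c.label <= max(c.log_activities)

    def test_conflicting_smiles_raises_naming_compound(self):
        recs = [
            make_record("R0", "C0", smiles="CCO"),
            make_record("R1", "C0", smiles="CCN"),
        ]
        with pytest.raises(ValueError, match="C0"):
            aggregate_per_compound(standardize_records(recs)[0])

    def test_output_sorted_by_compound_id(self):
        recs = [make_record("R0", "B"), make_record("R1", "A"), make_record("R2", "C")]
        out = aggregate_per_compound(standardize_records(recs)[0])
        assert [c.compound_id for c in out] == ["A", "B", "C"]

    def test_duplicate_values_count_as_separate_measurements(self):
        recs = [make_record("R0", "C0", value=10.0), make_record("R1", "C0", value=10.0)]
        (c,) = aggregate_per_compound(standardize_records(recs)[0])
        assert c.n_values == 2
        assert c.std_log_activity == 0.0

    def test_nm_scale_mean_also_reported(self):
        recs = [make_record("R0", "C0", value=37.0), make_record("R1", "C0", value=68.2)]
        (c,) = aggregate_per_compound(standardize_records(recs)[0])
        assert c.mean_activity_nm == pytest.approx((37.0 + 68.2) / 2)


class TestCsvRoundTrip:
    def test_read_and_curate_from_csv(self, tmp_path):
        csv = tmp_path / "raw.csv"
        csv.write_text(
            "molecule_chembl_id,canonical_smiles,target_chembl_id,standard_type,"
            "standard_relation,standard_value,standard_units\n"
            "C1,,T1,Ki,=,100,nM\n"
            "C1,,T1,Ki,=,1,µM\n"
            "C2,,T1,IC50,=,200,nM\n"
            "C3,,T1,Ki,<,50,nM\n"
            "C4,,T1,Ki,=,oops,nM\n"
        )
        records = read_activity_csv(csv)
        assert len(records) == 5
        curated, report = curate(records, "strict")
        by_id = {c.compound_id: c for c in curated}
        assert set(by_id) == {"C1", "C2"}
        assert by_id["C1"].n_values == 2
        assert by_id["C1"].label == pytest.approx((2.0 + 3.0) / 2)
        assert by_id["C2"].label == pytest.approx(2.0)  # IC50 200 -> Ki 100 nM
        assert report.records_in == 5
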