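"""Plate-table parsing, replicate aggregation, QC and standard-curve fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scallopsex import (
    CtRecord,
    aggregate_replicates,
    check_controls,
    fit_standard_curve,
    read_ct_table,
    write_ct_table,
)
from scallopsex.errors import (
    InsufficientDataError,
    InvalidCurveError,
    SchemaError,
    ValidationError,
)
from scallopsex.synth import simulate_dilution_series

HEADER = "sample_id,gene,replicate,ct,role,dilution_step\n"


def write(tmp_path, body, name="plate.csv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadCtTable:
    def test_row_count_identity(self, tmp_path):
        p = write(tmp_path, "s1,FOXL2,1,20.0,unknown,\ns1,FOXL2,2,20.1,unknown,\ns1,EF1A,1,19.5,unknown,\n")
        assert len(read_ct_table(p)) == 3

    def test_undetermined_ct_becomes_missing(self, tmp_path, caplog):
        p = write(tmp_path, "s1,FOXL2,1,Undetermined,unknown,\n")
        with caplog.at_level("WARNING"):
            (rec,) = read_ct_table(p)
        assert rec == CtRecord("s1", "FOXL2", 1, None, "unknown", None)
        assert any("undetermined" in m.lower() for m in caplog.messages)

    def test_missing_gene_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,replicate,ct,role,dilution_step\ns1,1,20.0,unknown,\n")
        with pytest.raises(SchemaError, match="gene"):
            read_ct_table(p)

    def test_duplicate_well_rejected(self, tmp_path):
        p = write(tmp_path, "s1,FOXL2,1,20.0,unknown,\ns1,FOXL2,1,20.3,unknown,\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_ct_table(p)

    def test_standard_requires_dilution_step(self, tmp_path):
        p = write(tmp_path, "std,FOXL2,1,20.0,standard,\n")
        with pytest.raises(ValidationError, match="dilution_step"):
            read_ct_table(p)

    def test_tab_dialect(self, tmp_path):
        p = tmp_path / "plate.tsv"
        p.write_text(HEADER.replace(",", "\t") + "s1\tFOXL2\t1\t20.0\tunknown\t\n")
        assert read_ct_table(p, sep="\t")[0].ct == 20.0

    def test_round_trip_bit_exact(self, tmp_path):
        records = [
            CtRecord("s1", "FOXL2", 1, 20.123456789, "unknown", None),
            CtRecord("s1", "EF1A", 2, None, "unknown", None),
            CtRecord("ntc", "FOXL2", 1, None, "ntc", None),
            CtRecord("std", "FOXL2", 1, 15.0000001, "standard", 3),
        ]
        p = tmp_path / "out.csv"
        write_ct_table(records, p)
        assert read_ct_table(p) == records


class TestAggregateReplicates:
    def make(self, cts, sample="s1", gene="FOXL2"):
        return [CtRecord(sample, gene, i + 1, ct, "unknown") for i, ct in enumerate(cts)]

    @pytest.mark.parametrize(
        "cts, mean, sd, n",
        [
            ([20.0, 20.0, 20.0], 20.0, 0.0, 3),
            # oracle: sample SD (ddof=1) of {19.8, 20.0, 20.2} = sqrt(0.04/2 + 0.04/2) = 0.2
            ([19.8, 20.0, 20.2], 20.0, 0.2, 3),
            ([20.0, None, 20.4], 20.2, None, 2),  # missing excluded
        ],
    )
    def test_mean_and_sd(self, cts, mean, sd, n):
        out = aggregate_replicates(self.make(cts))
        row = out.iloc[0]
        assert row.mean_ct == pytest.approx(mean)
        assert row.n_used == n
        if sd is not None:
            assert row.sd_ct == pytest.approx(sd)

    def test_high_sd_flagged_not_dropped(self):
        out = aggregate_replicates(self.make([19.0, 20.0, 21.0]), max_sd=0.5)
        assert out.iloc[0].flag == "high_sd"
        assert np.isfinite(out.iloc[0].mean_ct)

    def test_all_missing_group_propagates_as_missing(self, caplog):
        records = self.make([None, None, None]) + self.make([20.0], sample="s2")
        with caplog.at_level("WARNING"):
            out = aggregate_replicates(records)
        row = out[out.sample_id == "s1"].iloc[0]
        assert math.isnan(row.mean_ct) and row.flag == "all_missing"

    def test_rejects_non_unknown_roles(self):
        with pytest.raises(ValidationError):
            aggregate_replicates([CtRecord("ntc", "FOXL2", 1, None, "ntc")])


class TestCheckControls:
    def test_flags_amplifying_ntc_only(self):
        records = [
            CtRecord("ntc1", "FOXL2", 1, None, "ntc"),  # clean
            CtRecord("ntc2", "FOXL2", 1, 25.0, "ntc"),  # contamination
            CtRecord("nrt", "FOXL2", 1, 36.0, "no_rt"),  # above the gate
        ]
        report = check_controls(records, min_ntc_ct=35.0)
        status = {w["sample_id"]: w["status"] for w in report["wells"]}
        assert status == {"ntc1": "pass", "ntc2": "fail", "nrt": "pass"}
        assert report["n_fail"] == 1

    def test_no_controls_noted(self):
        report = check_controls([CtRecord("s1", "FOXL2", 1, 20.0, "unknown")])
        assert report["note"] == "no controls found"


class TestStandardCurve:
    def test_perfect_doubling(self):
        # Ct up exactly one cycle per twofold dilution: slope -1/log10(2), E = 1
        records = simulate_dilution_series("FOXL2", efficiency=1.0, n_steps=6)
        curve = fit_standard_curve(records, "FOXL2")
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.slope == pytest.approx(-1.0 / math.log10(2.0), rel=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_of_generating_efficiency(self):
        records = simulate_dilution_series("EF1A", efficiency=1.02, n_steps=6)
        assert fit_standard_curve(records, "EF1A").efficiency == pytest.approx(1.02, abs=1e-6)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.8, max_value=1.1))
    def test_recovery_property_over_efficiency_range(self, eff):
        records = simulate_dilution_series("g", efficiency=eff, n_steps=6)
        assert fit_standard_curve(records, "g").efficiency == pytest.approx(eff, abs=1e-6)

    def test_permutation_and_intercept_shift_invariance(self, rng):
        records = simulate_dilution_series("g", efficiency=0.95, n_steps=6, ct_noise_sd=0.1, seed=3)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        shifted = [
            CtRecord(r.sample_id, r.gene, r.replicate, r.ct + 5.0, r.role, r.dilution_step)
            for r in records
        ]
        base = fit_standard_curve(records, "g")
        assert fit_standard_curve(shuffled, "g").efficiency == pytest.approx(base.efficiency)
        assert fit_standard_curve(shifted, "g").efficiency == pytest.approx(base.efficiency)

    def test_rising_ct_with_input_is_invalid(self):
        records = [
            CtRecord("std", "g", 1, 15.0 - k, "standard", k) for k in range(4)
        ]  # Ct falls with dilution: positive slope on log-input
        with pytest.raises(InvalidCurveError):
            fit_standard_curve(records, "g")

    def test_too_few_steps(self):
        records = simulate_dilution_series("g", efficiency=1.0, n_steps=2)
        with pytest.raises(InsufficientDataError):
            fit_standard_curve(records, "g")
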