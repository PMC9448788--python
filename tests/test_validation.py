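"""Rule engine: requirement ladder, structural rules, severity mapping."""
import numpy as np
import pytest

from aslbids import (AslContext, ImageSeries, SidecarMetadata, applicable_fields,
                     mutate_dataset, validate)
from aslbids.validation import (check_conditional_requirements,
                                check_context_volume_match, check_m0_consistency,
                                check_pepolar_fieldmap,
                                check_scaling_fields_absent)


def rule_ids(issues, severity=None):
    return {i.rule_id for i in issues if severity is None or i.severity == severity}


@pytest.mark.parametrize("name", ["asl001", "asl002", "asl003", "asl004", "asl005"])
def test_example_fixtures_are_valid(fixtures, name):
    report = validate(fixtures[name][0])
    assert report.valid and report.n_errors == 0


def test_missing_required_field_is_single_error(fixtures):
    ds = fixtures["asl005"][0].copy()
    del ds.asl_sidecar.entries["M0Type"]
    report = validate(ds)
    assert not report.valid
    errors = [i for i in report.issues if i.severity == "ERROR"]
    assert len(errors) == 1 and errors[0].field == "M0Type"
    assert errors[0].rule_id == "ASL101"


def test_missing_recommended_field_is_warning_only(fixtures):
    ds = fixtures["asl002"][0].copy()
    del ds.asl_sidecar.entries["AcquisitionVoxelSize"]
    report = validate(ds)
    assert report.valid
    assert any(i.rule_id == "ASL102" and i.field == "AcquisitionVoxelSize"
               for i in report.issues)


def test_strict_mode_promotes_recommended(fixtures):
    ds = fixtures["asl002"][0].copy()
    del ds.asl_sidecar.entries["AcquisitionVoxelSize"]
    assert validate(ds).valid
    assert not validate(ds, strict=True).valid


def test_validation_is_deterministic(fixtures):
    ds = fixtures["asl004"][0]
    assert validate(ds).to_dict() == validate(ds).to_dict()


def test_severity_monotonicity(fixtures, registry):
    """No rule emits ERROR for a RECOMMENDED/OPTIONAL omission."""
    ds = fixtures["asl002"][0].copy()
    for spec in applicable_fields("asl", ds.asl_sidecar.entries, registry):
        if spec.requirement_for("asl") != "REQUIRED":
            ds.asl_sidecar.entries.pop(spec.name, None)
    assert validate(ds).valid


# --- context/volume coherence -------------------------------------------------

def make_series(n):
    return ImageSeries(np.ones((4, 4, 3, n)))


def test_consistent_context_passes():
    sc = SidecarMetadata("asl", {"TotalAcquiredPairs": 5})
    issues = check_context_volume_match(
        make_series(10), AslContext(("control", "label") * 5), sc)
    assert issues == []


def test_context_count_mismatch_errors():
    issues = check_context_volume_match(
        make_series(10), AslContext(("control", "label") * 4), None)
    assert "ASL201" in rule_ids(issues, "ERROR")


def test_unbalanced_pairs_error():
    issues = check_context_volume_match(
        make_series(3), AslContext(("control", "control", "label")), None)
    assert "ASL202" in rule_ids(issues, "ERROR")


def test_pair_count_vs_declared_is_warning():
    sc = SidecarMetadata("asl", {"TotalAcquiredPairs": 40})
    issues = check_context_volume_match(
        make_series(10), AslContext(("control", "label") * 5), sc)
    assert rule_ids(issues, "ERROR") == set()
    assert "ASL203" in rule_ids(issues, "WARNING")


def test_deltam_mixed_with_pairs_errors():
    issues = check_context_volume_match(
        make_series(3), AslContext(("control", "label", "deltam")), None)
    assert "ASL204" in rule_ids(issues, "ERROR")


# --- M0 consistency -----------------------------------------------------------

def test_m0_separate_ok(fixtures):
    assert check_m0_consistency(fixtures["asl002"][0]) == []


def test_m0_included_without_rows_errors(fixtures):
    ds = fixtures["asl002"][0].copy()  # Separate layout, claim Included
    ds.asl_sidecar.entries["M0Type"] = "Included"
    assert "ASL301" in rule_ids(check_m0_consistency(ds), "ERROR")


def test_m0_estimate_paths(fixtures):
    ds = fixtures["asl005"][0].copy()
    ds.m0_series = ds.m0_sidecar = None
    ds.context = AslContext(tuple(t for t in ds.context if t != "m0scan"))
    ds.asl_sidecar.entries["M0Type"] = "Estimate"
    ds.asl_sidecar.entries["M0Estimate"] = 1200.0
    assert rule_ids(check_m0_consistency(ds), "ERROR") == set()
    ds.readme_present = False
    assert "ASL302" in rule_ids(check_m0_consistency(ds), "WARNING")
    ds.asl_sidecar.entries["M0Estimate"] = -1.0
    assert "ASL301" in rule_ids(check_m0_consistency(ds), "ERROR")


def test_m0_absent_with_leftovers_errors(fixtures):
    ds = fixtures["asl005"][0].copy()  # in-series m0scan rows present
    ds.asl_sidecar.entries["M0Type"] = "Absent"
    assert "ASL301" in rule_ids(check_m0_consistency(ds), "ERROR")


# --- conditional requirements -------------------------------------------------

def test_2d_without_slice_timing_errors():
    sc = SidecarMetadata("asl", {"MRAcquisitionType": "2D",
                                 "MagneticFieldStrength": 3})
    issues = check_conditional_requirements(sc)
    assert any(i.field == "SliceTiming" and i.severity == "ERROR" for i in issues)


def test_slice_timing_length_mismatch_errors():
    sc = SidecarMetadata("asl", {"MRAcquisitionType": "2D",
                                 "SliceTiming": [0.0, 0.04],
                                 "MagneticFieldStrength": 3})
    issues = check_conditional_requirements(sc, n_slices=5)
    assert "ASL402" in rule_ids(issues, "ERROR")


def test_pasl_cutoff_chain():
    ok = SidecarMetadata("asl", {"ArterialSpinLabelingType": "PASL",
                                 "BolusCutOffFlag": True,
                                 "BolusCutOffDelayTime": 0.7,
                                 "MagneticFieldStrength": 3})
    assert rule_ids(check_conditional_requirements(ok), "ERROR") == set()
    missing_flag = SidecarMetadata("asl", {"ArterialSpinLabelingType": "PASL",
                                           "MagneticFieldStrength": 3})
    assert any(i.field == "BolusCutOffFlag"
               for i in check_conditional_requirements(missing_flag))
    no_delay = SidecarMetadata("asl", {"ArterialSpinLabelingType": "PASL",
                                       "BolusCutOffFlag": True,
                                       "MagneticFieldStrength": 3})
    assert any(i.field == "BolusCutOffDelayTime"
               for i in check_conditional_requirements(no_delay))


def test_pld_array_length_mismatch_errors():
    sc = SidecarMetadata("asl", {"PostLabelingDelay": [1.0, 1.5, 2.0],
                                 "MagneticFieldStrength": 3})
    issues = check_conditional_requirements(sc, n_volumes=8)
    assert "ASL403" in rule_ids(issues, "ERROR")


def test_milliseconds_suspicion_warning():
    sc = SidecarMetadata("asl", {"PostLabelingDelay": 1800,
                                 "MagneticFieldStrength": 3})
    issues = check_conditional_requirements(sc)
    warn = [i for i in issues if i.rule_id == "ASL404"]
    assert warn and warn[0].field == "PostLabelingDelay"
    assert "millisecond" in warn[0].message


def test_missing_field_strength_errors():
    issues = check_conditional_requirements(SidecarMetadata("asl", {}))
    assert any(i.field == "MagneticFieldStrength" and i.severity == "ERROR"
               for i in issues)


# --- scaling deny-list --------------------------------------------------------

def test_scaling_key_in_asl_sidecar_errors(fixtures):
    ds = fixtures["asl005"][0].copy()
    ds.asl_sidecar.entries["RescaleSlope"] = 1.6
    issues = check_scaling_fields_absent(ds)
    assert rule_ids(issues, "ERROR") == {"ASL501"}


def test_clean_sidecars_pass(fixtures):
    assert check_scaling_fields_absent(fixtures["asl004"][0]) == []


def test_scaling_key_attributed_to_m0_sidecar(fixtures):
    ds = fixtures["asl002"][0].copy()
    ds.m0_sidecar.entries["ScaleSlope"] = 2.0
    issues = check_scaling_fields_absent(ds)
    assert len(issues) == 1 and issues[0].path.endswith("_m0scan.json")


# --- PEPolar ------------------------------------------------------------------

def test_pepolar_opposite_polarity_passes(fixtures):
    assert check_pepolar_fieldmap(fixtures["asl004"][0]) == []


def test_pepolar_axis_mismatch_errors(fixtures):
    ds = fixtures["asl004"][0].copy()
    ds.fieldmap_entries[0].sidecar.entries["PhaseEncodingDirection"] = "i-"
    assert "ASL603" in rule_ids(check_pepolar_fieldmap(ds), "ERROR")


def test_pepolar_same_polarity_errors(fixtures):
    ds = mutate_dataset(fixtures["asl004"][0], "break-pepolar")
    assert "ASL603" in rule_ids(check_pepolar_fieldmap(ds), "ERROR")


def test_pepolar_dangling_intendedfor_errors(fixtures):
    ds = fixtures["asl004"][0].copy()
    ds.fieldmap_entries[0].sidecar.entries["IntendedFor"] = \
        "perf/sub-01_nonexistent.nii.gz"
    assert "ASL601" in rule_ids(check_pepolar_fieldmap(ds), "ERROR")


def test_pepolar_missing_direction_on_either_side_errors(fixtures):
    ds = fixtures["asl004"][0].copy()
    del ds.asl_sidecar.entries["PhaseEncodingDirection"]
    assert "ASL602" in rule_ids(check_pepolar_fieldmap(ds), "ERROR")
    ds2 = fixtures["asl004"][0].copy()
    del ds2.fieldmap_entries[0].sidecar.entries["PhaseEncodingDirection"]
    assert "ASL602" in rule_ids(check_pepolar_fieldmap(ds2), "ERROR")


# --- report surface -----------------------------------------------------------

def test_report_valid_tracks_error_count(fixtures):
    ds = fixtures["asl005"][0].copy()
    report = validate(ds)
    assert report.valid == (report.n_errors == 0)
    ds.asl_sidecar.entries["RescaleSlope"] = 1.0
    report = validate(ds)
    assert report.n_errors > 0 and not report.valid


def test_report_json_shape(fixtures):
    import json

    d = json.loads(validate(fixtures["asl003"][0]).to_json())
    assert set(d) == {"valid", "n_errors", "n_warnings", "issues"}
    ds = fixtures["asl003"][0].copy()
    del ds.asl_sidecar.entries["M0Type"]
    d = json.loads(validate(ds).to_json())
    issue = d["issues"][0]
    assert set(issue) == {"rule_id", "severity", "path", "field", "message"}
    assert issue["message"]
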