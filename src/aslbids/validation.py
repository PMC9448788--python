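"""Rule engine validating ASL datasets against the metadata schema.

Severity follows the requirement ladder: a missing REQUIRED field (under its
applicability condition) is an ERROR, a missing RECOMMENDED field a WARNING,
a missing OPTIONAL field is silent.  Structural rules cover context/volume
coherence, M0 declaration consistency, the ban on scale-factor fields, and
PEPolar fieldmap linkage.  Problems are reported as issues, never raised.

Rule catalogue (stable ids, published in the docs)::

    ASL101  missing REQUIRED field                       ERROR
    ASL102  missing RECOMMENDED field                    WARNING
    ASL103  value kind or enumeration violation          ERROR
    ASL201  context row count != volume count            ERROR
    ASL202  unequal control and label row counts         ERROR
    ASL203  observed pair count != TotalAcquiredPairs    WARNING
    ASL204  difference volumes mixed with raw pairs      ERROR
    ASL301  M0Type inconsistent with dataset contents    ERROR
    ASL302  M0 estimate without a dataset README         WARNING
    ASL402  SliceTiming length != slice count            ERROR
    ASL403  PostLabelingDelay array length != volumes    ERROR
    ASL404  value outside plausible range                WARNING
    ASL501  intensity scale-factor field present         ERROR
    ASL601  IntendedFor missing or dangling              ERROR
    ASL602  PhaseEncodingDirection missing on a side     ERROR
    ASL603  PhaseEncodingDirections not polar opposites  ERROR
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import dataset_file_map, existing_subject_files
from .model import AslContext, AslDataset, ImageSeries, SidecarMetadata
from .registry import applicable_fields, build_field_registry, registry_index

ERROR = "ERROR"
WARNING = "WARNING"

RULES = {
    "ASL101": "missing REQUIRED field",
    "ASL102": "missing RECOMMENDED field",
    "ASL103": "value kind or enumeration violation",
    "ASL201": "context row count differs from image volume count",
    "ASL202": "unequal control and label row counts",
    "ASL203": "observed pair count differs from TotalAcquiredPairs",
    "ASL204": "difference volumes mixed with raw control/label pairs",
    "ASL301": "M0Type inconsistent with dataset contents",
    "ASL302": "M0 estimate origin not documented in a dataset README",
    "ASL402": "SliceTiming length differs from slice count",
    "ASL403": "PostLabelingDelay array length differs from volume count",
    "ASL404": "value outside plausible range (milliseconds suspected for times)",
    "ASL501": "intensity scale-factor field present in a sidecar",
    "ASL601": "IntendedFor missing or resolving to no existing file",
    "ASL602": "PhaseEncodingDirection missing on one side of a PEPolar pair",
    "ASL603": "PhaseEncodingDirections are not exact polarity opposites",
}

#: Sidecar keys that would smuggle intensity scale factors into the dataset.
#: All scaling must be applied to the voxel data at conversion time.
SCALING_DENYLIST = (
    "ScaleSlope", "RescaleSlope", "RescaleIntercept", "ScaleIntercept",
    "M0ScaleFactor", "AslScaleFactor", "PhilipsRescaleSlope",
    "PhilipsScaleSlope", "PhilipsRWVSlope", "ScalingFactor",
)

#: Times above this many seconds trigger a milliseconds-suspicion WARNING.
MS_SUSPICION_THRESHOLD_S = 10.0


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: str
    path: str
    field: Optional[str]
    message: str

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "severity": self.severity,
                "path": self.path, "field": self.field, "message": self.message}


@dataclass
class ValidationReport:
    issues: list

    @property
    def valid(self) -> bool:
        return self.n_errors == 0

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == ERROR)

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == WARNING)

    def errors_for_field(self, field: str) -> list:
        return [i for i in self.issues if i.severity == ERROR and i.field == field]

    def rule_ids(self, severity: Optional[str] = None) -> set:
        return {i.rule_id for i in self.issues
                if severity is None or i.severity == severity}

    def to_dict(self) -> dict:
        return {"valid": self.valid, "n_errors": self.n_errors,
                "n_warnings": self.n_warnings,
                "issues": [i.to_dict() for i in self.issues]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        if not self.issues:
            return "No issues found. Dataset is valid.\n"
        lines = [f"{i.severity:7s} {i.rule_id} [{i.path}"
                 + (f" :: {i.field}" if i.field else "") + f"] {i.message}"
                 for i in self.issues]
        lines.append(f"{self.n_errors} error(s), {self.n_warnings} warning(s); "
                     + ("valid" if self.valid else "invalid"))
        return "\n".join(lines) + "\n"


def _missing_issue(name: str, role: str, level: str, path: str) -> ValidationIssue:
    rule = "ASL101" if level == "REQUIRED" else "ASL102"
    severity = ERROR if level == "REQUIRED" else WARNING
    return ValidationIssue(rule, severity, path, name,
                           f"missing {level} field '{name}' for role '{role}'")


# --- registry-driven presence and conformance checks --------------------------

def check_registry_fields(sidecar: SidecarMetadata, role: str, asl_values,
                          path: str, registry=None) -> list:
    """Presence of applicable REQUIRED/RECOMMENDED fields + value conformance."""
    issues = []
    for spec in applicable_fields(role, asl_values, registry):
        level = spec.requirement_for(role)
        if spec.name not in sidecar:
            if level in ("REQUIRED", "RECOMMENDED"):
                issues.append(_missing_issue(spec.name, role, level, path))
            continue
        value = sidecar.get(spec.name)
        if not spec.conforms(value):
            issues.append(ValidationIssue(
                "ASL103", ERROR, path, spec.name,
                f"value {value!r} does not conform to kind '{spec.value_kind}'"))
            continue
        if spec.allowed_values is not None and value not in spec.allowed_values:
            issues.append(ValidationIssue(
                "ASL103", ERROR, path, spec.name,
                f"value {value!r} not in allowed set {sorted(spec.allowed_values)}"))
            continue
        if spec.plausible_range is not None:
            lo, hi = spec.plausible_range
            scalars = value if isinstance(value, (list, tuple)) else [value]
            if any(not (lo <= v <= hi) for v in scalars):
                issues.append(ValidationIssue(
                    "ASL404", WARNING, path, spec.name,
                    f"value {value!r} outside plausible range [{lo}, {hi}]"
                    + (" (milliseconds instead of seconds?)"
                       if spec.units == "s" and any(
                           v > MS_SUSPICION_THRESHOLD_S for v in scalars) else "")))
    return issues


# --- structural rules ---------------------------------------------------------

def check_context_volume_match(asl_series: ImageSeries, context: AslContext,
                               asl_sidecar: Optional[SidecarMetadata] = None,
                               path: str = "perf/_aslcontext.tsv") -> list:
    issues = []
    if len(context) != asl_series.n_volumes:
        issues.append(ValidationIssue(
            "ASL201", ERROR, path, None,
            f"aslcontext lists {len(context)} volumes but the image has "
            f"{asl_series.n_volumes}"))
    n_control, n_label = context.count("control"), context.count("label")
    n_diff = context.count("deltam") + context.count("cbf")
    if n_diff and (n_control or n_label):
        issues.append(ValidationIssue(
            "ASL204", ERROR, path, None,
            "deltam/cbf volumes must not be mixed with control/label volumes "
            "in one series"))
    if n_control != n_label:
        issues.append(ValidationIssue(
            "ASL202", ERROR, path, None,
            f"{n_control} control row(s) vs {n_label} label row(s); "
            "pairs must balance"))
    pairs_observed = n_control if n_control == n_label and n_control else n_diff
    declared = asl_sidecar.get("TotalAcquiredPairs") if asl_sidecar else None
    if (pairs_observed and isinstance(declared, (int, float))
            and not isinstance(declared, bool) and pairs_observed != declared):
        issues.append(ValidationIssue(
            "ASL203", WARNING, path, "TotalAcquiredPairs",
            f"{pairs_observed} pair(s) observed but TotalAcquiredPairs is "
            f"{declared} (averaged export?)"))
    return issues


def check_m0_consistency(dataset: AslDataset) -> list:
    """M0Type declaration vs what the dataset actually contains."""
    sc = dataset.asl_sidecar
    m0type = sc.get("M0Type")
    if m0type not in ("Separate", "Included", "Estimate", "Absent"):
        return []  # presence/enum checks already fire
    path = f"sub-{dataset.subject}/" + dataset_file_map(dataset)["asl_sidecar"]
    issues = []
    has_file = dataset.m0_series is not None
    n_rows = dataset.context.count("m0scan")
    estimate = sc.get("M0Estimate")

    def err(msg):
        issues.append(ValidationIssue("ASL301", ERROR, path, "M0Type", msg))

    if m0type == "Separate":
        if not has_file:
            err("M0Type 'Separate' but no _m0scan image+sidecar in perf/")
        if n_rows:
            err(f"M0Type 'Separate' but aslcontext has {n_rows} m0scan row(s)")
    elif m0type == "Included":
        if n_rows == 0:
            err("M0Type 'Included' but aslcontext has no m0scan row")
        if has_file:
            err("M0Type 'Included' but a separate _m0scan file exists in perf/")
    elif m0type == "Estimate":
        ok = (isinstance(estimate, (int, float)) and not isinstance(estimate, bool)
              and estimate > 0)
        if not ok:
            issues.append(ValidationIssue(
                "ASL301", ERROR, path, "M0Estimate",
                f"M0Type 'Estimate' requires a positive M0Estimate, got {estimate!r}"))
        if not dataset.readme_present:
            issues.append(ValidationIssue(
                "ASL302", WARNING, path, "M0Estimate",
                "origin of the scalar M0 estimate should be documented in the "
                "dataset README"))
    elif m0type == "Absent":
        if has_file:
            err("M0Type 'Absent' but a _m0scan file exists in perf/")
        if n_rows:
            err(f"M0Type 'Absent' but aslcontext has {n_rows} m0scan row(s)")
        if estimate is not None:
            err("M0Type 'Absent' but M0Estimate is present")
    return issues


def check_conditional_requirements(asl_sidecar: SidecarMetadata,
                                   n_slices: Optional[int] = None,
                                   n_volumes: Optional[int] = None,
                                   path: str = "perf/_asl.json") -> list:
    """Conditional-requirement and cross-field rules on the ASL sidecar."""
    sc = asl_sidecar
    issues = []
    labeling = sc.get("ArterialSpinLabelingType")

    if sc.get("MRAcquisitionType") == "2D" and "SliceTiming" not in sc:
        issues.append(_missing_issue("SliceTiming", "asl", "REQUIRED", path))
    st = sc.get("SliceTiming")
    if (isinstance(st, (list, tuple)) and n_slices is not None
            and len(st) != n_slices):
        issues.append(ValidationIssue(
            "ASL402", ERROR, path, "SliceTiming",
            f"SliceTiming has {len(st)} entries but the image has "
            f"{n_slices} slices"))
    if labeling in ("CASL", "PCASL") and "LabelingDuration" not in sc:
        issues.append(_missing_issue("LabelingDuration", "asl", "REQUIRED", path))
    if labeling == "PASL" and "BolusCutOffFlag" not in sc:
        issues.append(_missing_issue("BolusCutOffFlag", "asl", "REQUIRED", path))
    if sc.get("BolusCutOffFlag") is True and "BolusCutOffDelayTime" not in sc:
        issues.append(_missing_issue("BolusCutOffDelayTime", "asl", "REQUIRED", path))
    pld = sc.get("PostLabelingDelay")
    if (isinstance(pld, (list, tuple)) and n_volumes is not None
            and len(pld) != n_volumes):
        issues.append(ValidationIssue(
            "ASL403", ERROR, path, "PostLabelingDelay",
            f"PostLabelingDelay array has {len(pld)} entries for "
            f"{n_volumes} volumes"))
    if sc.get("LookLocker") is True and "FlipAngle" not in sc:
        issues.append(_missing_issue("FlipAngle", "asl", "REQUIRED", path))
    if "MagneticFieldStrength" not in sc:
        issues.append(_missing_issue("MagneticFieldStrength", "asl", "REQUIRED", path))
    # plausibility warnings are shared with the registry conformance scan
    issues.extend(i for i in check_registry_fields(sc, "asl", sc.entries, path)
                  if i.rule_id == "ASL404")
    return issues


def check_scaling_fields_absent(dataset: AslDataset) -> list:
    """No sidecar may carry intensity scale factors; they belong in the voxels."""
    issues = []
    files = dataset_file_map(dataset)
    prefix = f"sub-{dataset.subject}/"
    targets = [(prefix + files["asl_sidecar"], dataset.asl_sidecar)]
    if dataset.m0_sidecar is not None:
        targets.append((prefix + files["m0_sidecar"], dataset.m0_sidecar))
    for i, entry in enumerate(dataset.fieldmap_entries):
        targets.append((prefix + files[f"fmap{i}_sidecar"], entry.sidecar))
    for path, sidecar in targets:
        for key in SCALING_DENYLIST:
            if key in sidecar:
                issues.append(ValidationIssue(
                    "ASL501", ERROR, path, key,
                    f"scale-factor field '{key}' is not allowed; apply all "
                    "scaling to the image data at conversion"))
    return issues


def _polar_opposites(a: str, b: str) -> bool:
    valid = {"i", "i-", "j", "j-", "k", "k-"}
    if a not in valid or b not in valid:
        return False
    return a[0] == b[0] and a.endswith("-") != b.endswith("-")


def check_pepolar_fieldmap(dataset: AslDataset) -> list:
    """Linkage and polarity rules for reversed phase-encoding m0scans."""
    issues = []
    files = dataset_file_map(dataset)
    prefix = f"sub-{dataset.subject}/"
    known = existing_subject_files(dataset)
    for i, entry in enumerate(dataset.fieldmap_entries):
        path = prefix + files[f"fmap{i}_sidecar"]
        target = entry.sidecar.get("IntendedFor")
        target_sidecar = None
        if target is None:
            issues.append(ValidationIssue(
                "ASL601", ERROR, path, "IntendedFor",
                "PEPolar m0scan must link its counterpart via IntendedFor"))
        elif target not in known:
            issues.append(ValidationIssue(
                "ASL601", ERROR, path, "IntendedFor",
                f"IntendedFor target {target!r} does not exist"))
        else:
            if target == files["asl_image"]:
                target_sidecar = (dataset.asl_sidecar,
                                  prefix + files["asl_sidecar"])
            elif target == files.get("m0_image"):
                target_sidecar = (dataset.m0_sidecar,
                                  prefix + files["m0_sidecar"])
        pe_fmap = entry.sidecar.get("PhaseEncodingDirection")
        if pe_fmap is None:
            issues.append(ValidationIssue(
                "ASL602", ERROR, path, "PhaseEncodingDirection",
                "PEPolar fieldmap lacks PhaseEncodingDirection"))
        if target_sidecar is not None:
            sc, target_path = target_sidecar
            pe_main = sc.get("PhaseEncodingDirection")
            if pe_main is None:
                issues.append(ValidationIssue(
                    "ASL602", ERROR, target_path, "PhaseEncodingDirection",
                    "PEPolar counterpart lacks PhaseEncodingDirection"))
            elif pe_fmap is not None and not _polar_opposites(pe_fmap, pe_main):
                issues.append(ValidationIssue(
                    "ASL603", ERROR, path, "PhaseEncodingDirection",
                    f"{pe_fmap!r} vs {pe_main!r}: PEPolar pair must use the "
                    "same axis with opposite polarity"))
    return issues


# --- driver -------------------------------------------------------------------

def validate(dataset: AslDataset, registry=None, strict: bool = False) -> ValidationReport:
    """Run every rule; deterministic issue order; problems are issues, not raises.

    ``strict`` promotes missing-RECOMMENDED warnings to errors.
    """
    if registry is None:
        registry = build_field_registry()
    files = dataset_file_map(dataset)
    prefix = f"sub-{dataset.subject}/"
    asl_values = dataset.asl_sidecar.entries
    issues = []
    issues += check_registry_fields(dataset.asl_sidecar, "asl", asl_values,
                                    prefix + files["asl_sidecar"], registry)
    if dataset.m0_sidecar is not None:
        issues += check_registry_fields(dataset.m0_sidecar, "m0scan", asl_values,
                                        prefix + files["m0_sidecar"], registry)
    for i, entry in enumerate(dataset.fieldmap_entries):
        issues += check_registry_fields(entry.sidecar, "fieldmap", asl_values,
                                        prefix + files[f"fmap{i}_sidecar"],
                                        registry)
    issues += check_context_volume_match(dataset.asl_series, dataset.context,
                                         dataset.asl_sidecar,
                                         prefix + files["aslcontext"])
    issues += check_m0_consistency(dataset)
    issues += check_conditional_requirements(
        dataset.asl_sidecar, n_slices=dataset.asl_series.n_slices,
        n_volumes=dataset.asl_series.n_volumes,
        path=prefix + files["asl_sidecar"])
    issues += check_scaling_fields_absent(dataset)
    issues += check_pepolar_fieldmap(dataset)

    if strict:
        issues = [ValidationIssue(i.rule_id, ERROR, i.path, i.field, i.message)
                  if i.rule_id == "ASL102" else i for i in issues]

    unique = list(dict.fromkeys(issues))  # conditional checks may duplicate ASL101
    unique.sort(key=lambda i: (i.rule_id, i.path, i.field or "", i.message))
    return ValidationReport(unique)
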