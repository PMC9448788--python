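"""Machine-readable metadata schema for the ``perf`` datatype.

Each sidecar field is described by a :class:`FieldSpec`: its value kind,
units, per-role requirement level, and an applicability predicate evaluated
against the ASL sidecar values.  Requirement levels are ranked by necessity
for cerebral blood flow quantification: REQUIRED fields are those without
which a single-PLD CBF value cannot be computed, RECOMMENDED fields improve
or contextualize quantification, and OPTIONAL fields add description only.

The registry is fixed to the BIDS 1.6.0 ASL field set; fields beyond the
quantification core are marked OPTIONAL.  All time-valued fields are stored
in seconds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Sequence

from .model import RequirementLevel

Number = (int, float)


def _is_number(v: Any) -> bool:
    return isinstance(v, Number) and not isinstance(v, bool)


def _is_number_array(v: Any) -> bool:
    return isinstance(v, (list, tuple)) and len(v) > 0 and all(_is_number(x) for x in v)


@dataclass(frozen=True)
class FieldSpec:
    """Schema entry for one sidecar field.

    ``levels`` maps each file role the field applies to onto its requirement
    level; ``condition`` (evaluated on the ASL sidecar values) gates
    applicability, so a field whose condition is false is simply not part of
    the schema for that dataset.
    """

    name: str
    value_kind: str  # number | string | boolean | number_array | string_array
    levels: Mapping[str, str]
    units: str = ""
    condition: Optional[Callable[[Mapping[str, Any]], bool]] = None
    condition_desc: str = ""
    allowed_values: Optional[tuple] = None
    plausible_range: Optional[tuple] = None
    scalar_or_array: bool = False  # scalar accepted where an array is declared and vice versa

    def __post_init__(self):
        if self.allowed_values is not None and len(self.allowed_values) == 0:
            raise ValueError("allowed_values, when present, must be non-empty")
        for level in self.levels.values():
            RequirementLevel.rank(level)  # raises on unknown level

    def requirement_for(self, role: str) -> Optional[str]:
        return self.levels.get(role)

    def applies(self, role: str, asl_values: Mapping[str, Any]) -> bool:
        if role not in self.levels:
            return False
        if self.condition is None:
            return True
        return bool(self.condition(asl_values))

    def conforms(self, value: Any) -> bool:
        """True when ``value`` matches the declared value kind."""
        kind = self.value_kind
        if self.scalar_or_array:
            return _is_number(value) or _is_number_array(value)
        if kind == "number":
            return _is_number(value)
        if kind == "boolean":
            return isinstance(value, bool)
        if kind == "string":
            return isinstance(value, str)
        if kind == "number_array":
            return _is_number_array(value)
        if kind == "string_array":
            return isinstance(value, (list, tuple)) and all(isinstance(x, str) for x in value)
        raise ValueError(f"unknown value kind {kind!r}")


# --- applicability predicates -------------------------------------------------

def _is_2d(v: Mapping) -> bool:
    return v.get("MRAcquisitionType") == "2D"


def _is_casl(v: Mapping) -> bool:
    return v.get("ArterialSpinLabelingType") in ("CASL", "PCASL")


def _is_pasl(v: Mapping) -> bool:
    return v.get("ArterialSpinLabelingType") == "PASL"


def _pasl_cutoff(v: Mapping) -> bool:
    return _is_pasl(v) and v.get("BolusCutOffFlag") is True


def _m0_estimate(v: Mapping) -> bool:
    return v.get("M0Type") == "Estimate"


REQ = RequirementLevel.REQUIRED
REC = RequirementLevel.RECOMMENDED
OPT = RequirementLevel.OPTIONAL

PE_DIRECTIONS = ("i", "i-", "j", "j-", "k", "k-")


def build_field_registry() -> list:
    """Return the complete field registry, in stable documentation order."""
    specs = [
        # --- labeling scheme and timing (ASL sidecar) -------------------------
        FieldSpec("ArterialSpinLabelingType", "string", {"asl": REQ},
                  allowed_values=("CASL", "PCASL", "PASL")),
        FieldSpec("PostLabelingDelay", "number", {"asl": REQ}, units="s",
                  scalar_or_array=True, plausible_range=(0.0, 10.0)),
        FieldSpec("LabelingDuration", "number", {"asl": REQ}, units="s",
                  condition=_is_casl, condition_desc="ArterialSpinLabelingType in {CASL, PCASL}",
                  scalar_or_array=True, plausible_range=(0.0, 10.0)),
        FieldSpec("BolusCutOffFlag", "boolean", {"asl": REQ},
                  condition=_is_pasl, condition_desc="ArterialSpinLabelingType == PASL"),
        FieldSpec("BolusCutOffDelayTime", "number", {"asl": REQ}, units="s",
                  condition=_pasl_cutoff,
                  condition_desc="PASL with BolusCutOffFlag true",
                  plausible_range=(0.0, 10.0)),
        FieldSpec("BolusCutOffTechnique", "string", {"asl": REQ},
                  condition=_pasl_cutoff,
                  condition_desc="PASL with BolusCutOffFlag true"),
        # --- M0 calibration ---------------------------------------------------
        FieldSpec("M0Type", "string", {"asl": REQ},
                  allowed_values=("Separate", "Included", "Estimate", "Absent")),
        FieldSpec("M0Estimate", "number", {"asl": REQ},
                  condition=_m0_estimate, condition_desc="M0Type == Estimate"),
        # --- series structure -------------------------------------------------
        FieldSpec("TotalAcquiredPairs", "number", {"asl": REQ}),
        FieldSpec("BackgroundSuppression", "boolean", {"asl": REQ}),
        FieldSpec("MRAcquisitionType", "string", {"asl": REQ},
                  allowed_values=("2D", "3D")),
        FieldSpec("SliceTiming", "number_array", {"asl": REQ}, units="s",
                  condition=_is_2d, condition_desc="MRAcquisitionType == 2D",
                  plausible_range=(0.0, 10.0)),
        # --- scanner / sequence parameters ------------------------------------
        FieldSpec("MagneticFieldStrength", "number", {"asl": REQ}, units="T",
                  plausible_range=(0.05, 20.0)),
        FieldSpec("EchoTime", "number", {"asl": REQ, "m0scan": REQ}, units="s",
                  plausible_range=(0.0, 0.5)),
        FieldSpec("FlipAngle", "number", {"asl": REQ, "m0scan": REQ}, units="degrees",
                  scalar_or_array=True, plausible_range=(1e-3, 180.0)),
        FieldSpec("RepetitionTimePreparation", "number",
                  {"asl": REQ, "m0scan": REQ}, units="s",
                  plausible_range=(0.0, 30.0)),
        # --- recommended context ----------------------------------------------
        FieldSpec("AcquisitionVoxelSize", "number_array", {"asl": REC, "m0scan": OPT},
                  units="mm"),
        FieldSpec("BackgroundSuppressionNumberPulses", "number", {"asl": REC}),
        FieldSpec("BackgroundSuppressionPulseTime", "number_array", {"asl": REC},
                  units="s"),
        # --- optional description ---------------------------------------------
        FieldSpec("LookLocker", "boolean", {"asl": OPT}),
        FieldSpec("LabelingEfficiency", "number", {"asl": OPT},
                  plausible_range=(0.0, 1.0)),
        FieldSpec("LabelingLocationDescription", "string", {"asl": OPT}),
        FieldSpec("LabelingSlabThickness", "number", {"asl": OPT}, units="mm"),
        FieldSpec("LabelingDistance", "number", {"asl": OPT}, units="mm"),
        FieldSpec("LabelingPulseAverageGradient", "number", {"asl": OPT}, units="mT/m"),
        FieldSpec("LabelingPulseMaximumGradient", "number", {"asl": OPT}, units="mT/m"),
        FieldSpec("LabelingPulseAverageB1", "number", {"asl": OPT}, units="uT"),
        FieldSpec("LabelingPulseDuration", "number", {"asl": OPT}, units="s"),
        FieldSpec("LabelingPulseFlipAngle", "number", {"asl": OPT}, units="degrees"),
        FieldSpec("LabelingPulseInterval", "number", {"asl": OPT}, units="s"),
        FieldSpec("PCASLType", "string", {"asl": OPT},
                  allowed_values=("balanced", "unbalanced")),
        FieldSpec("CASLType", "string", {"asl": OPT},
                  allowed_values=("single-coil", "double-coil")),
        FieldSpec("PASLType", "string", {"asl": OPT}),
        FieldSpec("VascularCrushing", "boolean", {"asl": OPT}),
        FieldSpec("VascularCrushingVENC", "number", {"asl": OPT}, units="cm/s",
                  scalar_or_array=True),
        FieldSpec("AcquisitionDuration", "number", {"asl": OPT}, units="s"),
        # --- linkage ----------------------------------------------------------
        FieldSpec("IntendedFor", "string", {"m0scan": REQ, "fieldmap": REQ}),
        FieldSpec("PhaseEncodingDirection", "string",
                  {"asl": OPT, "m0scan": OPT, "fieldmap": REQ},
                  allowed_values=PE_DIRECTIONS),
    ]
    names = [s.name for s in specs]
    assert len(names) == len(set(names)), "field names must be unique"
    return specs


def registry_index(registry: Optional[Sequence[FieldSpec]] = None) -> dict:
    """Name → FieldSpec mapping for a registry (builds the default if None)."""
    if registry is None:
        registry = build_field_registry()
    return {s.name: s for s in registry}


def applicable_fields(role: str, asl_sidecar_values: Mapping[str, Any],
                      registry: Optional[Sequence[FieldSpec]] = None) -> list:
    """Registry entries applicable to ``role`` given the ASL sidecar values.

    Deterministic: preserves registry order; predicates are pure.
    """
    if role not in ("asl", "m0scan", "fieldmap"):
        raise ValueError(f"unknown role {role!r}")
    if registry is None:
        registry = build_field_registry()
    return [s for s in registry if s.applies(role, asl_sidecar_values)]


def registry_to_json(registry: Optional[Sequence[FieldSpec]] = None) -> str:
    """Export the registry as a JSON document for documentation generation."""
    if registry is None:
        registry = build_field_registry()
    doc = []
    for s in registry:
        doc.append({
            "name": s.name,
            "kind": s.value_kind + ("|scalar-or-array" if s.scalar_or_array else ""),
            "units": s.units,
            "requirement": dict(s.levels),
            "condition": s.condition_desc,
            "allowed_values": list(s.allowed_values) if s.allowed_values else None,
            "plausible_range": list(s.plausible_range) if s.plausible_range else None,
        })
    return json.dumps(doc, indent=2)
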