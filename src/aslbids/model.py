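"""Core domain types for ASL datasets in BIDS layout.

The model mirrors what lives on disk for one subject's ``perf`` datatype:
a 4D ASL time series plus its JSON sidecar, the ordered per-volume type
labels from ``_aslcontext.tsv``, an optional separate M0 calibration scan,
optional reversed-polarity fieldmap entries under ``fmap/``, and an optional
labeling-plane screenshot.  Image data are held as fully scaled floating
point arrays: any intensity scale factors must already have been applied at
conversion time, so there is nothing left to multiply.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

import numpy as np

#: The five legal per-volume type tokens, compared case-sensitively.
VOLUME_TYPES = ("control", "label", "m0scan", "deltam", "cbf")

#: Sidecar roles distinguished by the field registry.
ROLES = ("asl", "m0scan", "fieldmap")


class RequirementLevel:
    """Metadata requirement ladder, ranked by necessity for quantification."""

    REQUIRED = "REQUIRED"
    RECOMMENDED = "RECOMMENDED"
    OPTIONAL = "OPTIONAL"

    #: total order for severity mapping: REQUIRED > RECOMMENDED > OPTIONAL
    ORDER = {"REQUIRED": 3, "RECOMMENDED": 2, "OPTIONAL": 1}

    @classmethod
    def rank(cls, level: str) -> int:
        return cls.ORDER[level]


@dataclass(frozen=True)
class AslContext:
    """Ordered per-volume type labels — the ``_aslcontext.tsv`` contents.

    Order equals acquisition order, never scanner export order.
    """

    volume_types: tuple

    def __post_init__(self):
        if len(self.volume_types) == 0:
            raise ValueError("aslcontext must list at least one volume")
        for token in self.volume_types:
            if token not in VOLUME_TYPES:
                raise ValueError(f"unknown volume type token: {token!r}")
        object.__setattr__(self, "volume_types", tuple(self.volume_types))

    def __len__(self) -> int:
        return len(self.volume_types)

    def __iter__(self):
        return iter(self.volume_types)

    def indices(self, token: str) -> list:
        return [i for i, t in enumerate(self.volume_types) if t == token]

    def count(self, token: str) -> int:
        return self.volume_types.count(token)

    @property
    def has_pairs(self) -> bool:
        return self.count("control") > 0 or self.count("label") > 0


@dataclass
class ImageSeries:
    """A 3D or 4D image with voxel size; values are fully scaled floats.

    The 4th axis, when present, is the volume axis; the 3rd spatial axis is
    the slice axis that ``SliceTiming`` refers to.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 6.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim not in (3, 4):
            raise ValueError("image series must be 3D or 4D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image series contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3:
            raise ValueError("voxel_size_mm must have 3 components")

    @property
    def n_volumes(self) -> int:
        return int(self.voxels.shape[3]) if self.voxels.ndim == 4 else 1

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[2])

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def volume(self, index: int) -> np.ndarray:
        """Return the 3D volume at acquisition index ``index``."""
        if self.voxels.ndim == 3:
            if index != 0:
                raise IndexError(index)
            return self.voxels
        return self.voxels[..., index]

    def equals(self, other: "ImageSeries") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.array_equal(self.voxels, other.voxels)
            and self.voxel_size_mm == other.voxel_size_mm
        )


@dataclass
class SidecarMetadata:
    """JSON sidecar contents for one file role.

    Known fields are type-checked against the registry at parse time; unknown
    names are retained untouched (pass-through).
    """

    role: str
    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown sidecar role: {self.role!r}")

    def get(self, name: str, default: Any = None) -> Any:
        return self.entries.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def copy(self) -> "SidecarMetadata":
        import copy as _copy

        return SidecarMetadata(self.role, _copy.deepcopy(self.entries))


@dataclass
class FieldmapEntry:
    """One reversed-polarity (PEPolar) calibration image under ``fmap/``."""

    series: ImageSeries
    sidecar: SidecarMetadata
    direction: str = "PA"  # the dir- filename entity


@dataclass
class AslDataset:
    """One subject's ``perf`` contents plus linked ``fmap`` entries."""

    subject: str
    asl_series: ImageSeries
    asl_sidecar: SidecarMetadata
    context: AslContext
    m0_series: Optional[ImageSeries] = None
    m0_sidecar: Optional[SidecarMetadata] = None
    fieldmap_entries: list = field(default_factory=list)
    labeling_screenshot_present: bool = False
    extra_files: list = field(default_factory=list)
    readme_present: bool = True
    name: str = "ASL dataset"

    def __post_init__(self):
        if (self.m0_series is None) != (self.m0_sidecar is None):
            raise ValueError("m0_series and m0_sidecar must both be present or both absent")

    def copy(self) -> "AslDataset":
        import copy as _copy

        return _copy.deepcopy(self)

    def equals(self, other: "AslDataset") -> bool:
        """Model identity: images bit-exact, metadata key-equal, context order-equal."""
        if self.subject != other.subject or self.name != other.name:
            return False
        if not self.asl_series.equals(other.asl_series):
            return False
        if self.asl_sidecar.entries != other.asl_sidecar.entries:
            return False
        if self.context.volume_types != other.context.volume_types:
            return False
        if (self.m0_series is None) != (other.m0_series is None):
            return False
        if self.m0_series is not None:
            if not self.m0_series.equals(other.m0_series):
                return False
            if self.m0_sidecar.entries != other.m0_sidecar.entries:
                return False
        if len(self.fieldmap_entries) != len(other.fieldmap_entries):
            return False
        for a, b in zip(self.fieldmap_entries, other.fieldmap_entries):
            if a.direction != b.direction or not a.series.equals(b.series):
                return False
            if a.sidecar.entries != b.sidecar.entries:
                return False
        return (
            self.labeling_screenshot_present == other.labeling_screenshot_present
            and self.readme_present == other.readme_present
        )
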