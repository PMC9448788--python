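"""On-disk ASL-BIDS layout: directory tree, NIfTI, JSON sidecars, TSV context.

Layout written/read for one subject::

    <root>/
      dataset_description.json
      README
      sub-<label>/
        perf/
          sub-<label>_asl.nii.gz          + _asl.json + _aslcontext.tsv
          sub-<label>_m0scan.nii.gz       + _m0scan.json        (M0Type Separate)
          sub-<label>_asllabeling.jpg                           (optional)
        fmap/
          sub-<label>_dir-<d>_m0scan.nii.gz + .json             (PEPolar)

Images are stored as float64 NIfTI-1 with scl slope/intercept fixed to 1/0:
all intensity scaling has been applied at conversion, so a byte-exact
write → read round trip is part of the format contract.  Gzip members are
written with a zero mtime so identical datasets produce identical bytes.
"""
from __future__ import annotations

import gzip
import io as _io
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .errors import (AmbiguousLayoutError, IoFailureError, MalformedJsonError,
                     MalformedTsvError, MissingFileError, TypeMismatchError)
from .model import (AslContext, AslDataset, FieldmapEntry, ImageSeries,
                    SidecarMetadata, VOLUME_TYPES)
from .registry import registry_index

BIDS_VERSION = "1.6.0"

SUFFIXES = ("asl", "m0scan", "aslcontext", "asllabeling", "cbf")
EXTENSIONS = (".nii", ".nii.gz", ".json", ".tsv", ".jpg")

_NAME_RE = re.compile(
    r"^sub-(?P<subject>[a-zA-Z0-9]+)"
    r"(?:_ses-(?P<session>[a-zA-Z0-9]+))?"
    r"(?:_acq-(?P<acquisition>[a-zA-Z0-9]+))?"
    r"(?:_dir-(?P<direction>[a-zA-Z0-9]+))?"
    r"(?:_run-(?P<run>\d+))?"
    r"_(?P<suffix>[a-z][a-z0-9]*)"
    r"(?P<extension>\.nii\.gz|\.nii|\.json|\.tsv|\.jpg)$"
)


@dataclass(frozen=True)
class BidsName:
    """Parsed BIDS filename entities for the ``perf``/``fmap`` files we handle."""

    subject: str
    suffix: str
    extension: str
    session: Optional[str] = None
    acquisition: Optional[str] = None
    direction: Optional[str] = None
    run: Optional[int] = None

    def render(self) -> str:
        parts = [f"sub-{self.subject}"]
        if self.session is not None:
            parts.append(f"ses-{self.session}")
        if self.acquisition is not None:
            parts.append(f"acq-{self.acquisition}")
        if self.direction is not None:
            parts.append(f"dir-{self.direction}")
        if self.run is not None:
            parts.append(f"run-{self.run}")
        return "_".join(parts) + f"_{self.suffix}{self.extension}"


def parse_bids_name(filename: str) -> BidsName:
    """Parse a filename into entities; parse→render is the identity."""
    m = _NAME_RE.match(filename)
    if m is None:
        raise ValueError(f"not a parseable BIDS filename: {filename!r}")
    g = m.groupdict()
    return BidsName(
        subject=g["subject"],
        session=g["session"],
        acquisition=g["acquisition"],
        direction=g["direction"],
        run=int(g["run"]) if g["run"] is not None else None,
        suffix=g["suffix"],
        extension=g["extension"],
    )


# --- subject-relative path naming --------------------------------------------

def dataset_file_map(ds: AslDataset) -> dict:
    """Map of logical slots to subject-relative paths this dataset occupies.

    These are the paths ``write_dataset`` produces and the paths sidecar
    ``IntendedFor`` values must resolve against.
    """
    sub = ds.subject
    files = {
        "asl_image": f"perf/sub-{sub}_asl.nii.gz",
        "asl_sidecar": f"perf/sub-{sub}_asl.json",
        "aslcontext": f"perf/sub-{sub}_aslcontext.tsv",
    }
    if ds.m0_series is not None:
        files["m0_image"] = f"perf/sub-{sub}_m0scan.nii.gz"
        files["m0_sidecar"] = f"perf/sub-{sub}_m0scan.json"
    if ds.labeling_screenshot_present:
        files["labeling_screenshot"] = f"perf/sub-{sub}_asllabeling.jpg"
    for i, entry in enumerate(ds.fieldmap_entries):
        stem = f"fmap/sub-{sub}_dir-{entry.direction}_m0scan"
        files[f"fmap{i}_image"] = stem + ".nii.gz"
        files[f"fmap{i}_sidecar"] = stem + ".json"
    return files


def existing_subject_files(ds: AslDataset) -> set:
    """All subject-relative paths present in the dataset (incl. extras)."""
    return set(dataset_file_map(ds).values()) | set(ds.extra_files)


# --- TSV ----------------------------------------------------------------------

def parse_aslcontext(tsv_text: str) -> AslContext:
    """Parse ``_aslcontext.tsv`` text: header ``volume_type``, one token/row."""
    if not tsv_text.strip():
        raise MalformedTsvError("aslcontext is empty")
    lines = tsv_text.splitlines()
    if lines[0].strip("\r") != "volume_type":
        raise MalformedTsvError(
            f"aslcontext header must be 'volume_type', got {lines[0]!r}")
    tokens = []
    for line in lines[1:]:
        token = line.strip("\r")
        if not token:
            continue
        if token not in VOLUME_TYPES:
            raise MalformedTsvError(f"unknown volume_type token {token!r}")
        tokens.append(token)
    if not tokens:
        raise MalformedTsvError("aslcontext lists no volumes")
    return AslContext(tuple(tokens))


def render_aslcontext(context: AslContext) -> str:
    return "volume_type\n" + "\n".join(context) + "\n"


# --- JSON sidecars ------------------------------------------------------------

def parse_sidecar(json_text: str, role: str, registry=None) -> SidecarMetadata:
    """Parse a sidecar; registered names are type-checked, unknown names kept."""
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise MalformedJsonError(f"invalid JSON sidecar: {exc}") from exc
    if not isinstance(data, dict):
        raise MalformedJsonError("sidecar must be a JSON object")
    index = registry_index(registry)
    for name, value in data.items():
        spec = index.get(name)
        if spec is not None and spec.requirement_for(role) is not None:
            if not spec.conforms(value):
                raise TypeMismatchError(
                    name, f"field {name!r}: value {value!r} does not conform "
                          f"to kind {spec.value_kind!r}")
    return SidecarMetadata(role, data)


def _dump_json(data: dict) -> str:
    return json.dumps(data, indent=4, sort_keys=True, ensure_ascii=False) + "\n"


# --- NIfTI --------------------------------------------------------------------

def _write_nifti_gz(series: ImageSeries, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(series.voxels, dtype=np.float64),
                          affine=series.affine)
    zooms = list(series.voxel_size_mm)
    if series.voxels.ndim == 4:
        zooms.append(1.0)
    img.header.set_zooms(zooms)
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    payload = img.to_bytes()
    with open(path, "wb") as f:
        # mtime=0 and empty filename keep the gzip member deterministic
        with gzip.GzipFile(filename="", fileobj=f, mode="wb", mtime=0) as gz:
            gz.write(payload)


def _read_nifti(path: Path) -> ImageSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageSeries(data, zooms)


def _write_screenshot(path: Path) -> None:
    """Deterministic placeholder JPEG standing in for the labeling-plane shot."""
    from PIL import Image

    arr = np.zeros((48, 64), dtype=np.uint8)
    arr[:] = np.linspace(40, 200, 64, dtype=np.uint8)[None, :]
    arr[20:28, 8:56] = 255  # stylised labeling plane
    Image.fromarray(arr, mode="L").save(str(path), format="JPEG", quality=90)


# --- dataset write ------------------------------------------------------------

def write_dataset(ds: AslDataset, root) -> list:
    """Write the dataset tree under ``root``; returns sorted relative paths.

    ``read_dataset(write_dataset(ds))`` reproduces ``ds``: images bit-exact,
    sidecars key-equal, context order-equal.
    """
    root = Path(root)
    written = []
    try:
        root.mkdir(parents=True, exist_ok=True)
        desc = {"Name": ds.name, "BIDSVersion": BIDS_VERSION, "DatasetType": "raw"}
        (root / "dataset_description.json").write_text(_dump_json(desc), encoding="utf-8")
        written.append("dataset_description.json")
        if ds.readme_present:
            (root / "README").write_text(
                f"{ds.name}\n\nSynthetic ASL dataset written by the aslbids "
                "toolkit. M0 estimates, when used, derive from the generator's "
                "ground-truth equilibrium magnetization map.\n",
                encoding="utf-8")
            written.append("README")

        subdir = root / f"sub-{ds.subject}"
        files = dataset_file_map(ds)
        for slot, rel in files.items():
            (subdir / rel).parent.mkdir(parents=True, exist_ok=True)
        _write_nifti_gz(ds.asl_series, subdir / files["asl_image"])
        (subdir / files["asl_sidecar"]).write_text(
            _dump_json(ds.asl_sidecar.entries), encoding="utf-8")
        (subdir / files["aslcontext"]).write_text(
            render_aslcontext(ds.context), encoding="utf-8")
        if ds.m0_series is not None:
            _write_nifti_gz(ds.m0_series, subdir / files["m0_image"])
            (subdir / files["m0_sidecar"]).write_text(
                _dump_json(ds.m0_sidecar.entries), encoding="utf-8")
        if ds.labeling_screenshot_present:
            _write_screenshot(subdir / files["labeling_screenshot"])
        for i, entry in enumerate(ds.fieldmap_entries):
            _write_nifti_gz(entry.series, subdir / files[f"fmap{i}_image"])
            (subdir / files[f"fmap{i}_sidecar"]).write_text(
                _dump_json(entry.sidecar.entries), encoding="utf-8")
        written.extend(f"sub-{ds.subject}/{rel}" for rel in files.values())
    except OSError as exc:
        raise IoFailureError(f"failed writing dataset to {root}: {exc}") from exc
    return sorted(written)


def write_cbf_derivatives(root, subject: str, results, provenance: dict,
                          voxel_size_mm=(3.0, 3.0, 6.0)) -> list:
    """Write CBF maps + provenance under ``<root>/derivatives/aslbids/``.

    ``results`` is the ``[(pld_s, CbfMap), ...]`` list the quantifier
    returns; multi-delay data get one map per delay (``pld-<k>`` entity).
    Returns the written paths relative to ``root``.
    """
    root = Path(root)
    outdir = root / "derivatives" / "aslbids" / f"sub-{subject}" / "perf"
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    single = len(results) == 1
    for k, (pld, cbf_map) in enumerate(results, start=1):
        stem = (f"sub-{subject}_cbf" if single else f"sub-{subject}_pld-{k}_cbf")
        _write_nifti_gz(ImageSeries(cbf_map.values, voxel_size_mm),
                        outdir / f"{stem}.nii.gz")
        written.append(str((outdir / f"{stem}.nii.gz").relative_to(root)))
    prov = dict(provenance)
    prov["PostLabelingDelays"] = [pld for pld, _ in results]
    prov_path = outdir / f"sub-{subject}_cbf.json"
    prov_path.write_text(_dump_json(prov), encoding="utf-8")
    written.append(str(prov_path.relative_to(root)))
    return sorted(written)


# --- dataset read -------------------------------------------------------------

def _sole(matches: Sequence[Path], what: str, where: Path) -> Path:
    if len(matches) == 0:
        raise MissingFileError(f"no {what} found in {where}")
    if len(matches) > 1:
        raise AmbiguousLayoutError(
            f"multiple {what} files in {where}: {[m.name for m in matches]}; "
            "one ASL run per subject is supported")
    return matches[0]


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return image_path.with_name(name[: -len(ext)] + ".json")
    raise ValueError(name)


def read_dataset(root, subject: str, registry=None) -> AslDataset:
    """Read one subject's ``perf`` (+ ``fmap``) contents from a BIDS tree."""
    root = Path(root)
    desc_path = root / "dataset_description.json"
    if not desc_path.exists():
        raise MissingFileError(f"no dataset_description.json in {root}")
    try:
        desc = json.loads(desc_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise MalformedJsonError(f"invalid dataset_description.json: {exc}") from exc

    subdir = root / f"sub-{subject}"
    perf = subdir / "perf"
    if not perf.is_dir():
        raise MissingFileError(f"no perf directory for subject {subject!r}")

    asl_img_path = _sole(sorted(perf.glob("*_asl.nii*")), "_asl image", perf)
    asl_sc_path = _sidecar_path(asl_img_path)
    if not asl_sc_path.exists():
        raise MissingFileError(f"missing ASL sidecar {asl_sc_path.name}")
    entities = parse_bids_name(asl_img_path.name)
    ctx_path = perf / BidsName(
        subject=entities.subject, session=entities.session,
        acquisition=entities.acquisition, direction=None, run=entities.run,
        suffix="aslcontext", extension=".tsv").render()
    if not ctx_path.exists():
        raise MissingFileError(f"missing {ctx_path.name}")

    asl_series = _read_nifti(asl_img_path)
    asl_sidecar = parse_sidecar(asl_sc_path.read_text(encoding="utf-8"), "asl", registry)
    context = parse_aslcontext(ctx_path.read_text(encoding="utf-8"))

    m0_series = m0_sidecar = None
    m0_matches = sorted(perf.glob("*_m0scan.nii*"))
    consumed = {asl_img_path, asl_sc_path, ctx_path}
    if m0_matches:
        m0_img_path = _sole(m0_matches, "_m0scan image", perf)
        m0_sc_path = _sidecar_path(m0_img_path)
        if not m0_sc_path.exists():
            raise MissingFileError(f"missing m0scan sidecar {m0_sc_path.name}")
        m0_series = _read_nifti(m0_img_path)
        m0_sidecar = parse_sidecar(m0_sc_path.read_text(encoding="utf-8"),
                                   "m0scan", registry)
        consumed |= {m0_img_path, m0_sc_path}

    screenshot = sorted(perf.glob("*_asllabeling.jpg"))
    consumed |= set(screenshot)

    fieldmaps = []
    fmap_dir = subdir / "fmap"
    if fmap_dir.is_dir():
        for img_path in sorted(fmap_dir.glob("*_m0scan.nii*")):
            sc_path = _sidecar_path(img_path)
            if not sc_path.exists():
                raise MissingFileError(f"missing fieldmap sidecar {sc_path.name}")
            ent = parse_bids_name(img_path.name)
            fieldmaps.append(FieldmapEntry(
                series=_read_nifti(img_path),
                sidecar=parse_sidecar(sc_path.read_text(encoding="utf-8"),
                                      "fieldmap", registry),
                direction=ent.direction or "PA"))
            consumed |= {img_path, sc_path}

    extra = sorted(
        str(p.relative_to(subdir)).replace("\\", "/")
        for p in subdir.rglob("*") if p.is_file() and p not in consumed)

    return AslDataset(
        subject=subject,
        asl_series=asl_series,
        asl_sidecar=asl_sidecar,
        context=context,
        m0_series=m0_series,
        m0_sidecar=m0_sidecar,
        fieldmap_entries=fieldmaps,
        labeling_screenshot_present=bool(screenshot),
        extra_files=extra,
        readme_present=(root / "README").exists() or (root / "README.md").exists(),
        name=desc.get("Name", "ASL dataset"),
    )
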