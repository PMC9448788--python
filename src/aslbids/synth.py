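"""Synthetic ASL-BIDS dataset generator with known ground truth.

Emulates the five published example acquisition configurations (GE
single-PLD PCASL 3D spiral; Philips single-PLD PCASL 2D-EPI; Siemens
multi-PLD PASL 3D GRASE; custom multi-PLD PCASL 2D-EPI with a PEPolar
fieldmap; Siemens single-PLD PCASL 3D GRASE with in-series m0scan) plus
arbitrary randomized plans, and can inject single catalogued defects for
validator testing.

The forward model is the exact inverse of the quantification module: the
per-pair difference signal is computed from the true CBF map through the
same single-delay perfusion equations (same constants, same per-slice
effective delays), so a noise-free dataset quantifies back to the ground
truth to floating-point precision.  No MR physics beyond that is emulated —
no T2* decay, motion, or coil sensitivities; the generator exists to
exercise format, validation, and quantification logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidPlanError, UnknownExampleError, UnknownViolationError
from .model import (AslContext, AslDataset, FieldmapEntry, ImageSeries,
                    SidecarMetadata)
from .quantify import (DEFAULT_ALPHA, DEFAULT_LAMBDA, T1_BLOOD_S, T1_TISSUE_S,
                       effective_pld)

#: Two-compartment phantom values: conventional gray/white-matter physiology
#: used purely as test fixtures.
GM_CBF, WM_CBF = 60.0, 20.0          # mL/100 g/min
GM_M0, WM_M0 = 1000.0, 800.0         # arbitrary signal units

#: Static-tissue attenuation applied to control/label baselines when
#: background suppression is on (single configurable factor; the m0scan is
#: never suppressed, which is what makes ASL and M0 signal levels differ).
BACKGROUND_SUPPRESSION_FACTOR = 0.1

DEFAULT_RTP_S = 4.0                  # RepetitionTimePreparation, both series
DEFAULT_TE_S = 0.012
DEFAULT_FLIP_DEG = 90
FIELD_STRENGTH_T = 3.0


@dataclass(frozen=True)
class AcquisitionPlan:
    """Configuration of one synthetic acquisition."""

    name: str
    labeling_type: str               # PCASL | PASL
    plds_s: tuple                    # post-labeling delays (PASL: inversion times)
    labeling_duration_s: Optional[float] = None
    bolus_cutoff_delay_s: Optional[float] = None
    readout: str = "3D"              # 2D | 3D
    slice_timing_s: Optional[tuple] = None
    n_pairs: int = 10
    m0_mode: str = "Separate"        # Separate | Included | Estimate | Absent
    background_suppression: bool = True
    n_bs_pulses: int = 2
    pepolar_fieldmap: bool = False
    deltam_only: bool = False
    labeling_screenshot: bool = False
    grid: tuple = (16, 16, 5)
    noise_sd: float = 1.0
    seed: int = 0
    manufacturer: str = "Siemens"

    def __post_init__(self):
        object.__setattr__(self, "plds_s", tuple(float(p) for p in self.plds_s))
        if self.slice_timing_s is not None:
            object.__setattr__(self, "slice_timing_s",
                               tuple(float(t) for t in self.slice_timing_s))

    def validate(self) -> None:
        if self.labeling_type not in ("PCASL", "PASL"):
            raise InvalidPlanError(f"labeling_type {self.labeling_type!r}")
        if self.labeling_type == "PCASL" and self.labeling_duration_s is None:
            raise InvalidPlanError("PCASL plans need labeling_duration_s")
        if self.labeling_type == "PASL" and self.bolus_cutoff_delay_s is None:
            raise InvalidPlanError("PASL plans need bolus_cutoff_delay_s")
        if self.readout not in ("2D", "3D"):
            raise InvalidPlanError(f"readout {self.readout!r}")
        if self.readout == "2D":
            st = self.slice_timing_s
            if st is None or len(st) != self.grid[2]:
                raise InvalidPlanError(
                    "2D plans need slice_timing_s of length nz")
            if any(t < 0 for t in st) or len(set(st)) != len(st):
                raise InvalidPlanError(
                    "slice_timing_s must be nonnegative and distinct")
        if not self.plds_s:
            raise InvalidPlanError("at least one post-labeling delay required")
        if self.n_pairs < 1:
            raise InvalidPlanError("n_pairs must be >= 1")
        if self.m0_mode not in ("Separate", "Included", "Estimate", "Absent"):
            raise InvalidPlanError(f"m0_mode {self.m0_mode!r}")
        if self.noise_sd < 0:
            raise InvalidPlanError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """The true maps and constants the forward model embeds."""

    cbf_true: np.ndarray             # mL/100 g/min
    m0_true: np.ndarray              # equilibrium magnetization, signal units
    alpha: float
    t1_blood_s: float
    lambda_ml_per_g: float = DEFAULT_LAMBDA

    def __post_init__(self):
        if np.any(self.cbf_true < 0):
            raise ValueError("cbf_true must be nonnegative")
        if np.any(self.m0_true[self.mask] <= 0):
            raise ValueError("m0_true must be positive inside the brain mask")

    @property
    def mask(self) -> np.ndarray:
        return self.m0_true > 0


def default_ground_truth(grid=(16, 16, 5), labeling_type: str = "PCASL") -> GroundTruth:
    """Two-compartment phantom: inner 'gray matter' block, outer 'white
    matter' shell, zero background."""
    nx, ny, nz = grid
    cbf = np.zeros(grid)
    m0 = np.zeros(grid)
    bx, by = max(nx // 8, 1), max(ny // 8, 1)
    bz = 1 if nz >= 3 else 0
    brain = np.zeros(grid, dtype=bool)
    brain[bx:nx - bx, by:ny - by, bz:nz - bz if bz else nz] = True
    cbf[brain] = WM_CBF
    m0[brain] = WM_M0
    gx, gy = nx // 4, ny // 4
    gz = max(bz, 1) if nz >= 5 else bz
    inner = np.zeros(grid, dtype=bool)
    inner[gx:nx - gx, gy:ny - gy, gz:nz - gz if gz else nz] = True
    inner &= brain
    cbf[inner] = GM_CBF
    m0[inner] = GM_M0
    return GroundTruth(cbf, m0, alpha=DEFAULT_ALPHA[labeling_type],
                       t1_blood_s=T1_BLOOD_S[FIELD_STRENGTH_T])


# --- the five example configurations ------------------------------------------

def example_plan(name: str) -> AcquisitionPlan:
    """Plan matching one of the published example configurations asl001..asl005.

    Sequence parameters the published table does not print (exact delay
    values, durations, pair counts) are filled with consensus-typical
    defaults; see the methods documentation.
    """
    nz = 5
    st_2d = tuple(round(0.0365 * z, 4) for z in range(nz))
    plans = {
        # GE product: single-PLD PCASL, stack-of-spirals 3D, 4 BS pulses,
        # time series holds only deltam + m0scan volumes
        "asl001": AcquisitionPlan(
            name="asl001", labeling_type="PCASL", plds_s=(1.525,),
            labeling_duration_s=1.450, readout="3D", n_pairs=3,
            m0_mode="Included", background_suppression=True, n_bs_pulses=4,
            deltam_only=True, manufacturer="GE"),
        # Philips WIP: single-PLD PCASL, single-shot 2D-EPI, 2 BS pulses,
        # separate m0scan
        "asl002": AcquisitionPlan(
            name="asl002", labeling_type="PCASL", plds_s=(1.8,),
            labeling_duration_s=1.8, readout="2D", slice_timing_s=st_2d,
            n_pairs=30, m0_mode="Separate", background_suppression=True,
            n_bs_pulses=2, labeling_screenshot=True, manufacturer="Philips"),
        # Siemens C2P (Bremen): multi-TI PASL, segmented 3D GRASE, 2 BS
        # pulses, separate m0scan
        "asl003": AcquisitionPlan(
            name="asl003", labeling_type="PASL",
            plds_s=(1.0, 1.5, 2.0, 2.5, 3.0), bolus_cutoff_delay_s=0.7,
            readout="3D", n_pairs=10, m0_mode="Separate",
            background_suppression=True, n_bs_pulses=2),
        # custom multi-PLD PCASL, 2D-EPI, 2 BS pulses, in-series m0scan,
        # plus a reversed phase-encoding m0scan in fmap/
        "asl004": AcquisitionPlan(
            name="asl004", labeling_type="PCASL",
            plds_s=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0), labeling_duration_s=1.4,
            readout="2D", slice_timing_s=st_2d, n_pairs=24,
            m0_mode="Included", background_suppression=True, n_bs_pulses=2,
            pepolar_fieldmap=True),
        # Siemens WIP: single-PLD PCASL, segmented 3D GRASE, 4 BS pulses,
        # in-series m0scan
        "asl005": AcquisitionPlan(
            name="asl005", labeling_type="PCASL", plds_s=(2.0,),
            labeling_duration_s=1.8, readout="3D", n_pairs=8,
            m0_mode="Included", background_suppression=True, n_bs_pulses=4),
    }
    try:
        return plans[name]
    except KeyError:
        raise UnknownExampleError(
            f"unknown example {name!r}; choose from {sorted(plans)}") from None


EXAMPLE_NAMES = ("asl001", "asl002", "asl003", "asl004", "asl005")


# --- forward model ------------------------------------------------------------

def _build_asl_sidecar(plan: AcquisitionPlan, gt: GroundTruth,
                       pld_value) -> SidecarMetadata:
    voxel_mm = [3.0, 3.0, 6.0]
    entries = {
        "ArterialSpinLabelingType": plan.labeling_type,
        "PostLabelingDelay": pld_value,
        "BackgroundSuppression": plan.background_suppression,
        "M0Type": plan.m0_mode,
        "TotalAcquiredPairs": plan.n_pairs,
        "MagneticFieldStrength": FIELD_STRENGTH_T,
        "MRAcquisitionType": plan.readout,
        "EchoTime": DEFAULT_TE_S,
        "FlipAngle": DEFAULT_FLIP_DEG,
        "RepetitionTimePreparation": DEFAULT_RTP_S,
        "AcquisitionVoxelSize": voxel_mm,
        "Manufacturer": plan.manufacturer,
    }
    if plan.labeling_type == "PCASL":
        entries["LabelingDuration"] = plan.labeling_duration_s
    else:
        entries["BolusCutOffFlag"] = True
        entries["BolusCutOffDelayTime"] = plan.bolus_cutoff_delay_s
        entries["BolusCutOffTechnique"] = "Q2TIPS"
    if plan.readout == "2D":
        entries["SliceTiming"] = list(plan.slice_timing_s)
    if plan.background_suppression:
        entries["BackgroundSuppressionNumberPulses"] = plan.n_bs_pulses
        entries["BackgroundSuppressionPulseTime"] = [
            round(0.4 * (i + 1), 3) for i in range(plan.n_bs_pulses)]
    if plan.m0_mode == "Estimate":
        entries["M0Estimate"] = round(float(gt.m0_true[gt.mask].mean()), 6)
    if plan.labeling_screenshot:
        entries["LabelingLocationDescription"] = (
            "Labeling plane placed perpendicular to the internal carotid and "
            "vertebral arteries, 90 mm below the AC-PC line")
    if plan.pepolar_fieldmap:
        entries["PhaseEncodingDirection"] = "j-"
    return SidecarMetadata("asl", entries)


def _deltam_volume(plan: AcquisitionPlan, gt: GroundTruth, pld: float,
                   sidecar: SidecarMetadata) -> np.ndarray:
    """Per-pair difference signal implied by the true CBF at this delay."""
    t1b = gt.t1_blood_s
    if plan.labeling_type == "PCASL":
        denom_time = t1b * (1.0 - np.exp(-plan.labeling_duration_s / t1b))
    else:
        denom_time = plan.bolus_cutoff_delay_s
    nz = plan.grid[2]
    pld_eff = effective_pld(sidecar, nz, pld)[None, None, :]
    return (gt.cbf_true * 2.0 * gt.alpha * denom_time * gt.m0_true
            * np.exp(-pld_eff / t1b) / (6000.0 * gt.lambda_ml_per_g))


def synthesize_dataset(plan: AcquisitionPlan,
                       ground_truth: Optional[GroundTruth] = None) -> tuple:
    """Build a valid dataset from a plan; returns ``(AslDataset, GroundTruth)``.

    Deterministic for a given (plan, seed); with ``noise_sd == 0`` the
    quantification module recovers the true CBF map exactly.
    """
    plan.validate()
    gt = ground_truth if ground_truth is not None else default_ground_truth(
        plan.grid, plan.labeling_type)
    if gt.cbf_true.shape != tuple(plan.grid):
        raise InvalidPlanError("ground truth shape differs from plan grid")
    rng = np.random.default_rng(plan.seed)

    def noisy(vol):
        if plan.noise_sd == 0:
            return vol.copy()
        return vol + rng.normal(0.0, plan.noise_sd, size=vol.shape)

    sat = 1.0 - np.exp(-DEFAULT_RTP_S / T1_TISSUE_S[FIELD_STRENGTH_T])
    m0_sat = gt.m0_true * sat
    bs = BACKGROUND_SUPPRESSION_FACTOR if plan.background_suppression else 1.0
    baseline = m0_sat * bs

    pair_plds = [plan.plds_s[k % len(plan.plds_s)] for k in range(plan.n_pairs)]
    multi_pld = len(plan.plds_s) > 1

    # provisional sidecar (scalar delay) so the forward model can reuse the
    # quantifier's effective-delay computation
    sidecar = _build_asl_sidecar(plan, gt, plan.plds_s[0])

    types, vols, vol_plds = [], [], []
    in_series_m0 = plan.m0_mode == "Included"
    if in_series_m0:
        types.append("m0scan")
        vols.append(noisy(m0_sat))
        vol_plds.append(0.0)
    for pld in pair_plds:
        dm = _deltam_volume(plan, gt, pld, sidecar)
        if plan.deltam_only:
            types.append("deltam")
            vols.append(noisy(dm))
            vol_plds.append(pld)
        else:
            control = noisy(baseline)
            types.extend(["control", "label"])
            vols.extend([control, control - dm + (0 if plan.noise_sd == 0 else
                                                  rng.normal(0.0, plan.noise_sd,
                                                             size=dm.shape))])
            vol_plds.extend([pld, pld])

    if multi_pld:
        sidecar.entries["PostLabelingDelay"] = [float(p) for p in vol_plds]

    asl_series = ImageSeries(np.stack(vols, axis=-1))
    context = AslContext(tuple(types))

    m0_series = m0_sidecar = None
    if plan.m0_mode == "Separate":
        m0_series = ImageSeries(noisy(m0_sat))
        m0_entries = {
            "EchoTime": DEFAULT_TE_S,
            "FlipAngle": DEFAULT_FLIP_DEG,
            "RepetitionTimePreparation": DEFAULT_RTP_S,
            "IntendedFor": f"perf/sub-01_asl.nii.gz",
            "AcquisitionVoxelSize": [3.0, 3.0, 6.0],
        }
        if plan.pepolar_fieldmap:
            m0_entries["PhaseEncodingDirection"] = "j-"
        m0_sidecar = SidecarMetadata("m0scan", m0_entries)

    fieldmaps = []
    if plan.pepolar_fieldmap:
        target = ("perf/sub-01_m0scan.nii.gz" if plan.m0_mode == "Separate"
                  else "perf/sub-01_asl.nii.gz")
        fieldmaps.append(FieldmapEntry(
            series=ImageSeries(noisy(m0_sat)),
            sidecar=SidecarMetadata("fieldmap", {
                "PhaseEncodingDirection": "j",
                "IntendedFor": target,
            }),
            direction="PA"))

    dataset = AslDataset(
        subject="01",
        asl_series=asl_series,
        asl_sidecar=sidecar,
        context=context,
        m0_series=m0_series,
        m0_sidecar=m0_sidecar,
        fieldmap_entries=fieldmaps,
        labeling_screenshot_present=plan.labeling_screenshot,
        readme_present=True,
        name=f"{plan.name} synthetic ASL dataset",
    )
    return dataset, gt


# --- randomized plans ---------------------------------------------------------

def random_plan(seed: int) -> AcquisitionPlan:
    """A random but internally consistent plan, for validity sweeps."""
    rng = np.random.default_rng(seed)
    labeling = str(rng.choice(["PCASL", "PASL"]))
    readout = str(rng.choice(["2D", "3D"]))
    nz = 5
    multi = bool(rng.integers(0, 2))
    if multi:
        base = float(rng.uniform(0.5, 1.0))
        plds = tuple(round(base + 0.5 * i, 3) for i in range(int(rng.integers(2, 5))))
    else:
        plds = (round(float(rng.uniform(1.0, 2.5)), 3),)
    n_pairs = int(rng.integers(2, 11)) * (len(plds) if multi else 1)
    m0_mode = str(rng.choice(["Separate", "Included", "Estimate", "Absent"]))
    return AcquisitionPlan(
        name=f"random{seed}",
        labeling_type=labeling,
        plds_s=plds,
        labeling_duration_s=1.8 if labeling == "PCASL" else None,
        bolus_cutoff_delay_s=0.7 if labeling == "PASL" else None,
        readout=readout,
        slice_timing_s=tuple(round(0.04 * z, 4) for z in range(nz))
        if readout == "2D" else None,
        n_pairs=n_pairs,
        m0_mode=m0_mode,
        background_suppression=bool(rng.integers(0, 2)),
        n_bs_pulses=int(rng.integers(2, 5)),
        pepolar_fieldmap=bool(rng.integers(0, 2)),
        noise_sd=float(rng.uniform(0.0, 2.0)),
        seed=seed,
    )


# --- defect injection ---------------------------------------------------------

#: violation id -> (rule ids that must fire, rule ids allowed as side effects)
MUTATION_RULES = {
    "truncate-context": ({"ASL201"}, {"ASL201", "ASL202"}),
    "wrong-m0type": ({"ASL301"}, {"ASL301"}),
    "scaling-key": ({"ASL501"}, {"ASL501"}),
    "break-pepolar": ({"ASL603"}, {"ASL603"}),
    "shuffle-context": ({"ASL202"}, {"ASL202", "ASL204"}),
}


def expected_rules(violation_id: str) -> tuple:
    """(must-fire, allowed) ERROR rule ids for a catalogued violation."""
    if violation_id.startswith("delete-field:"):
        return {"ASL101"}, {"ASL101", "ASL601", "ASL602"}
    try:
        return MUTATION_RULES[violation_id]
    except KeyError:
        raise UnknownViolationError(violation_id) from None


def mutate_dataset(dataset: AslDataset, violation_id: str) -> AslDataset:
    """Deep-copied dataset with exactly one injected defect."""
    ds = dataset.copy()
    if violation_id.startswith("delete-field:"):
        name = violation_id.split(":", 1)[1]
        sidecars = [ds.asl_sidecar]
        if ds.m0_sidecar is not None:
            sidecars.append(ds.m0_sidecar)
        sidecars.extend(e.sidecar for e in ds.fieldmap_entries)
        for sc in sidecars:
            if name in sc.entries:
                del sc.entries[name]
                return ds
        raise UnknownViolationError(
            f"field {name!r} not present in any sidecar")
    if violation_id == "truncate-context":
        if len(ds.context) < 2:
            raise UnknownViolationError("context too short to truncate")
        ds.context = AslContext(ds.context.volume_types[:-1])
        return ds
    if violation_id == "wrong-m0type":
        current = ds.asl_sidecar.get("M0Type")
        ds.asl_sidecar.entries["M0Type"] = (
            "Included" if current == "Separate" else "Separate")
        return ds
    if violation_id == "scaling-key":
        ds.asl_sidecar.entries["RescaleSlope"] = 1.6
        return ds
    if violation_id == "break-pepolar":
        if not ds.fieldmap_entries:
            raise UnknownViolationError("dataset has no PEPolar fieldmap")
        entry = ds.fieldmap_entries[0]
        target = entry.sidecar.get("IntendedFor", "")
        # same polarity as the target: no longer opposites
        src = (ds.m0_sidecar if target.endswith("_m0scan.nii.gz")
               and ds.m0_sidecar is not None else ds.asl_sidecar)
        entry.sidecar.entries["PhaseEncodingDirection"] = src.get(
            "PhaseEncodingDirection", "j-")
        return ds
    if violation_id == "shuffle-context":
        types = list(ds.context.volume_types)
        if "control" in types:
            types[types.index("control")] = "label"
        elif "deltam" in types:
            types[types.index("deltam")] = "control"
        else:
            raise UnknownViolationError("no control or deltam rows to relabel")
        ds.context = AslContext(tuple(types))
        return ds
    raise UnknownViolationError(violation_id)
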