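"""Single-PLD CBF quantification from sidecar metadata alone.

Implements the standard single-compartment perfusion models for
(pseudo-)continuous and pulsed labeling (2015 ISMRM perfusion consensus
forms).  For (P)CASL with labeling duration tau and post-labeling delay PLD::

    CBF = 6000 * lambda * dM * exp(PLD_eff / T1b)
          / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))      [mL/100g/min]

and for PASL under a QUIPSS-II bolus cutoff with inversion time TI and bolus
width TI1::

    CBF = 6000 * lambda * dM * exp(TI_eff / T1b) / (2 * alpha * TI1 * M0)

where dM is the mean control-minus-label difference, M0 the equilibrium
magnetization of blood (approximated by the saturation-corrected m0scan),
lambda the blood-brain partition coefficient, alpha the labeling efficiency,
and T1b the longitudinal relaxation time of arterial blood.  For 2D readouts
the effective PLD (or TI) of slice z is PostLabelingDelay + SliceTiming[z].

Everything needed here comes from REQUIRED sidecar fields, the aslcontext,
and field-strength-keyed defaults — which is the point: the REQUIRED
metadata ladder is sufficient for quantification.  Multi-delay series are
quantified per delay; kinetic-model fitting across delays is out of scope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (M0UnavailableError, MissingSliceTimingError,
                     UnknownFieldStrengthError, UnpairableContextError,
                     UnsupportedSchemeError)
from .model import AslContext, AslDataset, ImageSeries, SidecarMetadata

log = logging.getLogger(__name__)

#: Default constants keyed by MagneticFieldStrength (tesla).  Unknown field
#: strengths raise rather than interpolate.
T1_BLOOD_S = {3.0: 1.650, 1.5: 1.350}
T1_TISSUE_S = {3.0: 1.330, 1.5: 1.200}  # used only for M0 saturation correction

#: Default labeling efficiency by scheme (overridden by LabelingEfficiency).
DEFAULT_ALPHA = {"PCASL": 0.85, "CASL": 0.85, "PASL": 0.98}

#: Blood-brain partition coefficient, mL/g.
DEFAULT_LAMBDA = 0.9


@dataclass
class QuantificationParams:
    """Physiological constants entering the CBF formulas.

    Defaults are the 3 T consensus values; use :meth:`from_sidecar` to pick
    them by MagneticFieldStrength and labeling scheme.
    """

    lambda_ml_per_g: float = DEFAULT_LAMBDA
    t1_blood_s: float = T1_BLOOD_S[3.0]
    alpha: float = DEFAULT_ALPHA["PCASL"]
    t1_tissue_s: float = T1_TISSUE_S[3.0]
    mask_fraction: float = 0.1  # of the M0 robust maximum

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("labeling efficiency alpha must be in (0, 1]")
        for name in ("lambda_ml_per_g", "t1_blood_s", "t1_tissue_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_sidecar(cls, asl_sidecar: SidecarMetadata,
                     **overrides) -> "QuantificationParams":
        b0 = asl_sidecar.get("MagneticFieldStrength")
        b0 = float(b0) if b0 is not None else 3.0
        if b0 not in T1_BLOOD_S:
            raise UnknownFieldStrengthError(
                f"no default constants tabulated for {b0} T; "
                f"known: {sorted(T1_BLOOD_S)}")
        scheme = asl_sidecar.get("ArterialSpinLabelingType", "PCASL")
        alpha = asl_sidecar.get("LabelingEfficiency")
        if alpha is None:
            alpha = DEFAULT_ALPHA.get(scheme, DEFAULT_ALPHA["PCASL"])
        kwargs = dict(t1_blood_s=T1_BLOOD_S[b0], t1_tissue_s=T1_TISSUE_S[b0],
                      alpha=float(alpha))
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {"lambda_ml_per_g": self.lambda_ml_per_g,
                "t1_blood_s": self.t1_blood_s, "alpha": self.alpha,
                "t1_tissue_s": self.t1_tissue_s,
                "mask_fraction": self.mask_fraction}


@dataclass
class CbfMap:
    """CBF values in mL/100 g/min; voxels outside the mask are zeroed."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite CBF inside the mask")

    @property
    def masked_mean(self) -> float:
        return float(self.values[self.mask].mean())


# --- building blocks ----------------------------------------------------------

def pair_deltams(series: ImageSeries, context: AslContext) -> np.ndarray:
    """Stack of per-pair control-minus-label difference volumes.

    Pairs form in acquisition order: the k-th control with the k-th label.
    m0scan rows are excluded.  For deltam series the stored difference
    volumes are returned as-is.
    """
    controls = context.indices("control")
    labels = context.indices("label")
    deltams = context.indices("deltam")
    if deltams and not controls and not labels:
        return np.stack([series.volume(i) for i in deltams], axis=-1)
    if not controls or len(controls) != len(labels):
        raise UnpairableContextError(
            f"{len(controls)} control vs {len(labels)} label rows cannot pair")
    return np.stack([series.volume(c) - series.volume(l)
                     for c, l in zip(controls, labels)], axis=-1)


def subtract_pairs(series: ImageSeries, context: AslContext) -> np.ndarray:
    """Voxelwise mean control-minus-label difference over all pairs (3D)."""
    return pair_deltams(series, context).mean(axis=-1)


def resolve_m0(dataset: AslDataset, params: Optional[QuantificationParams] = None,
               allow_control_fallback: bool = False):
    """Resolve the calibration denominator M0 (3D map or scalar).

    Acquired m0scans are corrected for incomplete T1 relaxation by dividing
    by ``1 - exp(-RepetitionTimePreparation / T1_tissue)``.  A scalar
    M0Estimate is used uncorrected.
    """
    if params is None:
        params = QuantificationParams.from_sidecar(dataset.asl_sidecar)
    m0type = dataset.asl_sidecar.get("M0Type")
    if m0type == "Separate":
        if dataset.m0_series is None:
            raise M0UnavailableError("M0Type 'Separate' but no m0scan image")
        raw = (dataset.m0_series.voxels.mean(axis=-1)
               if dataset.m0_series.voxels.ndim == 4 else dataset.m0_series.voxels)
        rtp = dataset.m0_sidecar.get("RepetitionTimePreparation")
        return raw / _saturation_factor(rtp, params.t1_tissue_s)
    if m0type == "Included":
        rows = dataset.context.indices("m0scan")
        if not rows:
            raise M0UnavailableError("M0Type 'Included' but no m0scan rows")
        raw = np.stack([dataset.asl_series.volume(i) for i in rows],
                       axis=-1).mean(axis=-1)
        rtp = dataset.asl_sidecar.get("RepetitionTimePreparation")
        return raw / _saturation_factor(rtp, params.t1_tissue_s)
    if m0type == "Estimate":
        est = dataset.asl_sidecar.get("M0Estimate")
        if not isinstance(est, (int, float)) or isinstance(est, bool) or est <= 0:
            raise M0UnavailableError(f"unusable M0Estimate: {est!r}")
        return float(est)
    if m0type == "Absent":
        if allow_control_fallback:
            controls = dataset.context.indices("control")
            if not controls:
                raise M0UnavailableError("no control volumes for M0 fallback")
            log.warning("M0 absent: falling back to mean control signal; "
                        "CBF scale is approximate")
            return np.stack([dataset.asl_series.volume(i) for i in controls],
                            axis=-1).mean(axis=-1)
        raise M0UnavailableError(
            "M0Type 'Absent': no calibration data (pass "
            "allow_control_fallback=True for an approximate mean-control M0)")
    raise M0UnavailableError(f"unknown M0Type {m0type!r}")


def _saturation_factor(rtp, t1_tissue_s: float) -> float:
    if isinstance(rtp, (list, tuple)):
        if len(rtp) != 1:
            raise M0UnavailableError(
                "per-volume RepetitionTimePreparation arrays are not supported "
                "for M0 correction")
        rtp = rtp[0]
    if not isinstance(rtp, (int, float)) or isinstance(rtp, bool) or rtp <= 0:
        raise M0UnavailableError(
            f"RepetitionTimePreparation needed for M0 correction, got {rtp!r}")
    return 1.0 - float(np.exp(-float(rtp) / t1_tissue_s))


def effective_pld(asl_sidecar: SidecarMetadata, n_slices: int,
                  pld: Optional[float] = None) -> np.ndarray:
    """Per-slice effective post-labeling delay (length ``n_slices``).

    2D readouts add SliceTiming[z]; 3D readouts excite all slices at once.
    ``pld`` overrides the sidecar value (used per delay in multi-PLD series).
    """
    if pld is None:
        pld = asl_sidecar.get("PostLabelingDelay")
        if isinstance(pld, (list, tuple)):
            raise ValueError("per-volume PostLabelingDelay array: pass the "
                             "delay of the volume group explicitly")
    pld = float(pld)
    if asl_sidecar.get("MRAcquisitionType") == "2D":
        st = asl_sidecar.get("SliceTiming")
        if not isinstance(st, (list, tuple)) or len(st) != n_slices:
            raise MissingSliceTimingError(
                f"2D readout needs SliceTiming of length {n_slices}, got {st!r}")
        return pld + np.asarray(st, dtype=np.float64)
    return np.full(n_slices, pld, dtype=np.float64)


def _m0_mask(m0, fraction: float, shape) -> np.ndarray:
    if np.isscalar(m0):
        return np.ones(shape, dtype=bool)
    robust_max = float(np.percentile(m0, 99.0))
    return np.asarray(m0) > fraction * robust_max


def quantify_cbf(deltam: np.ndarray, m0, asl_sidecar: SidecarMetadata,
                 params: Optional[QuantificationParams] = None,
                 pld: Optional[float] = None) -> CbfMap:
    """Apply the single-delay CBF model to a mean difference map.

    ``m0`` may be a 3D map or a scalar; ``pld`` selects the delay when the
    sidecar stores a per-volume array.
    """
    if params is None:
        params = QuantificationParams.from_sidecar(asl_sidecar)
    if asl_sidecar.get("LookLocker") is True:
        raise UnsupportedSchemeError("Look-Locker series are not quantified")
    deltam = np.asarray(deltam, dtype=np.float64)
    nz = deltam.shape[2]
    pld_eff = effective_pld(asl_sidecar, nz, pld)[None, None, :]
    lam, t1b, alpha = params.lambda_ml_per_g, params.t1_blood_s, params.alpha
    scheme = asl_sidecar.get("ArterialSpinLabelingType")

    if scheme in ("PCASL", "CASL"):
        tau = asl_sidecar.get("LabelingDuration")
        if isinstance(tau, (list, tuple)):
            raise UnsupportedSchemeError(
                "per-volume LabelingDuration arrays are not supported in the "
                "single-delay model")
        if not isinstance(tau, (int, float)) or isinstance(tau, bool):
            raise UnsupportedSchemeError(f"LabelingDuration needed, got {tau!r}")
        denom_time = t1b * (1.0 - np.exp(-float(tau) / t1b))
    elif scheme == "PASL":
        if asl_sidecar.get("BolusCutOffFlag") is not True:
            raise UnsupportedSchemeError(
                "PASL without a bolus cutoff has an ill-defined bolus duration")
        ti1 = asl_sidecar.get("BolusCutOffDelayTime")
        if not isinstance(ti1, (int, float)) or isinstance(ti1, bool):
            raise UnsupportedSchemeError(
                f"BolusCutOffDelayTime needed, got {ti1!r}")
        denom_time = float(ti1)
    else:
        raise UnsupportedSchemeError(f"unknown labeling scheme {scheme!r}")

    mask = _m0_mask(m0, params.mask_fraction, deltam.shape)
    m0_arr = np.broadcast_to(np.float64(m0) if np.isscalar(m0)
                             else np.asarray(m0, dtype=np.float64), deltam.shape)
    safe_m0 = np.where(mask, m0_arr, 1.0)
    cbf = (6000.0 * lam * deltam * np.exp(pld_eff / t1b)
           / (2.0 * alpha * denom_time * safe_m0))
    cbf[~mask] = 0.0
    return CbfMap(cbf, mask)


# --- dataset-level driver -----------------------------------------------------

def _pld_of_volume(sidecar: SidecarMetadata, index: int):
    pld = sidecar.get("PostLabelingDelay")
    if isinstance(pld, (list, tuple)):
        return float(pld[index])
    return float(pld)


def quantify_dataset(dataset: AslDataset,
                     params: Optional[QuantificationParams] = None,
                     force: bool = False,
                     allow_control_fallback: bool = False) -> list:
    """Quantify a dataset into one CbfMap per distinct post-labeling delay.

    Returns ``[(pld_s, CbfMap), ...]`` sorted by delay (a single-element list
    for single-PLD data).  Refuses datasets with validation errors unless
    ``force`` is set.
    """
    if not force:
        from .validation import validate

        report = validate(dataset)
        if not report.valid:
            raise UnsupportedSchemeError(
                f"dataset has {report.n_errors} validation error(s); "
                "fix them or pass force=True")
    if params is None:
        params = QuantificationParams.from_sidecar(dataset.asl_sidecar)
    m0 = resolve_m0(dataset, params, allow_control_fallback)

    context, series, sc = dataset.context, dataset.asl_series, dataset.asl_sidecar
    controls = context.indices("control")
    labels = context.indices("label")
    deltam_rows = context.indices("deltam")
    groups = {}  # pld -> list of 3D deltam volumes
    if deltam_rows and not controls:
        for i in deltam_rows:
            groups.setdefault(round(_pld_of_volume(sc, i), 9), []).append(
                series.volume(i))
    else:
        if len(controls) != len(labels) or not controls:
            raise UnpairableContextError(
                f"{len(controls)} control vs {len(labels)} label rows")
        for c, l in zip(controls, labels):
            groups.setdefault(round(_pld_of_volume(sc, c), 9), []).append(
                series.volume(c) - series.volume(l))

    results = []
    for pld in sorted(groups):
        deltam = np.stack(groups[pld], axis=-1).mean(axis=-1)
        results.append((pld, quantify_cbf(deltam, m0, sc, params, pld=pld)))
    return results
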