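"""CBF quantification: building blocks, closed forms, recovery, invariances."""
from dataclasses import replace

import numpy as np
import pytest

from aslbids import (AslContext, ImageSeries, QuantificationParams,
                     SidecarMetadata, effective_pld, example_plan,
                     quantify_cbf, quantify_dataset, resolve_m0,
                     subtract_pairs, synthesize_dataset)
from aslbids.errors import (M0UnavailableError, MissingSliceTimingError,
                            UnknownFieldStrengthError, UnpairableContextError,
                            UnsupportedSchemeError)

# Closed-form oracle values, hand-evaluated from the single-delay models:
#   PCASL: 6000*0.9*0.01*e^(1.8/1.65) / (2*0.85*1.65*(1 - e^(-1.8/1.65)))
#   PASL:  6000*0.9*0.01*e^(1.8/1.65) / (2*0.98*0.7)
PCASL_HAND_VALUE = 86.29992012955985
PASL_HAND_VALUE = 117.16973478478751
SATURATION_ONE_T1 = 0.6321205588285577  # 1 - e^-1


def stack(volumes):
    return ImageSeries(np.stack(volumes, axis=-1))


# --- pair subtraction ---------------------------------------------------------

def test_subtract_pairs_mean():
    c = np.full((2, 2, 1), 10.0)
    l = np.full((2, 2, 1), 9.0)
    dm = subtract_pairs(stack([c, l, c, l]),
                        AslContext(("control", "label") * 2))
    assert np.allclose(dm, 1.0)


def test_subtract_pairs_excludes_m0scan():
    m0 = np.full((2, 2, 1), 900.0)
    c = np.full((2, 2, 1), 10.0)
    l = np.full((2, 2, 1), 8.0)
    dm = subtract_pairs(stack([m0, c, l]),
                        AslContext(("m0scan", "control", "label")))
    assert np.allclose(dm, 2.0)


def test_subtract_pairs_deltam_series():
    d1 = np.full((2, 2, 1), 3.0)
    d2 = np.full((2, 2, 1), 5.0)
    dm = subtract_pairs(stack([d1, d2]), AslContext(("deltam", "deltam")))
    assert np.allclose(dm, 4.0)


def test_unbalanced_context_unpairable():
    c = np.full((2, 2, 1), 1.0)
    with pytest.raises(UnpairableContextError):
        subtract_pairs(stack([c, c, c]),
                       AslContext(("control", "control", "label")))


# --- M0 resolution ------------------------------------------------------------

def test_m0_saturation_limit(fixtures):
    ds = fixtures["asl002"][0].copy()
    ds.m0_sidecar.entries["RepetitionTimePreparation"] = 1000.0
    raw = ds.m0_series.voxels
    m0 = resolve_m0(ds)
    assert np.allclose(m0, raw, rtol=1e-9)


def test_m0_saturation_at_one_t1(fixtures):
    ds = fixtures["asl002"][0].copy()
    params = QuantificationParams.from_sidecar(ds.asl_sidecar)
    ds.m0_sidecar.entries["RepetitionTimePreparation"] = params.t1_tissue_s
    m0 = resolve_m0(ds, params)
    assert np.allclose(m0, ds.m0_series.voxels / SATURATION_ONE_T1, rtol=1e-9)


def test_m0_estimate_used_uncorrected(fixtures):
    ds = fixtures["asl005"][0].copy()
    ds.asl_sidecar.entries["M0Type"] = "Estimate"
    ds.asl_sidecar.entries["M0Estimate"] = 1234.5
    assert resolve_m0(ds) == 1234.5


def test_m0_absent_raises_unless_fallback_allowed(fixtures):
    ds = fixtures["asl002"][0].copy()
    ds.asl_sidecar.entries["M0Type"] = "Absent"
    ds.m0_series = ds.m0_sidecar = None
    with pytest.raises(M0UnavailableError):
        resolve_m0(ds)
    fallback = resolve_m0(ds, allow_control_fallback=True)
    assert fallback.shape == ds.asl_series.voxels.shape[:3]


# --- effective delay ----------------------------------------------------------

def test_effective_pld_2d_adds_slice_timing():
    sc = SidecarMetadata("asl", {"MRAcquisitionType": "2D",
                                 "PostLabelingDelay": 1.8,
                                 "SliceTiming": [0.0, 0.04, 0.08]})
    assert np.allclose(effective_pld(sc, 3), [1.80, 1.84, 1.88])


def test_effective_pld_3d_is_constant():
    sc = SidecarMetadata("asl", {"MRAcquisitionType": "3D",
                                 "PostLabelingDelay": 2.0})
    assert np.allclose(effective_pld(sc, 5), [2.0] * 5)


def test_effective_pld_2d_without_slice_timing_raises():
    sc = SidecarMetadata("asl", {"MRAcquisitionType": "2D",
                                 "PostLabelingDelay": 1.8})
    with pytest.raises(MissingSliceTimingError):
        effective_pld(sc, 3)


# --- closed-form values -------------------------------------------------------

def pcasl_sidecar(**extra):
    base = {"ArterialSpinLabelingType": "PCASL", "PostLabelingDelay": 1.8,
            "LabelingDuration": 1.8, "MRAcquisitionType": "3D",
            "MagneticFieldStrength": 3.0}
    base.update(extra)
    return SidecarMetadata("asl", base)


def test_pcasl_closed_form_matches_hand_value():
    dm = np.full((2, 2, 1), 10.0)
    cbf = quantify_cbf(dm, np.full((2, 2, 1), 1000.0), pcasl_sidecar())
    assert np.allclose(cbf.values, PCASL_HAND_VALUE, rtol=1e-9)


def test_pasl_closed_form_matches_hand_value():
    sc = SidecarMetadata("asl", {
        "ArterialSpinLabelingType": "PASL", "PostLabelingDelay": 1.8,
        "BolusCutOffFlag": True, "BolusCutOffDelayTime": 0.7,
        "MRAcquisitionType": "3D", "MagneticFieldStrength": 3.0})
    dm = np.full((2, 2, 1), 10.0)
    cbf = quantify_cbf(dm, np.full((2, 2, 1), 1000.0), sc)
    assert np.allclose(cbf.values, PASL_HAND_VALUE, rtol=1e-9)


def test_zero_difference_gives_zero_cbf():
    cbf = quantify_cbf(np.zeros((2, 2, 1)), np.full((2, 2, 1), 1000.0),
                       pcasl_sidecar())
    assert np.all(cbf.values == 0.0)


def test_scalar_m0_accepted():
    dm = np.full((2, 2, 1), 10.0)
    cbf = quantify_cbf(dm, 1000.0, pcasl_sidecar())
    assert np.allclose(cbf.values, PCASL_HAND_VALUE, rtol=1e-9)


def test_unsupported_schemes_raise():
    dm = np.full((2, 2, 1), 1.0)
    m0 = np.full((2, 2, 1), 1000.0)
    with pytest.raises(UnsupportedSchemeError):
        quantify_cbf(dm, m0, SidecarMetadata("asl", {
            "ArterialSpinLabelingType": "PASL", "PostLabelingDelay": 1.8,
            "BolusCutOffFlag": False, "MRAcquisitionType": "3D"}))
    with pytest.raises(UnsupportedSchemeError):
        quantify_cbf(dm, m0, pcasl_sidecar(LookLocker=True))


def test_unknown_field_strength_errors():
    with pytest.raises(UnknownFieldStrengthError):
        QuantificationParams.from_sidecar(
            SidecarMetadata("asl", {"MagneticFieldStrength": 7.0}))


def test_labeling_efficiency_overrides_default():
    params = QuantificationParams.from_sidecar(
        pcasl_sidecar(LabelingEfficiency=0.72))
    assert params.alpha == 0.72
    assert QuantificationParams.from_sidecar(pcasl_sidecar()).alpha == 0.85


# --- recovery and invariances -------------------------------------------------

@pytest.mark.parametrize("name", ["asl001", "asl002", "asl003", "asl004", "asl005"])
def test_noise_free_recovery(noise_free, name):
    """Forward model inverted exactly: per-voxel error at float precision."""
    ds, gt = noise_free[name]
    for _, cbf in quantify_dataset(ds):
        m = cbf.mask & (gt.cbf_true > 0)
        assert m.any()
        rel = np.abs(cbf.values[m] - gt.cbf_true[m]) / gt.cbf_true[m]
        assert rel.max() <= 1e-6


def test_noisy_recovery_masked_mean_within_5pct():
    """At per-pair difference SNR ~5 and 40 pairs, the masked-mean CBF is
    recovered within 5% in each of 25 seeded replicates."""
    base = replace(example_plan("asl005"), n_pairs=40, noise_sd=1.0)
    for i in range(25):
        ds, gt = synthesize_dataset(replace(base, seed=500 + i))
        (_, cbf), = quantify_dataset(ds)
        m = gt.cbf_true > 0
        est = cbf.values[m & cbf.mask].mean()
        true = gt.cbf_true[m].mean()
        assert abs(est - true) / true <= 0.05


def test_scale_equivariance(noise_free):
    """CBF is invariant under joint positive rescaling of ASL and M0 data —
    the reason no scale factors may survive into the sidecars."""
    ds, _ = noise_free["asl002"]
    (_, ref), = quantify_dataset(ds)
    for c in (0.25, 3.0, 1e4):
        scaled = ds.copy()
        scaled.asl_series = ImageSeries(ds.asl_series.voxels * c,
                                        ds.asl_series.voxel_size_mm)
        scaled.m0_series = ImageSeries(ds.m0_series.voxels * c,
                                       ds.m0_series.voxel_size_mm)
        (_, out), = quantify_dataset(scaled)
        assert np.array_equal(out.mask, ref.mask)
        assert np.allclose(out.values[out.mask], ref.values[ref.mask],
                           rtol=1e-12)


def test_cbf_monotone_in_deltam_and_m0():
    dm = np.full((2, 2, 1), 10.0)
    m0 = np.full((2, 2, 1), 1000.0)
    sc = pcasl_sidecar()
    base = quantify_cbf(dm, m0, sc).values
    assert np.all(quantify_cbf(dm * 1.1, m0, sc).values > base)
    assert np.all(quantify_cbf(dm, m0 * 1.1, sc).values < base)


def test_quantify_dataset_refuses_invalid_unless_forced(fixtures):
    ds = fixtures["asl005"][0].copy()
    del ds.asl_sidecar.entries["M0Type"]
    with pytest.raises(UnsupportedSchemeError):
        quantify_dataset(ds)


def test_multi_pld_yields_one_map_per_delay(noise_free):
    ds, _ = noise_free["asl004"]
    results = quantify_dataset(ds)
    plds = [p for p, _ in results]
    assert plds == sorted(set(example_plan("asl004").plds_s))
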