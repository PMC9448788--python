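"""Conversion-time mandates: intensity scaling and acquisition-order restore.

Two things must happen when raw scanner exports become BIDS data and both
are irreversible omissions if skipped: every intensity scale factor must be
applied to the voxel data (BIDS has no fields to carry latent slopes), and
volumes must be sorted back from scanner export order into acquisition
order.  This module exposes exactly those two transforms so any converter
front-end can comply; reading vendor DICOM archives is out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LengthMismatchError, NotAPermutationError, ZeroSlopeError
from .model import AslContext, ImageSeries


@dataclass(frozen=True)
class ScaleFactors:
    """DICOM-style linear intensity scaling: stored = raw * slope + intercept.

    ASL and M0 series may carry different factors (background suppression
    makes their signal levels differ markedly); apply per series.
    """

    slope: float
    intercept: float = 0.0

    def __post_init__(self):
        if self.slope == 0:
            raise ZeroSlopeError("scale slope must be non-zero")

    def inverse(self) -> "ScaleFactors":
        return ScaleFactors(1.0 / self.slope, -self.intercept / self.slope)


def apply_scaling(raw_series: ImageSeries, factors: ScaleFactors) -> ImageSeries:
    """Apply ``v -> v*slope + intercept`` voxelwise, in floating point."""
    scaled = raw_series.voxels * float(factors.slope) + float(factors.intercept)
    return ImageSeries(scaled, raw_series.voxel_size_mm)


def _check_permutation(order_map, n: int) -> list:
    order = [int(i) for i in order_map]
    if len(order) != n:
        raise LengthMismatchError(
            f"order map length {len(order)} != number of volumes {n}")
    if sorted(order) != list(range(n)):
        raise NotAPermutationError(f"{order} is not a permutation of 0..{n - 1}")
    return order


def sort_to_acquisition_order(series: ImageSeries,
                              context_export_order: AslContext,
                              order_map) -> tuple:
    """Reorder volumes (and their context rows) into acquisition order.

    ``order_map[i]`` is the acquisition index of the volume at export index
    ``i``; the context rows move jointly with the volumes so the type of each
    volume is unchanged by the move.
    """
    n = series.n_volumes
    if len(context_export_order) != n:
        raise LengthMismatchError(
            f"context has {len(context_export_order)} rows for {n} volumes")
    order = _check_permutation(order_map, n)

    if series.voxels.ndim == 3:
        return ImageSeries(series.voxels.copy(), series.voxel_size_mm), context_export_order

    sorted_vox = np.empty_like(series.voxels)
    sorted_types = [None] * n
    types = list(context_export_order)
    for export_idx, acq_idx in enumerate(order):
        sorted_vox[..., acq_idx] = series.voxels[..., export_idx]
        sorted_types[acq_idx] = types[export_idx]
    return (ImageSeries(sorted_vox, series.voxel_size_mm),
            AslContext(tuple(sorted_types)))
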