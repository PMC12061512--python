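"""Repeated-B-scan dynamic contrast (optical microangiography, OMAG).

The dynamic index of a voxel is the mean magnitude of the complex
difference between consecutive repeated B-scan frames,

    Id = (1 / (N - 1)) * sum_{t=1}^{N-1} |R(t+1) - R(t)|,

computed after a per-A-line bulk-motion phase correction.  With a ~10 ms
frame interval both capillary and fast flow decorrelate between frames, so
OMAG detects slow capillary flow well — at the price of strong projection
("tail") artifacts beneath large vessels.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    MODE_REPEATED_B,
    AngiogramVolume,
    FieldSeriesVolume,
    ValidationError,
)

__all__ = ["bulk_phase_correct", "omag_index"]

log = logging.getLogger(__name__)


def _require_repeated_b(series: FieldSeriesVolume) -> None:
    if series.protocol.mode != MODE_REPEATED_B:
        raise ValidationError(
            f"OMAG requires the repeated_B protocol, got {series.protocol.mode!r}")


def bulk_phase_correct(series: FieldSeriesVolume) -> FieldSeriesVolume:
    """Remove per-A-line bulk-motion phase between adjacent frames.

    For each adjacent frame pair and each (x, y) A-line, a single global
    phase is estimated as the argument of the depth-summed cross product
    ``sum_z conj(R(t)) R(t+1)`` and removed from frame t+1.  Corrections
    accumulate along t, so every frame ends up referenced to frame 0.
    Magnitudes are untouched; only inter-frame phase is rotated away.

    A-lines with zero cross-product energy receive no correction.
    """
    _require_repeated_b(series)
    R = series.data.copy()
    nt = R.shape[3]
    n_zero = 0
    for t in range(nt - 1):
        cross = np.sum(np.conj(R[..., t]) * R[..., t + 1], axis=0)  # (x, y)
        zero = cross == 0
        n_zero += int(zero.sum())
        phi = np.where(zero, 0.0, np.angle(cross))
        R[..., t + 1] = R[..., t + 1] * np.exp(-1j * phi)[None, :, :]
    if n_zero:
        log.warning("bulk_phase_correct: %d zero-energy A-line pairs left uncorrected", n_zero)
    return FieldSeriesVolume(data=R, pitch_um=series.pitch_um, protocol=series.protocol)


def omag_index(series: FieldSeriesVolume) -> AngiogramVolume:
    """Mean consecutive complex-difference magnitude per voxel."""
    _require_repeated_b(series)
    R = series.data
    n = R.shape[3]
    if n < 2:
        raise ValidationError("OMAG needs at least 2 repeats")
    diff = np.abs(np.diff(R, axis=3))
    index = diff.mean(axis=3)
    return AngiogramVolume(data=index, pitch_um=series.pitch_um, provenance="omag")
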