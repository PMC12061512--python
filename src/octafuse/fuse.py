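"""Merge the two contrast volumes through the large-vessel projection column.

Inside the 3-D column mask the brightness-matched adaptive g1 index is
used (tail artifacts suppressed, large-vessel lumens preserved); outside
it the OMAG index is passed through untouched, preserving its full
capillary sensitivity.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import AngiogramVolume, BinaryMask3D, ValidationError

__all__ = ["match_brightness", "merge"]

log = logging.getLogger(__name__)


def match_brightness(ag1_vol: AngiogramVolume, omag_vol: AngiogramVolume,
                     mask3d: BinaryMask3D, percentile: float = 99.0) -> float:
    """Scale factor matching the g1 subvolume brightness to OMAG's.

    Returns ``s = P_pct(omag inside mask) / P_pct(ag1 inside mask)`` over
    in-mask voxels.  An empty mask or a zero denominator yields ``s = 1``
    with a warning.
    """
    if ag1_vol.data.shape != omag_vol.data.shape or ag1_vol.data.shape != mask3d.data.shape:
        raise ValidationError("volumes and mask must share the (z, x, y) grid")
    if not (50 < percentile < 100):
        raise ValidationError(f"percentile must lie in (50, 100), got {percentile}")
    inside = mask3d.data
    if not inside.any():
        log.warning("match_brightness: empty mask, scale = 1")
        return 1.0
    denom = float(np.percentile(ag1_vol.data[inside], percentile))
    if denom == 0.0:
        log.warning("match_brightness: zero in-mask percentile of the g1 volume, scale = 1")
        return 1.0
    return float(np.percentile(omag_vol.data[inside], percentile)) / denom


def merge(omag_vol: AngiogramVolume, ag1_vol: AngiogramVolume,
          mask3d: BinaryMask3D, scale: float = 1.0,
          feather_vox: int = 0) -> AngiogramVolume:
    """Hard binary merge: ``scale * ag1`` inside the mask, OMAG outside.

    With ``feather_vox = 0`` (default) voxel provenance is exact — each
    output voxel equals one of its two sources.  ``feather_vox`` in {1, 2}
    applies a linear cross-fade over that many voxels inside the mask
    boundary, for rendering only.
    """
    if omag_vol.data.shape != ag1_vol.data.shape or omag_vol.data.shape != mask3d.data.shape:
        raise ValidationError("volumes and mask must share the (z, x, y) grid")
    if feather_vox == 0 or not mask3d.data.any() or mask3d.data.all():
        data = np.where(mask3d.data, scale * ag1_vol.data, omag_vol.data)
    else:
        depth = ndimage.distance_transform_edt(mask3d.data)
        w = np.clip(depth / (feather_vox + 1), 0.0, 1.0)  # 0 outside -> 1 deep inside
        data = w * (scale * ag1_vol.data) + (1.0 - w) * omag_vol.data
    return AngiogramVolume(data=np.maximum(data, 0.0), pitch_um=omag_vol.pitch_um,
                           provenance="fused")
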