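"""Axial registration and blending of multi-focal-depth volumes.

Successive acquisitions focused ~180 um apart share an axial overlap; the
offset of each deeper volume is found by maximizing the cosine similarity
between the overlapping slabs, and the stack is blended with a linear
ramp across each overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AngiogramVolume, ValidationError

__all__ = ["StitchResult", "best_z_offset", "blend_stack"]


@dataclass
class StitchResult:
    """Best axial alignment of volume B against volume A.

    ``z_offset``: volume B's slice 0 aligns to volume A's slice z_offset.
    ``profile``: cosine similarity per candidate offset (parallel arrays
    ``offsets`` / ``similarities``).
    """

    z_offset: int
    similarity: float
    offsets: np.ndarray
    similarities: np.ndarray


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def best_z_offset(volA: AngiogramVolume, volB: AngiogramVolume,
                  search: Sequence[int] | range | None = None) -> StitchResult:
    """Search integer z-offsets for the maximal-cosine overlap slab.

    Ties resolve to the smallest offset.  Offsets whose overlap slab has
    zero norm score 0.
    """
    if volA.data.shape[1:] != volB.data.shape[1:]:
        raise ValidationError("volumes must share the en-face (x, y) grid")
    nzA = volA.data.shape[0]
    nzB = volB.data.shape[0]
    if search is None:
        search = range(0, nzA)
    offsets = [int(k) for k in search]
    valid = [k for k in offsets if min(nzA, k + nzB) - max(k, 0) >= 1]
    if not valid:
        raise ValidationError("search range yields no overlapping slices")

    sims = np.empty(len(valid))
    for i, k in enumerate(valid):
        a0 = max(k, 0)
        a1 = min(nzA, k + nzB)
        a = volA.data[a0:a1].ravel()
        b = volB.data[a0 - k : a1 - k].ravel()
        sims[i] = _cosine(a, b)
    best = int(np.argmax(sims))  # argmax returns the first (smallest offset) tie
    return StitchResult(z_offset=valid[best], similarity=float(sims[best]),
                        offsets=np.asarray(valid), similarities=sims)


def blend_stack(vols: Sequence[AngiogramVolume], offsets: Sequence[int],
                hard_cut: bool = False) -> AngiogramVolume:
    """Blend volumes at the given absolute z-offsets into one stack.

    ``offsets[i]`` is the output slice of volume i's slice 0 (offsets[0]
    must be 0, offsets nondecreasing).  In each pairwise overlap the weight
    of the shallower data falls linearly 1 -> 0 across the overlap (or
    switches at the midpoint when ``hard_cut``).  A gap between successive
    volumes (negative implied overlap) is an error.
    """
    if len(vols) == 0:
        raise ValidationError("need at least one volume")
    if len(vols) != len(offsets):
        raise ValidationError("need one offset per volume")
    offsets = [int(k) for k in offsets]
    if offsets[0] != 0:
        raise ValidationError("offsets[0] must be 0")
    shape_xy = vols[0].data.shape[1:]
    for v in vols:
        if v.data.shape[1:] != shape_xy:
            raise ValidationError("volumes must share the en-face (x, y) grid")

    out = vols[0].data.astype(np.float64).copy()
    end = out.shape[0]
    for vol, off in zip(vols[1:], offsets[1:]):
        if off > end:
            raise ValidationError(f"offset {off} implies a gap (previous stack ends at {end})")
        if off < 0:
            raise ValidationError("offsets must be nonnegative (ordered shallow to deep)")
        nz = vol.data.shape[0]
        new_end = max(end, off + nz)
        grown = np.empty((new_end,) + shape_xy, dtype=np.float64)
        grown[:end] = out
        if off + nz > end:
            grown[end:] = vol.data[end - off :]
        overlap = min(end, off + nz) - off
        if overlap > 0:
            if overlap == 1:
                w_deep = np.array([0.5])
            else:
                w_deep = np.linspace(0.0, 1.0, overlap)
            if hard_cut:
                w_deep = (w_deep >= 0.5).astype(float)
            w = w_deep[:, None, None]
            grown[off : off + overlap] = ((1.0 - w) * out[off : off + overlap]
                                          + w * vol.data[:overlap])
        out = grown
        end = new_end
    return AngiogramVolume(data=out, pitch_um=vols[0].pitch_um,
                           provenance=vols[0].provenance)
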