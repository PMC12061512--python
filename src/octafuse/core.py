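"""Domain containers and run configuration.

Coordinate convention (global, shared by every module): arrays are indexed
``(z, x, y)`` — ``z`` axial depth increasing downward, ``x`` fast scan,
``y`` slow scan — with a trailing ``t`` axis for time series. Indices are
0-based and ranges half-open. Voxel pitch is given in micrometres per axis
in the same ``(z, x, y)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "MODE_REPEATED_A",
    "MODE_REPEATED_B",
    "PROVENANCES",
    "AcquisitionProtocol",
    "REPEATED_A_PROTOCOL",
    "REPEATED_B_PROTOCOL",
    "FieldSeriesVolume",
    "AngiogramVolume",
    "EnFaceImage",
    "BinaryMask2D",
    "BinaryMask3D",
    "PipelineConfig",
]


class ValidationError(ValueError):
    """An object or argument violates a structural invariant."""


class FormatError(ValueError):
    """A file is missing required datasets or attributes."""


MODE_REPEATED_A = "repeated_A"
MODE_REPEATED_B = "repeated_B"
_MODES = (MODE_REPEATED_A, MODE_REPEATED_B)

#: Legal provenance tags for an angiogram: which contrast engine produced it.
PROVENANCES = frozenset({"omag", "ag1", "fused", "oof"})


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of one acquisition protocol.

    ``repeated_A`` (M-mode): many A-scans back to back at one transverse
    position — finely sampled, short span.  ``repeated_B``: a handful of
    B-scan frames at the same slow-axis position — coarse sampling, long
    span.  ``dt_ms`` is the inter-sample interval in milliseconds.
    """

    mode: str
    n_repeats: int
    dt_ms: float

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if int(self.n_repeats) != self.n_repeats or self.n_repeats < 2:
            raise ValidationError(f"n_repeats must be an integer >= 2, got {self.n_repeats!r}")
        if not (self.dt_ms > 0):
            raise ValidationError(f"dt_ms must be > 0, got {self.dt_ms!r}")

    @property
    def observation_span_ms(self) -> float:
        """Time between the first and the last sample: ``(n_repeats - 1) * dt``."""
        return (self.n_repeats - 1) * self.dt_ms

    @property
    def acquisition_lapse_ms(self) -> float:
        """Total time budget of the protocol at one location: ``n_repeats * dt``.

        This counts the dwell of every sample, i.e. 50 A-lines at 76 kHz
        occupy ~0.66 ms and five B-scan frames at 10 ms occupy ~50 ms.
        """
        return self.n_repeats * self.dt_ms


#: M-mode default: 50 repeated A-scans at a 76 kHz A-line rate.
REPEATED_A_PROTOCOL = AcquisitionProtocol(MODE_REPEATED_A, 50, 1.0 / 76.0)
#: Repeated B-scan default: 5 frames, ~10 ms frame interval.
REPEATED_B_PROTOCOL = AcquisitionProtocol(MODE_REPEATED_B, 5, 10.0)


def _check_pitch(pitch_um: Sequence[float], ndim: int) -> tuple[float, ...]:
    pitch = tuple(float(p) for p in pitch_um)
    if len(pitch) != ndim:
        raise ValidationError(f"pitch_um must have {ndim} components, got {len(pitch)}")
    if any(p <= 0 for p in pitch):
        raise ValidationError(f"pitch_um components must be > 0, got {pitch}")
    return pitch


@dataclass
class FieldSeriesVolume:
    """Complex OCT field time series ``R(t)`` on a ``(z, x, y, t)`` grid."""

    data: np.ndarray
    pitch_um: tuple[float, float, float]
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"field data must be 4-D (z, x, y, t), got ndim={self.data.ndim}")
        if not np.iscomplexobj(self.data):
            raise ValidationError("field data must be complex")
        if self.data.shape[3] != self.protocol.n_repeats:
            raise ValidationError(
                f"t-axis length {self.data.shape[3]} does not match "
                f"protocol.n_repeats {self.protocol.n_repeats}"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("field data contains NaN/Inf")
        self.pitch_um = _check_pitch(self.pitch_um, 3)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class AngiogramVolume:
    """Nonnegative dynamic-contrast index ``Id`` on a ``(z, x, y)`` grid."""

    data: np.ndarray
    pitch_um: tuple[float, float, float]
    provenance: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"angiogram data must be 3-D (z, x, y), got ndim={self.data.ndim}")
        if np.iscomplexobj(self.data):
            raise ValidationError("angiogram data must be real")
        if not np.isfinite(self.data).all():
            raise ValidationError("angiogram data contains NaN/Inf")
        if (self.data < 0).any():
            raise ValidationError("angiogram data must be nonnegative")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"provenance must be one of {sorted(PROVENANCES)}, got {self.provenance!r}")
        self.pitch_um = _check_pitch(self.pitch_um, 3)


@dataclass
class EnFaceImage:
    """Nonnegative en-face image on the ``(x, y)`` grid."""

    data: np.ndarray
    pitch_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("en-face image must be 2-D (x, y)")
        self.pitch_um = _check_pitch(self.pitch_um, 2)


@dataclass
class BinaryMask2D:
    """En-face boolean mask, indexed ``(x, y)``."""

    data: np.ndarray
    pitch_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("2-D mask must be indexed (x, y)")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        self.pitch_um = _check_pitch(self.pitch_um, 2)


@dataclass
class BinaryMask3D:
    """Axial extrusion of a :class:`BinaryMask2D`: every column constant in z."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("3-D mask must be indexed (z, x, y)")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if self.data.shape[0] > 0 and (self.data != self.data[0]).any():
            raise ValidationError("3-D mask must be constant along z (axial extrusion)")


@dataclass
class PipelineConfig:
    """Tunable parameters of the full dual-acquisition pipeline.

    Parameters
    ----------
    diameter_threshold_um:
        Minimum en-face vessel diameter for the large-vessel mask; vessels
        at or above this diameter define the projection column inside which
        the g1-based index replaces OMAG. Default 20 um.
    oof_scales_um:
        Ascending radii ``r`` of the multiscale optimally-oriented-flux
        filter, in micrometres.
    ag1_max_lag:
        Largest autocorrelation lag computed (must stay below the number of
        repeats of the M-mode protocol).
    ag1_probe_lags:
        Number of lag-to-lag phase increments of g1 entering the
        phase-chaos statistic.
    ag1_chaos_threshold:
        Circular-variance threshold above which a voxel is treated as
        artifact-like and given the short decorrelation horizon.
    ag1_ntau_short / ag1_ntau_long:
        The two decorrelation horizons assigned by the adaptive rule.
    fusion_percentile:
        Percentile used to match the brightness of the g1 subvolume to the
        OMAG subvolume inside the large-vessel column.
    oof_sigma_factor:
        Gaussian-derivative smoothing sigma expressed as a fraction of the
        OOF scale radius.
    oof_whole_volume:
        If true, apply OOF to the whole fused volume instead of the
        capillary (outside-mask) compartment only.
    """

    diameter_threshold_um: float = 20.0
    oof_scales_um: tuple[float, ...] = (3.0, 4.5, 6.0, 9.0, 12.0)
    ag1_max_lag: int = 49
    ag1_probe_lags: int = 32
    ag1_chaos_threshold: float = 0.4
    ag1_ntau_short: int = 1
    ag1_ntau_long: int = 49
    fusion_percentile: float = 99.0
    fusion_feather_vox: int = 0
    oof_sigma_factor: float = 0.5
    oof_whole_volume: bool = False
    mask_close: bool = True
    mask_dilate_margin_px: int = 1
    mip_z_range: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.diameter_threshold_um > 0):
            raise ValidationError("diameter_threshold_um must be > 0")
        scales = tuple(float(s) for s in self.oof_scales_um)
        if len(scales) == 0:
            raise ValidationError("oof_scales_um must be nonempty")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValidationError(f"oof_scales_um must be strictly ascending, got {scales}")
        self.oof_scales_um = scales
        if self.ag1_max_lag < 1:
            raise ValidationError("ag1_max_lag must be >= 1")
        if not (0 < self.ag1_chaos_threshold < np.pi**2):
            raise ValidationError("ag1_chaos_threshold must lie in (0, pi^2)")
        if not (self.ag1_ntau_short < self.ag1_ntau_long <= self.ag1_max_lag):
            raise ValidationError("require ntau_short < ntau_long <= ag1_max_lag")
        if not (50 < self.fusion_percentile < 100):
            raise ValidationError("fusion_percentile must lie in (50, 100)")
        if not (self.oof_sigma_factor > 0):
            raise ValidationError("oof_sigma_factor must be > 0")

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
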