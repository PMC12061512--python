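"""Synthetic speckle-field phantom with per-voxel ground truth.

The phantom emulates the temporal physics that the two contrast engines
exploit, not the optics of image formation.  Each voxel carries a complex
field time series ``R(t) = S + A * D(t) + n(t)``:

* **static** tissue — a fixed circular-complex-Gaussian speckle draw ``S``
  (fully developed speckle), constant over time;
* **lumen** voxels (capillary or large vessel) — a unit-variance complex
  AR(1) process ``D(t)`` with lag-1 coefficient ``rho = exp(-dt / tau_c)``,
  i.e. a discretized Ornstein–Uhlenbeck field whose autocorrelation is
  exactly ``E[g1(tau)] = exp(-tau / tau_c)``.  Fast flow in large vessels
  means short ``tau_c`` (fast decorrelation); slow capillary flow means a
  long ``tau_c``.  A small deterministic Doppler-like phase drift is added
  so the g1 phase of true flow evolves smoothly;
* **tail** voxels — multiply-scattered light beneath a large vessel: the
  lumen model with the tail correlation time, an attenuated amplitude, and
  an additional *random-walk phase jitter* per time step.  Tails therefore
  decorrelate like large vessels but with chaotic instead of smooth phase —
  the property the adaptive decorrelation index uses to identify them;
* additive i.i.d. circular complex Gaussian detection noise everywhere.

Generation is fully deterministic given ``(spec, protocol, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AcquisitionProtocol,
    FieldSeriesVolume,
    ValidationError,
)

__all__ = [
    "LABEL_STATIC",
    "LABEL_CAPILLARY",
    "LABEL_LARGE",
    "LABEL_TAIL",
    "VesselSegment",
    "PhantomSpec",
    "TruthVolume",
    "rasterize_phantom",
    "simulate_field_series",
    "default_phantom_spec",
]

LABEL_STATIC = 0
LABEL_CAPILLARY = 1
LABEL_LARGE = 2
LABEL_TAIL = 3

#: radius (um) at and above which a segment counts as a large vessel
_LARGE_RADIUS_UM = 10.0


@dataclass(frozen=True)
class VesselSegment:
    """A straight cylindrical vessel segment.

    Endpoints are 3-D points in micrometres, ``(z, x, y)`` order.
    ``flow_class`` "large" requires radius >= 10 um (diameter >= 20 um),
    "capillary" requires radius < 10 um.
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_um: float
    flow_class: str
    tau_c_ms: float

    def __post_init__(self) -> None:
        if self.flow_class not in ("large", "capillary"):
            raise ValidationError(f"flow_class must be 'large' or 'capillary', got {self.flow_class!r}")
        if not (self.radius_um > 0):
            raise ValidationError("radius_um must be > 0")
        if not (self.tau_c_ms > 0):
            raise ValidationError("tau_c_ms must be > 0")
        if self.flow_class == "large" and self.radius_um < _LARGE_RADIUS_UM:
            raise ValidationError("large vessels require radius_um >= 10 (diameter >= 20 um)")
        if self.flow_class == "capillary" and self.radius_um >= _LARGE_RADIUS_UM:
            raise ValidationError("capillaries require radius_um < 10")


@dataclass
class PhantomSpec:
    """Declarative description of a vessel-tree phantom.

    Defaults reflect a desk-scale slab of mouse cortex: 3 um isotropic
    voxels (near the 3.7 um axial / 3.5 um lateral optical resolution),
    unit-amplitude static speckle, 5% additive noise, and a tail column
    extending 90 um beneath large-vessel lumens with 60% of the lumen
    amplitude and a strong (2 rad/step) chaotic phase jitter.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    pitch_um: tuple[float, float, float] = (3.0, 3.0, 3.0)
    segments: tuple[VesselSegment, ...] = ()
    static_amp: float = 1.0
    noise_sigma: float = 0.05
    tail_depth_um: float = 90.0
    tail_tau_c_ms: float = 0.05
    tail_phase_jitter_rad: float = 2.0
    tail_attenuation: float = 0.6
    lumen_drift_rad_per_step: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (self.tail_phase_jitter_rad > 0):
            raise ValidationError("tail_phase_jitter_rad must be > 0")
        if not (0 < self.tail_attenuation <= 1):
            raise ValidationError("tail_attenuation must lie in (0, 1]")
        if not (self.tail_tau_c_ms > 0):
            raise ValidationError("tail_tau_c_ms must be > 0")


@dataclass
class TruthVolume:
    """Per-voxel class labels and correlation times.

    ``label`` holds the ``LABEL_*`` codes on the ``(z, x, y)`` grid;
    ``tau_c_map`` holds the field correlation time in ms (``inf`` for
    static voxels, which never decorrelate).
    """

    label: np.ndarray
    tau_c_map: np.ndarray

    def class_mask(self, code: int) -> np.ndarray:
        return self.label == code


def _segment_distance(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                      p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Euclidean distance (um) from each voxel center to the segment p0-p1."""
    d = p1 - p0
    seg_len2 = float(d @ d)
    # projection parameter clamped to [0, 1]
    t = np.zeros_like(coords[0])
    if seg_len2 > 0:
        for ax in range(3):
            t += (coords[ax] - p0[ax]) * d[ax]
        t = np.clip(t / seg_len2, 0.0, 1.0)
    dist2 = np.zeros_like(t)
    for ax in range(3):
        delta = coords[ax] - (p0[ax] + t * d[ax])
        dist2 += delta * delta
    return np.sqrt(dist2)


def rasterize_phantom(spec: PhantomSpec) -> TruthVolume:
    """Label every voxel of the grid and assign correlation times.

    A voxel is a lumen voxel iff its center lies within ``radius_um`` of a
    segment axis; lumen labels override static.  Tail labels are assigned
    afterwards, strictly below the deepest large-lumen voxel of each
    en-face column and within ``tail_depth_um``, never overriding a lumen.
    """
    nz, nx, ny = spec.shape
    dz, dx, dy = spec.pitch_um
    extent = (nz * dz, nx * dx, ny * dy)
    zc = (np.arange(nz) + 0.5) * dz
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    coords = np.meshgrid(zc, xc, yc, indexing="ij")

    label = np.full(spec.shape, LABEL_STATIC, dtype=np.uint8)
    tau_c = np.full(spec.shape, np.inf, dtype=np.float32)

    # large segments rasterized last so they win where segments overlap
    ordered = sorted(spec.segments, key=lambda s: s.flow_class == "large")
    for seg in ordered:
        p0 = np.asarray(seg.p0, dtype=float)
        p1 = np.asarray(seg.p1, dtype=float)
        for p in (p0, p1):
            if (p < 0).any() or (p > np.asarray(extent)).any():
                raise ValidationError(f"segment endpoint {tuple(p)} outside grid extent {extent}")
        inside = _segment_distance(coords, p0, p1) <= seg.radius_um
        label[inside] = LABEL_LARGE if seg.flow_class == "large" else LABEL_CAPILLARY
        tau_c[inside] = seg.tau_c_ms

    # tail columns beneath large lumens
    n_tail_slices = math.ceil(spec.tail_depth_um / dz)
    large = label == LABEL_LARGE
    has_large = large.any(axis=0)
    if has_large.any() and n_tail_slices > 0:
        # deepest large-lumen z per column (0 where none; masked by has_large)
        zmax = np.where(has_large, (nz - 1) - np.argmax(large[::-1], axis=0), -1)
        zidx = np.arange(nz)[:, None, None]
        in_tail = (zidx > zmax[None]) & (zidx <= zmax[None] + n_tail_slices) & has_large[None]
        in_tail &= label == LABEL_STATIC
        label[in_tail] = LABEL_TAIL
        tau_c[in_tail] = spec.tail_tau_c_ms

    return TruthVolume(label=label, tau_c_map=tau_c)


def _complex_normal(rng: np.random.Generator, shape, sigma: float = 1.0) -> np.ndarray:
    """Circular complex Gaussian with total std ``sigma`` (var sigma^2)."""
    scale = sigma / np.sqrt(2.0)
    return (rng.standard_normal(shape, dtype=np.float32) * scale
            + 1j * rng.standard_normal(shape, dtype=np.float32) * scale).astype(np.complex64)


def simulate_field_series(truth: TruthVolume, spec: PhantomSpec,
                          protocol: AcquisitionProtocol,
                          seed: int | None = None) -> FieldSeriesVolume:
    """Draw one field-series realization of the phantom under a protocol.

    Identical ``(truth, spec, protocol, seed)`` give bit-identical output.
    When ``seed`` is None, ``spec.seed`` is used.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    nt = protocol.n_repeats
    dt = protocol.dt_ms
    shape = truth.label.shape
    R = np.zeros(shape + (nt,), dtype=np.complex64)

    # static speckle: one fixed draw per voxel, constant over t
    static = truth.label == LABEL_STATIC
    n_static = int(static.sum())
    if n_static:
        S = _complex_normal(rng, n_static, spec.static_amp)
        R[static] = S[:, None]

    # dynamic voxels: complex AR(1) with per-voxel rho
    dynamic = ~static
    n_dyn = int(dynamic.sum())
    if n_dyn:
        tau = truth.tau_c_map[dynamic].astype(np.float64)
        rho = np.exp(-dt / tau).astype(np.float32)
        innov_sigma = np.sqrt(1.0 - rho**2).astype(np.float32)
        D = np.empty((n_dyn, nt), dtype=np.complex64)
        D[:, 0] = _complex_normal(rng, n_dyn)
        for t in range(1, nt):
            D[:, t] = rho * D[:, t - 1] + innov_sigma * _complex_normal(rng, n_dyn)

        is_tail = truth.label[dynamic] == LABEL_TAIL
        amp = np.where(is_tail, spec.static_amp * spec.tail_attenuation,
                       spec.static_amp).astype(np.float32)

        # smooth Doppler-like drift on lumen voxels, chaotic random-walk
        # phase on tail voxels
        steps = np.arange(nt, dtype=np.float32)
        phase = np.where(is_tail[:, None], 0.0,
                         spec.lumen_drift_rad_per_step * steps[None, :]).astype(np.float32)
        n_tail = int(is_tail.sum())
        if n_tail:
            jitter = rng.normal(0.0, spec.tail_phase_jitter_rad,
                                size=(n_tail, nt)).astype(np.float32)
            jitter[:, 0] = 0.0
            phase[is_tail] += np.cumsum(jitter, axis=1)
        R[dynamic] = amp[:, None] * D * np.exp(1j * phase)

    if spec.noise_sigma > 0:
        R += _complex_normal(rng, shape + (nt,), spec.noise_sigma)

    return FieldSeriesVolume(data=R, pitch_um=spec.pitch_um, protocol=protocol)


def default_phantom_spec(seed: int = 0, shape: tuple[int, int, int] = (64, 128, 128),
                         pitch_um: tuple[float, float, float] = (3.0, 3.0, 3.0),
                         ) -> PhantomSpec:
    """The reference phantom: one 30 um-diameter pial vessel and four 8 um
    capillaries, one of which runs beneath the large vessel inside its
    projection column.

    Correlation times: 0.05 ms in the large vessel (fast flow, decorrelates
    within the M-mode span), 5 ms in capillaries (slow flow, barely
    decorrelates over the M-mode span but fully over the ~10 ms B-scan
    frame interval).
    """
    nz, nx, ny = shape
    dz, dx, dy = pitch_um
    z_ext, x_ext, y_ext = nz * dz, nx * dx, ny * dy
    x_mid = x_ext / 2

    # depths as fractions of the axial extent so smaller grids stay valid;
    # at the reference 64 x 128 x 128 / 3 um grid these are 45..150 um
    z_large = 0.234 * z_ext
    z_caps = (0.547 * z_ext, 0.469 * z_ext, 0.625 * z_ext, 0.781 * z_ext)
    eps = min(dx, dy) / 4  # keep endpoints strictly inside the grid extent
    segments = [
        # large pial vessel: along y, shallow
        VesselSegment((z_large, x_mid, eps), (z_large, x_mid, y_ext - eps),
                      radius_um=15.0, flow_class="large", tau_c_ms=0.05),
        # capillary directly beneath the large vessel, inside the tail column
        VesselSegment((z_caps[0], x_mid, eps), (z_caps[0], x_mid, y_ext - eps),
                      radius_um=4.0, flow_class="capillary", tau_c_ms=5.0),
        # three capillaries away from the large vessel
        VesselSegment((z_caps[1], x_ext * 0.2, eps), (z_caps[1], x_ext * 0.2, y_ext - eps),
                      radius_um=4.0, flow_class="capillary", tau_c_ms=5.0),
        VesselSegment((z_caps[2], x_ext * 0.8, eps), (z_caps[2], x_ext * 0.8, y_ext - eps),
                      radius_um=4.0, flow_class="capillary", tau_c_ms=5.0),
        VesselSegment((z_caps[3], eps, y_ext * 0.3), (z_caps[3], x_ext - eps, y_ext * 0.3),
                      radius_um=4.0, flow_class="capillary", tau_c_ms=5.0),
    ]
    return PhantomSpec(shape=shape, pitch_um=pitch_um, segments=tuple(segments),
                       seed=seed)
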