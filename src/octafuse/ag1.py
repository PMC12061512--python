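"""Repeated-A-scan adaptive decorrelation contrast (Ag1-OCTA).

From the M-mode field series of each voxel the normalized temporal
autocorrelation

    g1(tau) = <conj(R(t)) R(t + tau)>_t / <|R(t)|^2>_t

is estimated over lags 0..max_lag.  The dynamic index is the maximum
decorrelation of |g1| inside an adaptively selected lag horizon n_tau,

    Id = |g1(1)| - min_{1 <= tau <= n_tau} |g1(tau)|.

The horizon is what suppresses projection artifacts: tail voxels beneath
large vessels decorrelate as fast as true fast flow, but their g1 *phase*
walks chaotically instead of drifting smoothly.  Voxels whose g1 phase
increments have a high circular variance are assigned the short horizon
(n_tau = 1 makes Id exactly zero); phase-stable voxels keep the long
horizon and retain full flow contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    MODE_REPEATED_A,
    AngiogramVolume,
    FieldSeriesVolume,
    ValidationError,
)

__all__ = ["G1Field", "autocorrelation_g1", "select_ntau", "ag1_index"]

log = logging.getLogger(__name__)


@dataclass
class G1Field:
    """Per-voxel complex autocorrelation and its adaptive horizon.

    ``g1`` is indexed ``(z, x, y, tau)`` for tau = 0..max_lag.  After
    :func:`select_ntau`, ``ntau_map`` holds the selected horizon (>= 1) and
    ``chaos_map`` the circular variance of the g1 phase increments.
    ``zero_power`` flags voxels whose mean power was zero (their g1 is
    defined as 1 at lag 0 and 0 elsewhere).
    """

    g1: np.ndarray
    pitch_um: tuple[float, float, float]
    ntau_map: np.ndarray | None = None
    chaos_map: np.ndarray | None = None
    zero_power: np.ndarray | None = None

    @property
    def max_lag(self) -> int:
        return self.g1.shape[-1] - 1


def autocorrelation_g1(series: FieldSeriesVolume, max_lag: int | None = None) -> G1Field:
    """Estimate g1(tau) per voxel for lags 0..max_lag.

    The lag-tau average uses all ``n_repeats - tau`` available sample
    pairs; normalization is by the full-series mean power (lag-0), so
    ``g1(0) == 1`` exactly wherever power is nonzero.
    """
    if series.protocol.mode != MODE_REPEATED_A:
        raise ValidationError(
            f"g1 analysis requires the repeated_A protocol, got {series.protocol.mode!r}")
    nt = series.protocol.n_repeats
    if max_lag is None:
        max_lag = nt - 1
    if not (1 <= max_lag < nt):
        raise ValidationError(f"max_lag must lie in [1, n_repeats), got {max_lag}")

    R = series.data
    power = np.mean(np.abs(R) ** 2, axis=-1)
    zero = power == 0
    if zero.any():
        log.warning("autocorrelation_g1: %d zero-power voxels flagged", int(zero.sum()))
    safe_power = np.where(zero, 1.0, power)

    out_dtype = np.complex64 if R.dtype == np.complex64 else np.complex128
    g1 = np.empty(R.shape[:3] + (max_lag + 1,), dtype=out_dtype)
    g1[..., 0] = 1.0
    for tau in range(1, max_lag + 1):
        corr = np.mean(np.conj(R[..., : nt - tau]) * R[..., tau:], axis=-1)
        g1[..., tau] = corr / safe_power
    if zero.any():
        g1[zero, 1:] = 0.0
        g1[zero, 0] = 1.0
    return G1Field(g1=g1, pitch_um=series.pitch_um, zero_power=zero)


def select_ntau(g1field: G1Field, probe_lags: int = 32, chaos_threshold: float = 0.4,
                ntau_short: int = 1, ntau_long: int | None = None) -> G1Field:
    """Assign each voxel a decorrelation horizon from its g1 phase stability.

    The chaos statistic is the circular variance of the lag-to-lag phase
    increments ``dphi(tau) = arg g1(tau+1) - arg g1(tau)`` over
    tau = 1..probe_lags.  Smooth Doppler-like drift gives near-constant
    increments (variance ~ 0); artifact voxels whose g1 phase is noise give
    variance near 1.  Voxels above ``chaos_threshold`` get ``ntau_short``
    (default 1, forcing a zero index), the rest get ``ntau_long``.
    """
    max_lag = g1field.max_lag
    if ntau_long is None:
        ntau_long = max_lag
    if probe_lags + 1 > max_lag:
        raise ValidationError(f"probe_lags + 1 must be <= max_lag ({max_lag}), got {probe_lags}")
    if not (1 <= ntau_short < ntau_long <= max_lag):
        raise ValidationError("require 1 <= ntau_short < ntau_long <= max_lag")

    g1 = g1field.g1
    # phase increment between consecutive lags, tau = 1..probe_lags
    inc = g1[..., 2 : probe_lags + 2] * np.conj(g1[..., 1 : probe_lags + 1])
    phase = np.exp(1j * np.angle(inc))
    chaos = 1.0 - np.abs(np.mean(phase, axis=-1))
    ntau = np.where(chaos > chaos_threshold, ntau_short, ntau_long).astype(np.int16)
    return G1Field(g1=g1, pitch_um=g1field.pitch_um, ntau_map=ntau,
                   chaos_map=chaos.astype(np.float32), zero_power=g1field.zero_power)


def ag1_index(g1field: G1Field) -> AngiogramVolume:
    """Adaptive decorrelation index: ``|g1(1)| - min_{1..n_tau} |g1(tau)|``.

    Nonnegative by construction (the minimum includes tau = 1); exactly
    zero wherever n_tau = 1 — the mechanism of tail-artifact suppression.
    """
    if g1field.ntau_map is None:
        raise ValidationError("ntau_map is not filled; run select_ntau first")
    absg = np.abs(g1field.g1[..., 1:])  # lags 1..max_lag
    running_min = np.minimum.accumulate(absg, axis=-1)
    idx = (g1field.ntau_map.astype(np.int64) - 1)[..., None]
    min_to_ntau = np.take_along_axis(running_min, idx, axis=-1)[..., 0]
    index = absg[..., 0] - min_to_ntau
    # guard tiny negative rounding residue in float32
    np.maximum(index, 0.0, out=index)
    return AngiogramVolume(data=index, pitch_um=g1field.pitch_um, provenance="ag1")
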