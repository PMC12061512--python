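"""Phantom rasterization geometry and AR(1) field statistics."""

import math

import numpy as np
import pytest

from octafuse import (
    REPEATED_A_PROTOCOL,
    REPEATED_B_PROTOCOL,
    ValidationError,
)
from octafuse.ag1 import autocorrelation_g1
from octafuse.phantom import (
    LABEL_CAPILLARY,
    LABEL_LARGE,
    LABEL_STATIC,
    LABEL_TAIL,
    PhantomSpec,
    TruthVolume,
    VesselSegment,
    rasterize_phantom,
    simulate_field_series,
)


def uniform_truth(label: int, tau_c_ms: float, shape=(10, 10, 10)) -> TruthVolume:
    """A truth volume in which every voxel belongs to one class."""
    return TruthVolume(label=np.full(shape, label, dtype=np.uint8),
                       tau_c_map=np.full(shape, tau_c_ms, dtype=np.float32))


def ensemble_g1(series, tau: int) -> complex:
    """Ensemble autocorrelation across voxels: aggregate numerator over
    aggregate power.  This is the unbiased check of the process statistics
    (the per-voxel normalized estimator carries a ratio bias at long lags
    when the series barely decorrelates)."""
    R = series.data.reshape(-1, series.data.shape[-1]).astype(np.complex128)
    power = np.mean(np.abs(R) ** 2)
    num = np.mean(np.conj(R[:, : R.shape[1] - tau]) * R[:, tau:])
    return num / power


class TestSegmentValidation:
    def test_large_requires_20um_diameter(self):
        with pytest.raises(ValidationError):
            VesselSegment((0, 0, 0), (0, 0, 30), radius_um=8, flow_class="large", tau_c_ms=0.05)

    def test_capillary_requires_sub_20um_diameter(self):
        with pytest.raises(ValidationError):
            VesselSegment((0, 0, 0), (0, 0, 30), radius_um=12, flow_class="capillary", tau_c_ms=5)


class TestRasterize:
    def test_empty_segments_all_static(self):
        truth = rasterize_phantom(PhantomSpec(shape=(8, 8, 8)))
        assert (truth.label == LABEL_STATIC).all()
        assert np.isinf(truth.tau_c_map).all()

    def test_tail_column_beneath_large_vessel(self):
        """A transverse large vessel grows a tail column spanning
        ceil(tail_depth / dz) slices directly beneath its lumen."""
        spec = PhantomSpec(
            shape=(40, 32, 32), pitch_um=(3, 3, 3), tail_depth_um=30.0,
            segments=(VesselSegment((30, 48, 1), (30, 48, 95), radius_um=15,
                                    flow_class="large", tau_c_ms=0.05),),
        )
        truth = rasterize_phantom(spec)
        large = truth.label == LABEL_LARGE
        tail = truth.label == LABEL_TAIL
        assert tail.any()
        # tails only in columns that contain large lumen
        assert not (tail.any(axis=0) & ~large.any(axis=0)).any()
        # in each such column the tail occupies exactly ceil(30/3)=10 slices
        # right beneath the deepest lumen voxel (depth 40*3=120 um suffices)
        n_expected = math.ceil(spec.tail_depth_um / 3.0)
        for x, y in zip(*np.nonzero(large.any(axis=0))):
            zmax = np.nonzero(large[:, x, y])[0].max()
            ztail = np.nonzero(tail[:, x, y])[0]
            assert ztail.size == n_expected
            assert ztail.min() == zmax + 1
            assert ztail.max() == zmax + n_expected

    def test_capillary_grows_no_tail(self):
        spec = PhantomSpec(
            shape=(20, 16, 16), pitch_um=(3, 3, 3),
            segments=(VesselSegment((15, 24, 1), (15, 24, 47), radius_um=4,
                                    flow_class="capillary", tau_c_ms=5.0),),
        )
        truth = rasterize_phantom(spec)
        assert (truth.label == LABEL_CAPILLARY).any()
        assert not (truth.label == LABEL_TAIL).any()

    def test_tail_never_overrides_lumen(self, small_truth):
        """In the reference geometry a capillary crosses the tail zone and
        keeps its lumen label."""
        assert (small_truth.label == LABEL_CAPILLARY).any()
        assert (small_truth.label == LABEL_TAIL).any()

    def test_segment_outside_grid_rejected(self):
        spec = PhantomSpec(
            shape=(8, 8, 8), pitch_um=(3, 3, 3),
            segments=(VesselSegment((12, 12, -5), (12, 12, 12), radius_um=4,
                                    flow_class="capillary", tau_c_ms=5.0),),
        )
        with pytest.raises(ValidationError):
            rasterize_phantom(spec)


class TestFieldStatistics:
    def test_noise_free_static_voxels_are_constant(self):
        truth = uniform_truth(LABEL_STATIC, np.inf, shape=(4, 4, 4))
        spec = PhantomSpec(shape=(4, 4, 4), noise_sigma=0.0)
        series = simulate_field_series(truth, spec, REPEATED_B_PROTOCOL, seed=3)
        assert np.all(series.data == series.data[..., :1])
        assert (np.abs(series.data[..., 0]) > 0).any()

    @pytest.mark.parametrize("tau_c_ms,lag,label", [
        (5.0, 49, LABEL_CAPILLARY),   # slow flow: |g1| ~ exp(-0.645/5) = 0.879
        (0.05, 10, LABEL_LARGE),      # fast flow: |g1| ~ exp(-0.132/0.05) = 0.072
    ])
    def test_ar1_matches_exponential_autocorrelation(self, tau_c_ms, lag, label):
        """Ensemble-mean g1 of noise-free lumen voxels reproduces the
        closed form exp(-tau / tau_c) within 0.02 at 1000 voxels."""
        truth = uniform_truth(label, tau_c_ms)
        spec = PhantomSpec(shape=(10, 10, 10), noise_sigma=0.0)
        series = simulate_field_series(truth, spec, REPEATED_A_PROTOCOL, seed=7)
        # the deterministic Doppler drift is a common phase: it drops out of
        # the magnitude of the ensemble g1
        for tau in (1, lag):
            expected = np.exp(-tau * REPEATED_A_PROTOCOL.dt_ms / tau_c_ms)
            assert abs(ensemble_g1(series, tau)) == pytest.approx(expected, abs=0.02)

    def test_repeated_b_decorrelates_both_flow_classes(self):
        """At a 10 ms frame interval both capillary and large-vessel voxels
        fall below |g1(1 frame)| = 0.15: the long-span protocol sees all flow."""
        for tau_c in (5.0, 0.05):
            truth = uniform_truth(LABEL_CAPILLARY if tau_c == 5.0 else LABEL_LARGE, tau_c)
            spec = PhantomSpec(shape=(10, 10, 10), noise_sigma=0.0)
            series = simulate_field_series(truth, spec, REPEATED_B_PROTOCOL, seed=5)
            R = series.data
            corr = np.mean(np.conj(R[..., :-1]) * R[..., 1:], axis=-1)
            power = np.mean(np.abs(R) ** 2, axis=-1)
            g1_1 = abs(corr.mean() / power.mean())
            assert g1_1 < 0.15

    def test_repeated_a_separates_flow_classes(self):
        """Over the 0.645 ms M-mode span capillaries barely decorrelate
        (|g1| > 0.85 at every lag) while large vessels decorrelate fully
        (|g1| < 0.1 at the last lag): the weak-capillary premise."""
        spec = PhantomSpec(shape=(10, 10, 10), noise_sigma=0.0)
        cap = simulate_field_series(uniform_truth(LABEL_CAPILLARY, 5.0), spec,
                                    REPEATED_A_PROTOCOL, seed=8)
        for tau in range(1, 50):
            assert abs(ensemble_g1(cap, tau)) > 0.85

        large = simulate_field_series(uniform_truth(LABEL_LARGE, 0.05), spec,
                                      REPEATED_A_PROTOCOL, seed=9)
        assert abs(ensemble_g1(large, 49)) < 0.1

    def test_determinism(self, small_truth, small_spec):
        a = simulate_field_series(small_truth, small_spec, REPEATED_B_PROTOCOL, seed=42)
        b = simulate_field_series(small_truth, small_spec, REPEATED_B_PROTOCOL, seed=42)
        c = simulate_field_series(small_truth, small_spec, REPEATED_B_PROTOCOL, seed=43)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_tail_amplitude_attenuated(self):
        """Tail voxels carry tail_attenuation times the lumen amplitude."""
        spec = PhantomSpec(shape=(10, 10, 10), noise_sigma=0.0, tail_attenuation=0.5)
        t_tail = uniform_truth(LABEL_TAIL, spec.tail_tau_c_ms)
        t_large = uniform_truth(LABEL_LARGE, spec.tail_tau_c_ms)
        p_tail = np.mean(np.abs(simulate_field_series(t_tail, spec, REPEATED_A_PROTOCOL, 1).data) ** 2)
        p_large = np.mean(np.abs(simulate_field_series(t_large, spec, REPEATED_A_PROTOCOL, 1).data) ** 2)
        assert p_tail / p_large == pytest.approx(0.25, rel=0.1)
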