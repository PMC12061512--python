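"""Shared fixtures: small seeded phantoms and field-series builders."""

from __future__ import annotations

import numpy as np
import pytest

from octafuse import (
    REPEATED_A_PROTOCOL,
    REPEATED_B_PROTOCOL,
    AcquisitionProtocol,
    FieldSeriesVolume,
    PipelineConfig,
)
from octafuse.phantom import (
    default_phantom_spec,
    rasterize_phantom,
    simulate_field_series,
)
from octafuse.pipeline import run_pipeline


def make_series(data: np.ndarray, mode: str = "repeated_B",
                dt_ms: float | None = None,
                pitch_um=(3.0, 3.0, 3.0)) -> FieldSeriesVolume:
    """Wrap a raw (z, x, y, t) complex array in a validated series."""
    if dt_ms is None:
        dt_ms = 10.0 if mode == "repeated_B" else 1.0 / 76.0
    protocol = AcquisitionProtocol(mode, data.shape[3], dt_ms)
    return FieldSeriesVolume(data=data, pitch_um=pitch_um, protocol=protocol)


@pytest.fixture(scope="session")
def small_spec():
    """A 32 x 64 x 64 instance of the reference phantom geometry."""
    return default_phantom_spec(seed=11, shape=(32, 64, 64))


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return rasterize_phantom(small_spec)


@pytest.fixture(scope="session")
def small_series_a(small_spec, small_truth):
    return simulate_field_series(small_truth, small_spec, REPEATED_A_PROTOCOL, seed=12)


@pytest.fixture(scope="session")
def small_series_b(small_spec, small_truth):
    return simulate_field_series(small_truth, small_spec, REPEATED_B_PROTOCOL, seed=13)


@pytest.fixture(scope="session")
def small_run(small_spec):
    """Full pipeline on the small phantom."""
    return run_pipeline(PipelineConfig(seed=11), phantom_spec=small_spec)
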