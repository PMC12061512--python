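"""Compute the two dynamic-contrast indices on a small phantom.

Builds a 32 x 64 x 64 voxel phantom (one 30 um pial vessel, four 8 um
capillaries), simulates both acquisition protocols, and prints the mean
contrast per ground-truth voxel class for each engine.  OMAG should light
up capillaries AND tail artifacts; the adaptive g1 index should null the
tails while keeping the large vessel.
"""

import numpy as np

from octafuse import (
    REPEATED_A_PROTOCOL,
    REPEATED_B_PROTOCOL,
    ag1_index,
    autocorrelation_g1,
    bulk_phase_correct,
    default_phantom_spec,
    omag_index,
    rasterize_phantom,
    select_ntau,
    simulate_field_series,
)
from octafuse.phantom import LABEL_CAPILLARY, LABEL_LARGE, LABEL_STATIC, LABEL_TAIL

spec = default_phantom_spec(seed=1, shape=(32, 64, 64))
truth = rasterize_phantom(spec)
series_b = simulate_field_series(truth, spec, REPEATED_B_PROTOCOL, seed=1)
series_a = simulate_field_series(truth, spec, REPEATED_A_PROTOCOL, seed=2)

omag = omag_index(bulk_phase_correct(series_b))
g1f = select_ntau(autocorrelation_g1(series_a, max_lag=49))
ag1 = ag1_index(g1f)

print(f"{'class':<10} {'OMAG Id':>9} {'Ag1 Id':>9}")
for name, code in [("static", LABEL_STATIC), ("capillary", LABEL_CAPILLARY),
                   ("large", LABEL_LARGE), ("tail", LABEL_TAIL)]:
    m = truth.label == code
    print(f"{name:<10} {omag.data[m].mean():>9.4f} {ag1.data[m].mean():>9.4f}")

print()
print("OMAG gives tails nearly large-vessel contrast (the projection "
      "artifact); the adaptive g1 index drives them toward zero while "
      "keeping the large vessel bright.")
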