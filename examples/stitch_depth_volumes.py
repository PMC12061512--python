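"""Register and blend two overlapping focal-depth volumes.

Fakes two acquisitions of the same textured volume offset by 20 slices
with independent 10% noise, recovers the axial offset by cosine
similarity, and blends them with a linear ramp.
"""

import numpy as np

from octafuse import AngiogramVolume, best_z_offset, blend_stack

rng = np.random.default_rng(3)
base = rng.random((80, 32, 32))
sig = base.std()
volA = AngiogramVolume(data=np.abs(base + rng.normal(0, 0.1 * sig, base.shape)),
                       pitch_um=(3, 3, 3), provenance="omag")
volB = AngiogramVolume(data=np.abs(base[20:] + rng.normal(0, 0.1 * sig, (60, 32, 32))),
                       pitch_um=(3, 3, 3), provenance="omag")

res = best_z_offset(volA, volB)
stacked = blend_stack([volA, volB], [0, res.z_offset])

print(f"true offset:      20 slices")
print(f"recovered offset: {res.z_offset} slices (cosine similarity {res.similarity:.4f})")
print(f"stacked depth:    {stacked.data.shape[0]} slices "
      f"(= 20 offset + 60 deep-volume slices)")
print()
print("The similarity profile peaks at the true overlap even at 10% noise; "
      "the blend ramps the shallow volume's weight 1 -> 0 across the "
      "60-slice overlap so no seam appears.")
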