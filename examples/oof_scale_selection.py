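"""Multiscale OOF response of synthetic bright tubes.

Builds two bright cylinders (radius 4 um and 8 um) in one volume and
shows that the optimally-oriented-flux response selects the scale
matching each radius, the mechanism behind capillary enhancement.
"""

import numpy as np

from octafuse import AngiogramVolume
from octafuse.oof import OOFParams, oof_response

shape = (40, 80, 40)
idx = np.indices(shape, dtype=float) + 0.5
thin = ((idx[0] - 20) ** 2 + (idx[1] - 20) ** 2) <= 4.0**2
thick = ((idx[0] - 20) ** 2 + (idx[1] - 60) ** 2) <= 8.0**2
vol = AngiogramVolume(data=(thin | thick).astype(float), pitch_um=(1, 1, 1),
                      provenance="fused")

params = OOFParams(scales_um=(3.0, 4.5, 6.0, 9.0, 12.0))
resp, argmax = oof_response(vol, params, return_scale_argmax=True)

print(f"scales searched (um):      {params.scales_um}")
print(f"radius-4 tube on-axis:     response {resp.data[20, 20, 10:30].mean():.4f}, "
      f"selected scale {np.median(argmax[20, 20, 10:30]):.1f} um")
print(f"radius-8 tube on-axis:     response {resp.data[20, 60, 10:30].mean():.4f}, "
      f"selected scale {np.median(argmax[20, 60, 10:30]):.1f} um")
print(f"background response:       {resp.data[5, 40, 10:30].max():.6f}")
print()
print("Each tube responds strongest at a scale near its own radius and the "
      "response is clamped to zero in flat background, so tubular vessels "
      "are enhanced without amplifying noise.")
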