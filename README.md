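# octafuse

Dual acquisition scheme 3D OCT angiography: suppress projection ("tail")
artifacts beneath large pial vessels while keeping full capillary
sensitivity, in one fused volume.

OCT angiography images blood vessels through the temporal fluctuation of
the complex OCT field R(t) caused by moving red blood cells. The two
standard acquisition schemes fail in complementary ways:

* **Repeated B-scan (OMAG)** — frames ~10 ms apart; the index
  `Id = (1/(N-1)) Σ_t |R(t+1) − R(t)|` detects even slow capillary flow,
  but multiply scattered photons project large-vessel dynamics into the
  voxels beneath them (tail artifacts).
* **Repeated A-scan (M-mode, adaptive g1)** — 50 A-lines at 76 kHz; from
  the field autocorrelation `g1(τ) = ⟨R*(t)R(t+τ)⟩_t / ⟨|R|²⟩_t` the index
  `Id = |g1(1)| − min_{τ≤n_τ} |g1(τ)|` is computed with a per-voxel horizon
  n_τ chosen from the g1 *phase* statistics: chaotic-phase (artifact)
  voxels get n_τ = 1, which forces Id = 0; smooth-drift (flow) voxels keep
  the full horizon. Tails are nulled — but capillaries barely decorrelate
  in the ~0.66 ms span and are nearly invisible.

`octafuse` computes both indices over the same field of view, builds a
large-vessel mask (≥ 20 µm en-face diameter) from the OMAG MIP, extrudes
it into the 3-D projection column, uses the brightness-matched g1 index
inside the column and OMAG outside, and finally enhances the capillary
compartment with a multiscale optimally-oriented-flux filter
`P = max_r max(−λ₁(r)/r², 0)` on the Gaussian-derivative Hessian.

A speckle-field phantom with per-voxel ground truth (static / capillary /
large vessel / tail classes, AR(1) field dynamics with exponential
autocorrelation) makes the whole pipeline testable without hardware.

## Worked example

```bash
python examples/dual_contrast.py
```

builds a 32 × 64 × 64 phantom (one 30 µm pial vessel, four 8 µm
capillaries), simulates both protocols and prints the mean contrast per
ground-truth class:

```
class        OMAG Id    Ag1 Id
static        0.0710    0.0460
capillary     1.1276    0.2285
large         1.1468    0.6850
tail          0.7264    0.0143
```

Reading the table: OMAG sees capillaries as brightly as large vessels —
but the tail voxels, which contain no flow, come out at ~63% of the
large-vessel contrast (the projection artifact). The adaptive g1 index
crushes the tails to ~2% of its large-vessel level, at the price of weak
capillary contrast. The fusion takes each engine where it is right:

```bash
python examples/full_pipeline.py
```

```
brightness scale (Ag1 -> OMAG):  2.216
tail_suppression_ratio:          0.0418
capillary Dice  fused / ag1-only / omag-only: 0.235 / 0.075 / 0.125
large-vessel Dice fused / omag-only:          0.916 / 0.451
mask column recall / precision:  1.000 / 0.989
```

The fused volume keeps tails at ~4% of their OMAG level while detecting
capillaries better than the g1-only method and large vessels better than
OMAG (whose large-vessel detection drowns in its own tail artifacts).
`examples/oof_scale_selection.py` and `examples/stitch_depth_volumes.py`
demonstrate the OOF scale selectivity and the cosine-similarity axial
stitching of multi-focal-depth volumes.

There is also a thin CLI mirroring the library (`octafuse phantom`,
`omag`, `ag1`, `mask`, `fuse`, `oof`, `stitch`, `run`) operating on HDF5
field containers and multi-page float32 TIFF stacks.

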