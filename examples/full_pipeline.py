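"""Run the complete dual-acquisition pipeline on the reference phantom.

Simulates both protocols over a 32 x 64 x 64 voxel vessel geometry, runs
OMAG + adaptive g1 contrast, builds the 20 um large-vessel projection
mask, fuses the two volumes and OOF-enhances the capillary compartment,
then prints the ground-truth evaluation report.
"""

from octafuse import PipelineConfig, default_phantom_spec, run_pipeline

spec = default_phantom_spec(seed=7, shape=(32, 64, 64))
result = run_pipeline(PipelineConfig(seed=7), phantom_spec=spec, outdir="scratch/pipeline_out")

r = result.report
print(f"brightness scale (Ag1 -> OMAG):  {result.scale:.3f}")
print(f"tail_suppression_ratio:          {r.tail_suppression_ratio:.4f}")
print(f"capillary Dice  fused / ag1-only / omag-only: "
      f"{r.capillary_dice:.3f} / {r.capillary_dice_ag1:.3f} / {r.capillary_dice_omag:.3f}")
print(f"large-vessel Dice fused / omag-only:          "
      f"{r.large_vessel_dice:.3f} / {r.large_vessel_dice_omag:.3f}")
print(f"mask column recall / precision:  {r.mask_column_recall:.3f} / {r.mask_column_precision:.3f}")
print()
print("tail_suppression_ratio is the mean fused contrast over true tail "
      "voxels divided by the mean OMAG contrast there: values well below 1 "
      "mean the projection artifact is suppressed.  The Dice rows show the "
      "fusion keeping OMAG's capillary detection while beating OMAG under "
      "the large vessel.  TIFF volumes are in scratch/pipeline_out/.")
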