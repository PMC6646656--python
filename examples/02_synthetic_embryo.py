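"""Generate a synthetic 2-cell embryo and recover it by segmentation.

The generator is the package's stand-in for confocal stacks of fixed,
stained embryos: red encodes the embryo envelope (actin), blue the
chromatin (Hoechst), green the nuclei. Segmenting its own noisy render
must give back the ground-truth masks — that closes the loop the real
image-processing chain relies on.
"""

import embryodose as ed

spec = ed.EmbryoGeometrySpec()  # calibrated defaults
masks = ed.make_embryo_geometry(spec)
print(f"voxel grid {masks.shape} at {masks.voxel_pitch} µm pitch")
for comp in ("embryo", "ab_nucleus", "p1_nucleus", "chromatin"):
    v = masks.volume_um3(comp)
    print(f"  {comp:12s} {v:9.1f} µm³  ({v * 1e-15:.2e} kg at water density)")

stack = ed.render_stack(masks, snr=10, seed=0)
print("\nrendered 3-channel stack at SNR 10; segmenting it back:")
for ch, truth in (("red", masks.embryo_mask),
                  ("blue", masks.chromatin_mask)):
    rec = ed.segment_channel(stack, ch)
    dice = ed.mask_agreement(rec, truth)
    print(f"  {ch}: Dice vs ground truth = {dice:.4f}")
print("Dice ~1.0 means the threshold chain recovers the phantom geometry "
      "essentially voxel-perfectly at this noise level.")
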