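"""Simulate a Landsat-like scene with defoliated patches and segment it.

The generator plants irregular infested patches (raised green/red
reflectance, depressed NIR/SWIR, rougher texture) in a healthy broadleaf
background.  Multiresolution region merging then grows image objects
until any further merge would raise heterogeneity past scale^2.
"""

import geodefol as gd

scene, labels, forest_type = gd.generate_scene(gd.SceneSpec(n_patches=10, seed=7))
print(f"scene: {scene.shape[0]}x{scene.shape[1]} px, bands {scene.band_names}")
print(f"truly infested pixels: {100 * labels.mean():.1f}%")

for scale in (0.5, 1.0, 2.0):
    seg = gd.segment(scene, gd.SegmentationConfig(scale=scale))
    print(f"scale {scale:>4}: {seg.n_objects:5d} objects")

# larger scale -> coarser objects: the counts above shrink monotonically.
# At scale 1.0 objects are patch-sized, a good unit for classification.
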