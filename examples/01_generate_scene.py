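"""Generate one synthetic darkfield frame and inspect its ground truth.

The generator emulates a darkfield image of unstained blood spiked with
tumor cells: near-black background, ~150 small bright blood cells on a
512 x 512 canvas, a few large speckled tumor cells, and an artifact halo.
"""

from ctcdf import SceneParams, generate_scene, label_components

image, mask, objects = generate_scene(SceneParams(n_tumor=4, artifact_halos=1, seed=7))

tumors = [o for o in objects if o.kind == "tumor"]
blood = [o for o in objects if o.kind == "blood"]
components = label_components(mask)

print(f"frame: {image.height} x {image.width}, background median "
      f"{int(__import__('numpy').median(image.pixels))}")
print(f"tumor cells: {len(tumors)}, mean diameter "
      f"{2 * sum(o.radius for o in tumors) / len(tumors):.1f} px")
print(f"blood cells: {len(blood)}")
print(f"ground-truth components: {len(components)}, areas "
      f"{[c.pixel_count for c in components]}")
# One mask component per tumor cell: the mask is true exactly on tumor
# pixels, which is what the pixel classifier learns to reproduce.
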