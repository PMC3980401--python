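"""Segment a synthetic skin-tissue image into visually disjoint regions.

Builds one layered image, runs Normalized-Cut segmentation at several
region counts, and prints the region sizes plus each region's bounding
rectangle.  More regions resolve finer inner structure of the tissue.
"""

from skinmil import SyntheticSpec, generate_images, segment_hierarchy

spec = SyntheticSpec(n_images=1, n_terms=4, noise_sd=0.02, seed=7)
(image,), truth = generate_images(spec)
print(f"image {image.id}: {image.height}x{image.width} px, "
      f"terms present: {[t for t, _ in truth.patch_map[image.id]]}")

for p, regions in segment_hierarchy(image, [6, 8, 10, 12]).items():
    sizes = sorted(r.n_pixels for r in regions)
    print(f"\np = {p:2d} regions, pixel counts: {sizes}")
    for k, reg in enumerate(sorted(regions, key=lambda r: -r.n_pixels)[:3]):
        h, w = reg.mask.shape
        print(f"  largest #{k}: {reg.n_pixels} px in a {h}x{w} covering rectangle "
              f"({reg.mask.mean():.0%} region, rest black padding)")

# Every pixel belongs to exactly one region at each granularity; the sizes
# show the three tissue bands splitting first, then the embedded patches.
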