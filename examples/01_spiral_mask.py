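"""Build an Ulam spiral and its Sophie Germain prime mask.

The mask is the feature-sampling template: within every image patch, only
the pixels at these coordinates are read as features.
"""

from ulameeg import sg_count, sg_mask, ulam_spiral

spiral = ulam_spiral(9)
print("9 x 9 Ulam spiral (1 at center, counter-clockwise):")
for row in spiral.grid:
    print(" ".join(f"{v:2d}" for v in row))

mask = sg_mask(9)
print(f"\nSophie Germain primes <= 81: {list(mask.values)}")
print(f"their (row, col) cells:      {list(mask.coords)}")
print(f"\nsg_count(15) = {sg_count(15)} -> with 19 channels and 225 patches "
      f"per 225x225 image: 19 * 225 * 15 = {19 * 225 * 15} features/segment")
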