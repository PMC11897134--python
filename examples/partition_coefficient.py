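"""Measure a fluorescence partition coefficient K = F_droplet / F_background.

Generates a synthetic confocal droplet field whose true K is 781 (a strongly
enriched hydrophobic dye) at signal-to-noise 10, segments the droplets by
Otsu thresholding, and measures K back.  Values far above 1 mean the guest
molecule is concentrated inside the condensed phase.
"""

from phasekit import gen_partition_image, partition_coefficient, segment_droplets

K_TRUE = 781.0
image, _ = gen_partition_image(
    K_TRUE, n_droplets=8, radius_px=(6, 18),
    background_level=80.0, noise_sd=8.0, image_shape=(256, 256), seed=11,
)
mask = segment_droplets(image)
result = partition_coefficient(image, mask)

print(f"segmented droplets : {result.n_droplets}")
print(f"F_droplet (mean)   : {result.f_droplet:.1f}")
print(f"F_background (med) : {result.f_background:.1f}")
print(f"K measured         : {result.k_global:.0f}   (true {K_TRUE:.0f}, "
      f"error {100 * abs(result.k_global - K_TRUE) / K_TRUE:.1f}%)")
print("K >> 1: the dye partitions strongly into the droplets.")
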