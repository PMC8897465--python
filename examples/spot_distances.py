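"""Detect 3D spots and measure FISH probe-pair distances.

Plants Gaussian spots in a noisy 3D stack, detects them with the LoG +
relative-threshold detector, then builds a two-channel pair with a
known physical offset and measures mutual-nearest-neighbor distances
respecting the anisotropic voxel size.
"""

import numpy as np

from mitobook import imaging, synthetic

stack, truth = synthetic.gen_image_stack(
    shape=(30, 128, 128), n_spots=50, peak_intensity=100.0, noise_sd=10.0,
    seed=1,
)
spots = imaging.detect_spots(stack, log_sigma=1.0, thr=5.0)
print(f"detected {len(spots)} spots (50 planted, SNR 10)")

# second channel: same loci shifted by (1, 2, 2) voxels = 0.42 um
base = truth.ground_truth["centers"][:20]
offset = np.array([1.0, 2.0, 2.0])
chan_a, _ = synthetic.gen_image_stack(centers=base, noise_sd=0.0,
                                      shape=(30, 128, 128), seed=1)
chan_b, _ = synthetic.gen_image_stack(centers=base + offset, noise_sd=0.0,
                                      shape=(30, 128, 128), seed=1)
pairs = imaging.mutual_nearest_pairs(
    imaging.detect_spots(chan_a, 1.0, 3.0),
    imaging.detect_spots(chan_b, 1.0, 3.0),
    max_dist=1.0,  # distances beyond 1 um are considered aberrant
)
dists = [d for _, _, d in pairs]
print(f"{len(pairs)} mutual-nearest pairs, median distance "
      f"{np.median(dists):.3f} um")
print("expected from planted offset:",
      round(float(np.sqrt((0.3 * 1) ** 2 + (0.1 * 2) ** 2 + (0.1 * 2) ** 2)), 3),
      "um")
# z contributes with its own (coarser) voxel size - the measured
# distance is physical, not pixelic.
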