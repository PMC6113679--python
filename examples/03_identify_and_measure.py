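"""Pixel identification and particle analysis of a synthetic imaging scene.

Places particles of known polymers on a 64 x 64 filter image (11-um pixels),
adds noise, identifies every pixel with the dual-correlation agreement rule,
and derives particle counts, sizes, and composition.
"""

import numpy as np

from addftir import (
    ParticleSpec,
    SceneSpec,
    composition_summary,
    find_particles,
    identify_pixels,
    size_histogram,
    synth_cube,
    synth_library,
    validate_against_truth,
)

lib = synth_library(5, seed=1)
particles = tuple(
    ParticleSpec(pid, pos, "rect", size)
    for pid, pos, size in [
        ("polymer_01", (5, 5), (1, 1)),
        ("polymer_02", (5, 20), (3, 3)),
        ("polymer_03", (20, 40), (5, 5)),
        ("polymer_04", (40, 10), (2, 4)),
        ("polymer_05", (50, 45), (4, 4)),
    ]
)
peak = max(lib.entries[i].intensities.max() for i in lib.sorted_ids())
scene = SceneSpec(shape=(64, 64), particles=particles,
                  noise_sigma=0.03 * peak, seed=7)
cube, truth, _ = synth_cube(scene, lib)

amap = identify_pixels(cube, lib)  # thresholds 0.6/0.6, agreement rule
summary = validate_against_truth(amap.cluster, truth)
print(f"assigned pixels: {amap.n_assigned} of {truth.astype(bool).sum()} particle pixels")
print(f"pixel-level: {summary.percent_correct:.1f}% correct, "
      f"{summary.percent_misassigned:.1f}% misassigned")

parts = find_particles(amap, closing_radius=1)
hist = size_histogram(parts)
comp = composition_summary(parts)
print(f"particles found: {len(parts)}")
print(f"share in the smallest (11 um) size class: {100 * hist.class_share(11.0):.0f}%")
print(f"share below 50 um: {100 * hist.fraction_below(50.0):.0f}%")
print("composition (% of particles):")
for _, row in comp.iterrows():
    print(f"  cluster {int(row.cluster_number)}: {row.percent:.0f}%")
# All five placed particles are recovered with their true polymer; sizes
# follow the maximum-extent-plus-one-pitch rule (a 1x1 particle is 11 um).
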