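"""Group inference with TFCE + maximal-statistic permutation testing.

Simulates a cohort with a self-vs-far distinctiveness effect planted in
a small central box of a 16³ grid, smooths the per-subject searchlight
maps, and runs the sign-flip permutation test with threshold-free
cluster enhancement.  Prints how many voxels survive FWE correction and
where they fall relative to the planted region (dilated by the
searchlight radius, since any sphere overlapping the region carries
signal).
"""

import numpy as np
from scipy import ndimage

import stategrain as sg

grid = (16, 16, 16)
region = np.zeros(grid, dtype=bool)
region[6:10, 6:10, 6:10] = True  # 4x4x4 planted box

cfg = sg.SimulationConfig(
    n_subjects=14, grid_shape=grid, targets=("self", "far"),
    n_states=10, dispersion_by_target={"self": 1.0, "far": 0.2},
    baseline_dispersion=0.3, noise_sd=0.4, effect_region=region, seed=23,
)
mask = np.ones(grid, dtype=bool)
radius = 2.0

stacks = {"self": [], "far": []}
for s in range(cfg.n_subjects):
    patterns = sg.simulate_subject_betas(cfg, s)
    maps = sg.searchlight_distinctiveness(patterns, mask, radius=radius,
                                          min_voxels=10)
    for t in stacks:
        stacks[t].append(sg.smooth_map(maps[t].values, 4.0, cfg.voxel_size_mm))

corrected = sg.permutation_fwe(
    (np.array(stacks["self"]), np.array(stacks["far"])),
    contrast="paired-t",
    tfce=sg.TFCEParams(E=0.5, H=2.0),
    scheme=sg.PermutationScheme(n_perms=500, seed=24),
)

sig = corrected.significant(0.05)
reach = ndimage.binary_dilation(region, iterations=int(radius) + 2)
print(f"permutations used: {corrected.n_perms_used} "
      f"(exhaustive: {corrected.exhaustive})")
print(f"voxels with corrected p < 0.05: {int(sig.sum())} "
      f"of {int(np.isfinite(corrected.p).sum())} tested")
print(f"  within reach of the planted box: {int(sig[reach].sum())}")
print(f"  far from the planted box:        {int(sig[~reach].sum())}")
print(f"minimum corrected p = {np.nanmin(corrected.p):.4f} "
      f"(bounded below by 2/n_perms)")
print("Searchlight spheres and smoothing smear the effect a few voxels "
      "beyond the planted box, but remote false positives are controlled "
      "at the family-wise 0.05 level.")
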