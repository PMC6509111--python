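"""Searchlight RSA distinctiveness on a simulated cohort.

Simulates 12 subjects whose mental-state activity patterns are more
dispersed (hence more mutually distinct) for the self than for a far
other inside a planted region, runs the radius-4 searchlight, and
summarizes the group difference as the ROI statistics a study would
report: the difference in mean pattern correlation (Δr) and the paired
Cohen's d.
"""

import numpy as np

import stategrain as sg

cfg = sg.SimulationConfig(
    n_subjects=12,
    grid_shape=(12, 12, 12),
    targets=("self", "far"),
    n_states=12,
    dispersion_by_target={"self": 0.45, "far": 0.25},
    noise_sd=0.8,
    seed=7,
)
mask = np.ones(cfg.grid_shape, dtype=bool)
region = cfg.region_mask()

roi_scalars = {"self": [], "far": []}
group_diff = []
for s in range(cfg.n_subjects):
    patterns = sg.simulate_subject_betas(cfg, s)
    maps = sg.searchlight_distinctiveness(patterns, mask, radius=4)
    group_diff.append(maps["self"].values - maps["far"].values)
    roi = sg.roi_distinctiveness(patterns, region)
    for t in roi_scalars:
        roi_scalars[t].append(roi[t])

comparison = sg.pairwise_target_tests(
    {t: np.array(v) for t, v in roi_scalars.items()}
)[0]
mean_diff = np.nanmean(np.mean(group_diff, axis=0)[region])

print(f"ROI mean dissimilarity: self = {np.mean(roi_scalars['self']):.3f}, "
      f"far = {np.mean(roi_scalars['far']):.3f}")
print(f"Delta-r (far minus self mean pattern correlation) = "
      f"{comparison.delta_r:.3f}")
print(f"paired Cohen's d = {comparison.cohen_d:.2f}, "
      f"t({comparison.df:.0f}) = {comparison.t:.2f}, p = {comparison.p:.2e}")
print(f"searchlight group difference inside planted region = {mean_diff:.3f}")
print("Positive values mean self states evoke more differentiated patterns "
      "than the far target's, as planted.")
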