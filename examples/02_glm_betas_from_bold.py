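"""First-level GLM round trip: events → design → BOLD → betas.

Builds an HRF-convolved design from a randomized event table, forward-
models a BOLD series from known condition betas, refits the GLM, and
reports how well the betas come back at two noise levels.
"""

import numpy as np

import stategrain as sg
from stategrain.glm import build_design_matrix, fit_glm

cfg = sg.SimulationConfig(
    n_subjects=1, grid_shape=(8, 8, 8), targets=("self", "far"),
    n_states=6, dispersion_by_target={"self": 1.0, "far": 0.2},
    noise_sd=0.2, seed=11,
)
truth = sg.simulate_subject_betas(cfg, 0)

events = sg.generate_trial_design(
    cfg.n_states, cfg.targets, pairing="state-list", n_runs=4, seed=11
)
n_trs = int(np.ceil((events["onset"].max() + 30.0) / 1.4))
design = build_design_matrix(events, tr=1.4, n_trs=n_trs)
print(f"design: {design.matrix.shape[0]} scans x {design.matrix.shape[1]} "
      f"regressors ({len(design.condition_cols)} condition columns)")

for noise in (0.0, 1.0):
    series = sg.simulate_bold(design, truth, noise_sd=noise, seed=42)
    fitted = fit_glm(series, design)
    err = max(
        np.abs(fitted.get(*c) - truth.get(*c)).max() for c in truth.conditions
    )
    v = np.concatenate([fitted.get(*c).ravel() for c in truth.conditions])
    r = np.corrcoef(v, truth.data.ravel())[0, 1]
    print(f"noise sd {noise:.1f}: max abs beta error = {err:.2e}, "
          f"truth-fit correlation = {r:.4f}")
print("With zero noise the OLS refit reproduces the generating betas "
      "exactly; with noise the error is set by the design efficiency.")
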