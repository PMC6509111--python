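"""Mixed-effects analysis of explicit state-similarity ratings.

Simulates a two-target rating study (all 45 pairs of 10 states, close
and far targets) with a planted fixed effect of 0.23 rating points —
far targets' states rated more similar to each other than close
targets' — then fits the maximal mixed model and prints the estimates
a behavioral study would report.
"""

import stategrain as sg

cfg = sg.RatingSimConfig(
    n_participants=120, n_states=10, targets=("close", "far"),
    fixed_target_effect=0.23, seed=31,
)
ratings = sg.simulate_ratings(cfg)
print(f"{cfg.n_participants} participants x "
      f"{len(ratings) // cfg.n_participants} trials = {len(ratings)} ratings")

res = sg.fit_state_similarity_lmm(ratings, fixed="close-vs-far")
row = res.fixed.iloc[-1]
lo, hi = res.ci()
print(f"fixed effect of target (far vs close): b = {row['b']:.3f} "
      f"[{lo:.3f}, {hi:.3f}], beta = {res.beta_std:.3f}")
print(f"t({row['df']:.1f}) = {row['t']:.2f}, p = {row['p']:.2e} "
      f"(Satterthwaite df)")
print(f"marginal R2 = {res.r2_marginal:.3f}, "
      f"conditional R2 = {res.r2_conditional:.2f}")
print(f"random structure: {res.random_structure}; "
      f"fallbacks: {res.fallback_log or 'none'}")
print("b near 0.23 with a CI covering it means the planted social-distance "
      "effect is recovered; conditional R2 reflects the participant and "
      "state-pair heterogeneity the random effects absorb.")
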