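"""Synthetic neural and behavioral data with known ground truth.

The generative model mirrors the statistical structure the analysis
assumes.  Each subject has one latent spatial map per mental state,
shared across target people, plus a mean map per target.  Inside a
designated *effect region* the state maps are scaled by a per-target
dispersion, so the spread of state-specific patterns — and hence their
pairwise correlation distance — differs by target; outside the region a
common baseline dispersion applies.  Planting dispersions such as
self > close > far therefore plants the ordering the representational
distinctiveness statistic should recover.

Behavioral similarity ratings follow a linear mixed model: a grand
mean, a fixed target (social-distance) effect, random intercepts and
target slopes for participants and for state pairs, and Gaussian
residuals.  Ratings are continuous by default; an optional
discretization rounds and clips them to the 1–6 response scale (which
attenuates the fixed effect, so recovery tests use the continuous
form).

All generators are pure functions of (config, seed): repeated calls
return bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volumes import PatternSet, make_affine

__all__ = [
    "SimulationConfig",
    "RatingSimConfig",
    "default_effect_region",
    "generate_trial_design",
    "simulate_subject_betas",
    "simulate_dataset",
    "simulate_bold",
    "simulate_ratings",
]

#: Spatial standard deviation of the per-target mean maps.  This sets the
#: "signal" scale against which state dispersion and noise compete when
#: patterns are correlated across voxels; it is fixed at 1 so that
#: dispersion and noise_sd are expressed relative to it.
TARGET_MEAN_SD = 1.0


def default_effect_region(grid_shape: Sequence[int]) -> np.ndarray:
    """Central box covering half the extent of each axis (~1/8 of voxels)."""
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    sl = tuple(slice(n // 4, n // 4 + max(1, n // 2)) for n in grid_shape)
    mask[sl] = True
    return mask


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic neural dataset.

    Defaults describe the standard planted-effect study: 20 subjects on a
    12×12×12 grid of 2 mm voxels, three targets (self, close, far) with
    25 states each, and within-target pattern dispersions 1.0/0.6/0.2 in
    a central effect region.
    """

    n_subjects: int = 20
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 2.0
    targets: tuple[str, ...] = ("self", "close", "far")
    n_states: int = 25
    effect_region: np.ndarray | None = None  # boolean grid mask; None → central box
    dispersion_by_target: Mapping[str, float] = field(
        default_factory=lambda: {"self": 1.0, "close": 0.6, "far": 0.2}
    )
    baseline_dispersion: float = 0.3
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.targets) == 0 or len(set(self.targets)) != len(self.targets):
            raise ValueError("targets must be nonempty and unique")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        missing = [t for t in self.targets if t not in self.dispersion_by_target]
        if missing:
            raise ValueError(f"no dispersion given for targets {missing}")
        disp = [self.dispersion_by_target[t] for t in self.targets]
        if any(d < 0 for d in disp) or self.baseline_dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersions and noise_sd must be nonnegative")
        region = self.region_mask()
        if region.shape != tuple(self.grid_shape):
            raise ValueError("effect_region shape does not match grid_shape")
        if not region.any() and len(set(disp)) > 1:
            raise ValueError(
                "distinct per-target dispersions require a nonempty effect region"
            )

    def region_mask(self) -> np.ndarray:
        if self.effect_region is None:
            return default_effect_region(self.grid_shape)
        return np.asarray(self.effect_region, dtype=bool)

    @property
    def states(self) -> list[str]:
        return [f"state{i:02d}" for i in range(self.n_states)]


@dataclass(frozen=True)
class RatingSimConfig:
    """Parameters of the synthetic similarity-rating dataset.

    Defaults follow the two-target (close vs far) design: 346
    participants rating all unordered pairs of 10 states for both
    targets (90 trials each), with a planted fixed target effect of
    0.23 rating points.  Random-effect standard deviations are chosen so
    random structure explains roughly 30–40% of total variance, as is
    typical of these rating tasks.
    """

    n_participants: int = 346
    n_states: int = 10
    targets: tuple[str, ...] = ("close", "far")
    fixed_target_effect: float = 0.23
    grand_mean: float = 3.5
    sd_participant_intercept: float = 0.6
    sd_pair_intercept: float = 0.3
    sd_participant_slope: float = 0.3
    sd_pair_slope: float = 0.1
    sd_residual: float = 1.0
    rating_scale: tuple[int, int] = (1, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.sd_participant_intercept,
            self.sd_pair_intercept,
            self.sd_participant_slope,
            self.sd_pair_slope,
            self.sd_residual,
        )
        if any(s < 0 for s in sds):
            raise ValueError("random-effect and residual sds must be nonnegative")
        if self.rating_scale[0] >= self.rating_scale[1]:
            raise ValueError("rating_scale must satisfy min < max")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if len(self.targets) == 0 or len(set(self.targets)) != len(self.targets):
            raise ValueError("targets must be nonempty and unique")

    @property
    def states(self) -> list[str]:
        return [f"state{i:02d}" for i in range(self.n_states)]


# ---------------------------------------------------------------------
# trial designs
# ---------------------------------------------------------------------

def generate_trial_design(
    n_states: int,
    targets: Sequence[str],
    pairing: str = "all-pairs",
    blocked: bool = False,
    n_runs: int = 1,
    seed: int = 0,
    states: Sequence[str] | None = None,
    trial_duration: float = 4.2,
    jitter_increment: float = 1.4,
    jitter_mean: float = 1.4,
    jitter_max: float = 4.2,
    initial_rest: float = 10.0,
) -> pd.DataFrame:
    """Generate a randomized trial table.

    Two pairings are supported.  ``"all-pairs"`` enumerates every
    unordered pair of states once per target (the rating-task design:
    C(n_states, 2) × n_targets rows, e.g. 315 for 15 states × 3 targets
    or 90 for 10 states × 2 targets) and returns columns
    ``trial, run, target, state_i, state_j``.  ``"state-list"`` presents
    each (target, state) once per run (the scanner design) and adds
    ``onset``/``duration`` columns, with inter-trial jitter drawn in
    fixed increments from a truncated Poisson.

    Blocked designs group trials by target within each run, with block
    order and within-block order randomized per seed; intermixed designs
    shuffle all trials within a run.
    """
    if n_states < 2:
        raise ValueError("invalid design: need at least 2 states")
    targets = list(targets)
    if not targets:
        raise ValueError("invalid design: need at least one target")
    if len(set(targets)) != len(targets):
        raise ValueError("invalid design: duplicate targets")
    if states is None:
        states = [f"state{i:02d}" for i in range(n_states)]
    elif len(states) != n_states:
        raise ValueError("states length must equal n_states")
    rng = np.random.default_rng(seed)

    if pairing == "all-pairs":
        if n_runs != 1:
            raise ValueError("all-pairs designs are single-session (n_runs=1)")
        pairs = list(combinations(states, 2))
        rows = []
        block_targets = list(targets)
        if blocked:
            rng.shuffle(block_targets)
        for t in block_targets:
            order = rng.permutation(len(pairs))
            for k in order:
                a, b = pairs[k]
                rows.append((1, t, a, b))
        df = pd.DataFrame(rows, columns=["run", "target", "state_i", "state_j"])
        if not blocked:
            df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
                drop=True
            )
        df.insert(0, "trial", np.arange(len(df)))
        assert len(df) == math.comb(n_states, 2) * len(targets)
        return df

    if pairing != "state-list":
        raise ValueError(f"unknown pairing {pairing!r}")

    rows = []
    n_levels = int(round(jitter_max / jitter_increment))
    for run in range(1, n_runs + 1):
        trials: list[tuple[str, str]] = []
        if blocked:
            block_order = list(targets)
            rng.shuffle(block_order)
            for t in block_order:
                order = rng.permutation(n_states)
                trials.extend((t, states[i]) for i in order)
        else:
            trials = [(t, s) for t in targets for s in states]
            order = rng.permutation(len(trials))
            trials = [trials[i] for i in order]
        onset = initial_rest
        for t, s in trials:
            rows.append((run, onset, trial_duration, t, s))
            jitter = jitter_increment * min(
                rng.poisson(jitter_mean / jitter_increment), n_levels
            )
            onset += trial_duration + jitter
    df = pd.DataFrame(rows, columns=["run", "onset", "duration", "target", "state"])
    df.insert(0, "trial", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------
# neural patterns
# ---------------------------------------------------------------------

def _subject_rng(seed: int, subject_id: int) -> np.random.Generator:
    # per-subject stream derived deterministically from (master seed, subject)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_id)]))


def simulate_subject_betas(config: SimulationConfig, subject_id: int) -> PatternSet:
    """Draw one subject's condition-wise beta volumes.

    Each state ``s`` has a latent spatial map ``z_s`` shared across
    targets; each target ``T`` has its own mean map ``m_T``.  The beta
    volume for condition (T, s) is::

        beta = m_T + disp_T(v) * z_s + noise

    where ``disp_T(v)`` equals ``dispersion_by_target[T]`` inside the
    effect region and ``baseline_dispersion`` elsewhere.  Larger
    dispersion spreads the target's state patterns further apart, which
    lowers their pairwise spatial correlation and raises the
    within-target correlation distance the RSA stage measures.
    """
    rng = _subject_rng(config.seed, subject_id)
    shape = tuple(config.grid_shape)
    region = config.region_mask()
    n_t, n_s = len(config.targets), config.n_states

    target_means = TARGET_MEAN_SD * rng.standard_normal((n_t, *shape))
    state_latents = rng.standard_normal((n_s, *shape))
    noise = (
        config.noise_sd * rng.standard_normal((n_t, n_s, *shape))
        if config.noise_sd > 0
        else np.zeros((n_t, n_s, *shape))
    )

    conditions = []
    data = np.empty((n_t * n_s, *shape))
    k = 0
    for i, target in enumerate(config.targets):
        disp = np.where(
            region, config.dispersion_by_target[target], config.baseline_dispersion
        )
        for j, state in enumerate(config.states):
            data[k] = target_means[i] + disp * state_latents[j] + noise[i, j]
            conditions.append((target, state))
            k += 1
    return PatternSet(
        subject=subject_id,
        conditions=conditions,
        data=data,
        affine=make_affine(config.voxel_size_mm),
    )


def simulate_dataset(config: SimulationConfig) -> list[PatternSet]:
    """All subjects' pattern sets under a shared master seed."""
    return [simulate_subject_betas(config, i) for i in range(config.n_subjects)]


def simulate_bold(
    design, true_betas: PatternSet, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Forward-model a 4-D series: design × betas + white noise, voxelwise.

    ``design`` is a :class:`~stategrain.glm.DesignMatrix`; condition
    columns pick up the matching beta volumes, nuisance columns carry
    zero true coefficients.  Returns an array of shape (n_TRs, nx, ny, nz).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    X = design.matrix
    missing = [c for c in design.conditions if c not in true_betas]
    if missing:
        raise ValueError(f"true_betas lacks conditions {missing}")
    shape = true_betas.grid_shape
    B = np.zeros((X.shape[1], int(np.prod(shape))))
    for col, cond in zip(design.condition_cols, design.conditions):
        B[col] = true_betas.get(*cond).ravel()
    Y = X @ B
    if noise_sd > 0:
        Y = Y + noise_sd * np.random.default_rng(seed).standard_normal(Y.shape)
    return Y.reshape(X.shape[0], *shape)


# ---------------------------------------------------------------------
# behavioral ratings
# ---------------------------------------------------------------------

def target_codes(targets: Sequence[str]) -> dict[str, float]:
    """Default numeric coding of the fixed target effect.

    The first target codes 0 and all others 1 — a self-vs-other binary
    when self comes first, and simply (close=0, far=1) for the
    two-target design, so the planted effect is the far−close mean
    difference.
    """
    return {t: (0.0 if i == 0 else 1.0) for i, t in enumerate(targets)}


def simulate_ratings(
    config: RatingSimConfig,
    discretize: bool = False,
    codes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a similarity-rating table from the mixed-effects generator.

    Returns one row per (participant, target, state pair) with columns
    ``participant, target, state_i, state_j, pair, rating``.  With
    ``discretize=True`` ratings are rounded and clipped to the response
    scale; the default keeps them continuous.
    """
    rng = np.random.default_rng(config.seed)
    codes = dict(codes) if codes is not None else target_codes(config.targets)
    pairs = list(combinations(config.states, 2))
    n_p, n_q = config.n_participants, len(pairs)

    u0 = config.sd_participant_intercept * rng.standard_normal(n_p)
    u1 = config.sd_participant_slope * rng.standard_normal(n_p)
    v0 = config.sd_pair_intercept * rng.standard_normal(n_q)
    v1 = config.sd_pair_slope * rng.standard_normal(n_q)

    rows = []
    for p in range(n_p):
        for t in config.targets:
            c = codes[t]
            eps = config.sd_residual * rng.standard_normal(n_q)
            mu = (
                config.grand_mean
                + config.fixed_target_effect * c
                + u0[p]
                + u1[p] * c
                + v0
                + v1 * c
                + eps
            )
            for q, (a, b) in enumerate(pairs):
                rows.append((p, t, a, b, f"{a}|{b}", mu[q]))
    df = pd.DataFrame(
        rows, columns=["participant", "target", "state_i", "state_j", "pair", "rating"]
    )
    if discretize:
        lo, hi = config.rating_scale
        df["rating"] = np.clip(np.round(df["rating"]), lo, hi).astype(int)
    return df
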