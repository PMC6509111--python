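"""Canned simulation experiments: error-rate and recovery studies.

These functions bundle the study conditions used to validate the
pipeline — fully null datasets for the family-wise error rate of the
permutation + TFCE procedure, planted-dispersion datasets for
recovery of the distinctiveness ordering, and mixed-model recovery of
a planted rating effect.  They are ordinary library code (seeded,
deterministic) so the same experiment can be run at different sizes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .behavior import fit_state_similarity_lmm
from .inference import (
    PermutationScheme,
    TFCEParams,
    pairwise_target_tests,
    permutation_fwe,
    smooth_map,
)
from .rsa import _neighbor_matrix, roi_distinctiveness, searchlight_distinctiveness
from .synth import RatingSimConfig, SimulationConfig, simulate_subject_betas

__all__ = [
    "null_fwer_experiment",
    "planted_recovery_experiment",
    "lmm_recovery_experiment",
]


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n)


def null_fwer_experiment(
    n_datasets: int = 200,
    n_subjects: int = 12,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_states: int = 8,
    n_perms: int = 500,
    dispersion: float = 0.5,
    noise_sd: float = 0.3,
    radius: float = 4.0,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
    progress: bool = False,
) -> dict:
    """Family-wise false-positive rate of the map-level pipeline under the null.

    Every dataset gives both targets identical pattern dispersion, so any
    voxel declared significant is a false positive.  Each dataset runs the
    full analysis — searchlight distinctiveness, 6 mm smoothing, paired t,
    TFCE, sign-flip maximal-statistic permutation — and contributes one
    flag: did *any* voxel reach corrected p < alpha?
    """
    mask = np.ones(grid_shape, dtype=bool)
    K, _ = _neighbor_matrix(mask, radius)
    data_seeds = _derive_seeds(seed, n_datasets)
    perm_seeds = _derive_seeds(seed + 1, n_datasets)
    flags = np.zeros(n_datasets, dtype=bool)
    for i in range(n_datasets):
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            grid_shape=grid_shape,
            voxel_size_mm=voxel_size_mm,
            targets=("self", "far"),
            n_states=n_states,
            dispersion_by_target={"self": dispersion, "far": dispersion},
            baseline_dispersion=dispersion,
            noise_sd=noise_sd,
            seed=int(data_seeds[i]),
        )
        stacks = {"self": [], "far": []}
        for s in range(n_subjects):
            ps = simulate_subject_betas(cfg, s)
            maps = searchlight_distinctiveness(
                ps, mask, radius=radius, neighbor_matrix=K
            )
            for t in stacks:
                stacks[t].append(
                    smooth_map(maps[t].values, fwhm_mm, voxel_size_mm)
                )
        cp = permutation_fwe(
            (np.array(stacks["self"]), np.array(stacks["far"])),
            contrast="paired-t",
            tfce=TFCEParams(E=0.5, H=2.0),
            scheme=PermutationScheme(n_perms=n_perms, seed=int(perm_seeds[i])),
            mask=mask,
        )
        flags[i] = bool(np.any(cp.p[np.isfinite(cp.p)] < alpha))
        if progress and (i + 1) % 20 == 0:
            print(f"  null dataset {i + 1}/{n_datasets}: "
                  f"{int(flags[:i + 1].sum())} with a false positive")
    fraction = flags.mean()
    return {
        "n_datasets": n_datasets,
        "n_false_positive": int(flags.sum()),
        "fwer": float(fraction),
        "flags": flags,
    }


def planted_recovery_experiment(
    n_seeds: int = 20,
    n_subjects: int = 20,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_states: int = 25,
    dispersions: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    radius: float = 4.0,
    n_searchlight_seeds: int = 3,
    seed: int = 0,
) -> dict:
    """Recovery of a planted distinctiveness ordering (self > close > far).

    For each master seed, simulates a cohort, computes ROI
    distinctiveness over the effect region per subject, and checks that
    all three pairwise mean differences have the planted sign.  For the
    first ``n_searchlight_seeds`` cohorts the searchlight map is also
    computed and the group self-vs-far difference compared inside vs
    outside the planted region (localization).
    """
    dispersions = dispersions or {"self": 1.0, "close": 0.6, "far": 0.2}
    targets = tuple(dispersions)
    order = sorted(targets, key=lambda t: -dispersions[t])
    cohort_seeds = _derive_seeds(seed, n_seeds)
    mask = np.ones(grid_shape, dtype=bool)
    K = None
    ordering_ok = np.zeros(n_seeds, dtype=bool)
    localization = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            grid_shape=grid_shape,
            targets=targets,
            n_states=n_states,
            dispersion_by_target=dispersions,
            noise_sd=noise_sd,
            seed=int(cohort_seeds[i]),
        )
        region = cfg.region_mask()
        scalars = {t: [] for t in targets}
        diffs = []
        do_searchlight = i < n_searchlight_seeds
        if do_searchlight and K is None:
            K, _ = _neighbor_matrix(mask, radius)
        for s in range(n_subjects):
            ps = simulate_subject_betas(cfg, s)
            roi = roi_distinctiveness(ps, region)
            for t in targets:
                scalars[t].append(roi[t])
            if do_searchlight:
                maps = searchlight_distinctiveness(
                    ps, mask, radius=radius, neighbor_matrix=K
                )
                diffs.append(maps[order[0]].values - maps[order[-1]].values)
        arrays = {t: np.array(v) for t, v in scalars.items()}
        tests = pairwise_target_tests(arrays)
        signs_ok = True
        for res in tests:
            a, b = res.pair
            planted = dispersions[a] - dispersions[b]
            if np.sign(res.mean_diff) != np.sign(planted):
                signs_ok = False
        ordering_ok[i] = signs_ok
        if do_searchlight:
            group = np.nanmean(diffs, axis=0)
            localization.append(
                {
                    "inside": float(np.nanmean(group[region])),
                    "outside": float(np.nanmean(group[~region])),
                }
            )
    return {
        "n_seeds": n_seeds,
        "n_ordering_correct": int(ordering_ok.sum()),
        "ordering_rate": float(ordering_ok.mean()),
        "localization": localization,
    }


def lmm_recovery_experiment(
    n_replicates: int = 100,
    n_participants: int = 346,
    n_states: int = 10,
    effect: float = 0.23,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Coverage / rejection behavior of the rating mixed model.

    Each replicate simulates a two-target (close vs far) rating study
    with fixed effect ``effect`` and fits the mixed model; reports how
    often the 95% CI covers the planted value and how often the test
    rejects at ``alpha`` (the type-I error rate when ``effect`` is 0).
    """
    rep_seeds = _derive_seeds(seed, n_replicates)
    base = RatingSimConfig(
        n_participants=n_participants,
        n_states=n_states,
        targets=("close", "far"),
        fixed_target_effect=effect,
    )
    covered = np.zeros(n_replicates, dtype=bool)
    rejected = np.zeros(n_replicates, dtype=bool)
    estimates = np.zeros(n_replicates)
    for i in range(n_replicates):
        ratings_cfg = replace(base, seed=int(rep_seeds[i]))
        from .synth import simulate_ratings

        df = simulate_ratings(ratings_cfg)
        res = fit_state_similarity_lmm(df, fixed="close-vs-far",
                                       standardize=False)
        lo, hi = res.ci()
        covered[i] = lo <= effect <= hi
        rejected[i] = res.p < alpha
        estimates[i] = res.b
    return {
        "n_replicates": n_replicates,
        "coverage": float(covered.mean()),
        "rejection_rate": float(rejected.mean()),
        "mean_estimate": float(estimates.mean()),
    }
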