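"""Reproducible end-to-end pipeline: simulate → (glm) → rsa → infer →
behavior → figure, with a JSON manifest tying every output to the seed
and parameters that produced it."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import fit_state_similarity_lmm, lsmeans_posthoc
from .geometry import mds_embed, plot_state_space, procrustes_align
from .glm import build_design_matrix, fit_glm
from .inference import (
    PermutationScheme,
    TFCEParams,
    pairwise_target_tests,
    permutation_fwe,
    smooth_map,
)
from .io import (
    load_pattern_set,
    save_events,
    save_pattern_set,
    save_ratings,
    save_volume,
)
from .rsa import (
    compute_rdm,
    average_target_dissimilarity,
    roi_distinctiveness,
    searchlight_distinctiveness,
)
from .rsa import _neighbor_matrix
from .synth import (
    RatingSimConfig,
    SimulationConfig,
    generate_trial_design,
    simulate_bold,
    simulate_ratings,
    simulate_subject_betas,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "rsa", "infer", "behavior", "figure")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs, serializable to YAML."""

    outdir: str = "stategrain_run"
    seed: int = 0
    # neural simulation
    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 2.0
    targets: tuple[str, ...] = ("self", "close", "far")
    n_states: int = 12
    dispersion_by_target: dict = field(
        default_factory=lambda: {"self": 1.0, "close": 0.6, "far": 0.2}
    )
    baseline_dispersion: float = 0.3
    noise_sd: float = 0.3
    # optional time-series round trip through the GLM
    simulate_timeseries: bool = False
    tr: float = 1.4
    bold_noise_sd: float = 1.0
    # rsa / inference
    radius: float = 4.0
    fwhm_mm: float = 6.0
    n_perms: int = 500
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    connectivity: int = 26
    # behavior
    n_participants: int = 46
    n_rating_states: int = 15
    rating_fixed_effect: float = 0.23
    lmm_fixed: str = "self-vs-other"

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects,
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=self.voxel_size_mm,
            targets=tuple(self.targets),
            n_states=self.n_states,
            dispersion_by_target=dict(self.dispersion_by_target),
            baseline_dispersion=self.baseline_dispersion,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )

    def rating_config(self) -> RatingSimConfig:
        return RatingSimConfig(
            n_participants=self.n_participants,
            n_states=self.n_rating_states,
            targets=tuple(self.targets),
            fixed_target_effect=self.rating_fixed_effect,
            seed=self.seed + 1,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _hash_params(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "manifest.json"
        self.config_hash = _hash_params(asdict(config))
        if self.path.exists():
            self.doc = json.loads(self.path.read_text())
            if self.doc.get("config_hash") != self.config_hash:
                logger.warning("config changed; previous stage outputs invalidated")
                self.doc["stages"] = {}
        else:
            self.doc = {"stages": {}}
        self.doc.update(
            {
                "version": __version__,
                "seed": config.seed,
                "config": asdict(config),
                "config_hash": self.config_hash,
            }
        )

    def done(self, stage: str) -> bool:
        rec = self.doc["stages"].get(stage)
        if not rec:
            return False
        return all(Path(p).exists() for p in rec["outputs"])

    def record(self, stage: str, outputs: list[Path], extra: dict | None = None):
        self.doc["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "hashes": {str(p): _file_hash(Path(p)) for p in outputs},
            **(extra or {}),
        }
        self.path.write_text(json.dumps(self.doc, indent=1, default=str))


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; each stage is idempotent
    (skipped when its recorded outputs already exist under the same
    configuration) and every output lands in the manifest."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    sim = config.sim_config()
    mask = np.ones(tuple(config.grid_shape), dtype=bool)

    def beta_path(s: int) -> Path:
        return outdir / f"sub-{s:02d}_betas.nii.gz"

    if "simulate" in stages and not manifest.done("simulate"):
        outputs = []
        for s in range(config.n_subjects):
            ps = simulate_subject_betas(sim, s)
            outputs.append(save_pattern_set(ps, beta_path(s)))
        events = generate_trial_design(
            config.n_states, config.targets, pairing="state-list",
            blocked=len(config.targets) > 2, n_runs=2, seed=config.seed,
        )
        outputs.append(save_events(events, outdir / "events.tsv"))
        manifest.record("simulate", outputs)

    if "glm" in stages and config.simulate_timeseries and not manifest.done("glm"):
        from .io import load_events

        events = load_events(outdir / "events.tsv")
        run_len = events.groupby("run")["onset"].max().max() + 30.0
        n_trs = int(np.ceil(run_len / config.tr))
        design = build_design_matrix(events, config.tr, n_trs)
        outputs = []
        for s in range(config.n_subjects):
            truth = load_pattern_set(beta_path(s))
            series = simulate_bold(
                design, truth, config.bold_noise_sd, seed=config.seed * 10_000 + s
            )
            fitted = fit_glm(series, design, mask, subject=s, affine=truth.affine)
            p = outdir / f"sub-{s:02d}_betas-refit.nii.gz"
            outputs.append(save_pattern_set(fitted, p))
        manifest.record("glm", outputs)

    if "rsa" in stages and not manifest.done("rsa"):
        K, _ = _neighbor_matrix(mask, config.radius)
        outputs = []
        roi_rows = []
        roi = sim.region_mask()
        for s in range(config.n_subjects):
            ps = load_pattern_set(beta_path(s))
            maps = searchlight_distinctiveness(
                ps, mask, radius=config.radius, neighbor_matrix=K
            )
            for target, dmap in maps.items():
                p = outdir / f"sub-{s:02d}_target-{target}_distinctiveness.nii.gz"
                outputs.append(save_volume(dmap.values, ps.affine, p))
            scalars = roi_distinctiveness(ps, roi)
            roi_rows.append({"subject": s, **scalars})
            rdm = compute_rdm(ps, voxel_index=roi)
            if s == 0:
                rdm.to_frame().to_csv(outdir / "sub-00_roi_rdm.csv")
                outputs.append(outdir / "sub-00_roi_rdm.csv")
        roi_df = pd.DataFrame(roi_rows)
        roi_df.to_csv(outdir / "roi_distinctiveness.csv", index=False)
        outputs.append(outdir / "roi_distinctiveness.csv")
        manifest.record("rsa", outputs)

    if "infer" in stages and not manifest.done("infer"):
        tfce = TFCEParams(E=config.tfce_E, H=config.tfce_H,
                          connectivity=config.connectivity)
        from .io import load_volume

        stacks = {
            t: np.stack(
                [
                    smooth_map(
                        load_volume(
                            outdir / f"sub-{s:02d}_target-{t}_distinctiveness.nii.gz"
                        )[0],
                        config.fwhm_mm,
                        config.voxel_size_mm,
                    )
                    for s in range(config.n_subjects)
                ]
            )
            for t in config.targets
        }
        outputs = []
        affine = load_pattern_set(beta_path(0)).affine
        pairs = [
            (a, b)
            for i, a in enumerate(config.targets)
            for b in config.targets[i + 1:]
        ]
        for i, (a, b) in enumerate(pairs):
            cp = permutation_fwe(
                (stacks[a], stacks[b]),
                contrast="paired-t",
                tfce=tfce,
                scheme=PermutationScheme(n_perms=config.n_perms,
                                         seed=config.seed + 100 + i),
            )
            p = outdir / f"pairedt_{a}-vs-{b}_pcorr.nii.gz"
            outputs.append(save_volume(cp.p, affine, p))
        if len(config.targets) >= 3:
            cp = permutation_fwe(
                stacks,
                contrast="anova",
                tfce=tfce,
                scheme=PermutationScheme(
                    n_perms=config.n_perms, seed=config.seed + 200,
                    kind="target-relabel",
                ),
            )
            outputs.append(save_volume(cp.p, affine, outdir / "anova_pcorr.nii.gz"))
        roi_df = pd.read_csv(outdir / "roi_distinctiveness.csv")
        scalars = {t: roi_df[t].to_numpy() for t in config.targets}
        tests = pairwise_target_tests(scalars)
        rows = [
            {
                "pair": "-".join(t.pair), "mean_diff": t.mean_diff,
                "delta_r": t.delta_r, "cohen_d": t.cohen_d, "t": t.t,
                "df": t.df, "p": t.p, "p_adjusted": t.p_adjusted,
            }
            for t in tests
        ]
        pd.DataFrame(rows).to_csv(outdir / "pairwise_tests.csv", index=False)
        outputs.append(outdir / "pairwise_tests.csv")
        manifest.record("infer", outputs)

    if "behavior" in stages and not manifest.done("behavior"):
        ratings = simulate_ratings(config.rating_config())
        outputs = [save_ratings(ratings, outdir / "ratings.csv")]
        fixed = config.lmm_fixed
        if fixed == "self-vs-other" and "self" not in config.targets:
            fixed = "close-vs-far"
        res = fit_state_similarity_lmm(ratings, fixed=fixed)
        summary = {
            "fixed": res.fixed.to_dict(orient="records"),
            "beta_std": res.beta_std,
            "r2_marginal": res.r2_marginal,
            "r2_conditional": res.r2_conditional,
            "variance_components": res.variance_components,
            "random_structure": res.random_structure,
            "fallback_log": res.fallback_log,
            "converged": res.converged,
            "singular": res.singular,
        }
        (outdir / "lmm_summary.json").write_text(
            json.dumps(summary, indent=1, default=float)
        )
        outputs.append(outdir / "lmm_summary.json")
        if len(config.targets) >= 3:
            post = lsmeans_posthoc(ratings, adjust="bonferroni")
            post.to_csv(outdir / "lsmeans_posthoc.csv", index=False)
            outputs.append(outdir / "lsmeans_posthoc.csv")
        manifest.record("behavior", outputs)

    if "figure" in stages and not manifest.done("figure"):
        roi = sim.region_mask()
        per_target = {}
        for t in config.targets:
            dists = []
            for s in range(config.n_subjects):
                ps = load_pattern_set(beta_path(s))
                rdm = compute_rdm(ps, voxel_index=roi)
                idx = [i for i, (tt, _) in enumerate(rdm.conditions) if tt == t]
                dists.append(rdm.matrix[np.ix_(idx, idx)])
            mean_d = np.mean(dists, axis=0)
            from .rsa import RDM

            per_target[t] = RDM(
                conditions=[(t, s) for s in sim.states], matrix=mean_d
            )
        embeddings = [mds_embed(per_target[config.targets[0]])]
        for t in config.targets[1:]:
            embeddings.append(
                procrustes_align(embeddings[0], mds_embed(per_target[t]))
            )
        coords = pd.concat(
            [
                pd.DataFrame(
                    {"target": e.target, "state": e.states,
                     "x": e.coords[:, 0], "y": e.coords[:, 1],
                     "radius": e.radius}
                )
                for e in embeddings
            ]
        )
        coords.to_csv(outdir / "state_space_coords.csv", index=False)
        plot_state_space(embeddings, path=outdir / "state_space.png")
        manifest.record(
            "figure", [outdir / "state_space_coords.csv", outdir / "state_space.png"]
        )

    return manifest.doc
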