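"""First-level GLM: design matrices and condition-wise beta estimation.

The design follows the standard event-related construction: one boxcar
regressor per (target, state) condition convolved with the canonical
double-gamma hemodynamic response, plus per-run intercept and linear
trend and optional head-motion covariates.  Betas are ordinary least
squares; synthetic noise is white, so no prewhitening is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .volumes import Condition, PatternSet, make_affine

__all__ = [
    "DesignMatrix",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "design_induced_similarity",
]

#: canonical double-gamma parameters (SPM-style): response peak 6 s,
#: undershoot peak 16 s, dispersions 1/1, peak:undershoot ratio 6,
#: kernel length 32 s.
HRF_PEAK = 6.0
HRF_UNDERSHOOT = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma response sampled at times ``t`` (seconds).

    Difference of two gamma densities (shapes 6 and 16, unit scale),
    normalized to unit peak; the positive lobe peaks near 5 s.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, HRF_PEAK) - gamma_dist.pdf(t, HRF_UNDERSHOOT) / HRF_RATIO
    h = np.where(t < 0, 0.0, h)
    peak = gamma_dist.pdf(HRF_PEAK - 1.0, HRF_PEAK)  # mode of the positive lobe
    return h / peak


@dataclass
class DesignMatrix:
    """Time × regressor matrix with labeled condition and nuisance columns."""

    matrix: np.ndarray
    labels: list[str]
    tr: float
    condition_cols: list[int]
    conditions: list[Condition]
    run_index: np.ndarray  # run label per scan

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("label count must match number of columns")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate regressor labels")
        if len(self.condition_cols) != len(self.conditions):
            raise ValueError("condition_cols and conditions must align")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def nuisance_cols(self) -> list[int]:
        cond = set(self.condition_cols)
        return [j for j in range(self.matrix.shape[1]) if j not in cond]


def _validate_events(events: pd.DataFrame, tr: float, n_trs: int) -> None:
    required = {"run", "onset", "duration", "target", "state"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table lacks columns {sorted(missing)}")
    if (events["onset"] < 0).any():
        raise ValueError("negative onsets")
    run_len = tr * n_trs
    if ((events["onset"] + events["duration"]) > run_len).any():
        raise ValueError("event extends beyond run length")
    if events.duplicated(subset=["run", "onset"]).any():
        raise ValueError("duplicate (run, onset) rows")


def build_design_matrix(
    events: pd.DataFrame,
    tr: float,
    n_trs: int,
    motion: np.ndarray | None = None,
    oversample: int = 16,
) -> DesignMatrix:
    """HRF-convolved boxcar design with per-run nuisance regressors.

    Parameters
    ----------
    events : DataFrame with columns run, onset, duration, target, state
        Onsets in seconds relative to the start of each run.
    tr : float
        Repetition time in seconds.
    n_trs : int
        Scans per run; total rows are ``n_trs × n_runs``.
    motion : optional (total_scans, m) array
        Head-motion covariates, centered per run and appended.
    oversample : int
        Temporal oversampling used for the boxcar/HRF convolution before
        resampling at scan times.

    One condition column per observed (target, state) spans all runs;
    nuisance columns are a per-run intercept and a per-run centered
    linear trend.
    """
    events = pd.DataFrame(events)
    _validate_events(events, tr, n_trs)
    runs = sorted(events["run"].unique()) if len(events) else [1]
    n_runs = len(runs)
    total = n_trs * n_runs

    conditions: list[Condition] = []
    seen = set()
    for t, s in zip(events["target"], events["state"]):
        if (t, s) not in seen:
            seen.add((t, s))
            conditions.append((str(t), str(s)))

    dt = tr / oversample
    hi_len = n_trs * oversample
    hrf = canonical_hrf(np.arange(0, HRF_LENGTH + dt, dt))
    scan_idx = (np.arange(n_trs) * oversample).astype(int)

    cond_block = np.zeros((total, len(conditions)))
    cond_of = {c: j for j, c in enumerate(conditions)}
    for r_i, run in enumerate(runs) if conditions else ():
        ev = events[events["run"] == run]
        hi = np.zeros((hi_len, len(conditions)))
        for _, row in ev.iterrows():
            j = cond_of[(str(row["target"]), str(row["state"]))]
            a = int(np.floor(row["onset"] / dt))
            b = int(np.ceil((row["onset"] + row["duration"]) / dt))
            hi[a:b, j] = 1.0
        conv = np.apply_along_axis(
            lambda col: np.convolve(col, hrf)[:hi_len], 0, hi
        )
        cond_block[r_i * n_trs : (r_i + 1) * n_trs] = conv[scan_idx]

    nuis_cols, nuis_labels = [], []
    for r_i, run in enumerate(runs):
        sl = slice(r_i * n_trs, (r_i + 1) * n_trs)
        mean = np.zeros(total)
        mean[sl] = 1.0
        trend = np.zeros(total)
        trend[sl] = np.linspace(-1.0, 1.0, n_trs)
        nuis_cols += [mean, trend]
        nuis_labels += [f"run{run}_mean", f"run{run}_trend"]
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != total:
            raise ValueError("motion rows must equal total scans")
        motion = motion.copy()
        for r_i in range(n_runs):
            sl = slice(r_i * n_trs, (r_i + 1) * n_trs)
            motion[sl] -= motion[sl].mean(axis=0)
        for m in range(motion.shape[1]):
            nuis_cols.append(motion[:, m])
            nuis_labels.append(f"motion{m + 1}")

    X = np.column_stack([cond_block] + [c[:, None] for c in nuis_cols]) if nuis_cols else cond_block
    labels = [f"{t}:{s}" for t, s in conditions] + nuis_labels
    run_index = np.repeat(runs, n_trs)
    return DesignMatrix(
        matrix=X,
        labels=labels,
        tr=tr,
        condition_cols=list(range(len(conditions))),
        conditions=conditions,
        run_index=run_index,
    )


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    # columns whose removal is forced by rank deficiency, via pivoted QR
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [labels[j] for j in sorted(piv[rank:])]


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    subject: str | int = "subject",
    affine: np.ndarray | None = None,
) -> PatternSet:
    """Voxelwise OLS; condition columns are extracted into a PatternSet.

    ``series`` is (n_scans, nx, ny, nz).  Voxels outside ``mask`` are NaN
    in the output.  A rank-deficient design raises, naming the collinear
    columns.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (time first)")
    if series.shape[0] != design.n_scans:
        raise ValueError(
            f"series has {series.shape[0]} scans but design has {design.n_scans} rows"
        )
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, design.labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    shape = series.shape[1:]
    Y = series.reshape(series.shape[0], -1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match series grid")
        Y = Y[:, mask.ravel()]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    n_cond = len(design.conditions)
    data = np.full((n_cond, *shape), np.nan)
    flat = data.reshape(n_cond, -1)
    cols = beta[design.condition_cols]
    if mask is not None:
        flat[:, mask.ravel()] = cols
    else:
        flat[:] = cols
    if affine is None:
        affine = make_affine(1.0)
    return PatternSet(
        subject=subject, conditions=list(design.conditions), data=data, affine=affine
    )


def design_induced_similarity(design: DesignMatrix) -> pd.DataFrame:
    """Correlation structure among condition estimators implied by the design.

    Under OLS the beta estimators covary as σ²(XᵀX)⁻¹; restricting that
    to the condition columns and normalizing yields the condition ×
    condition correlation matrix the block-design correction needs
    (blocked designs induce correlated estimators between conditions
    sharing a block).
    """
    if len(design.condition_cols) < 2:
        raise ValueError("need at least 2 condition columns")
    X = design.matrix
    xtx = X.T @ X
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular XᵀX; design is rank deficient") from exc
    sub = cov[np.ix_(design.condition_cols, design.condition_cols)]
    d = np.sqrt(np.diag(sub))
    corr = sub / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    labels = [f"{t}:{s}" for t, s in design.conditions]
    return pd.DataFrame(corr, index=labels, columns=labels)
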