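"""Representational similarity: correlation-distance RDMs and the
per-target distinctiveness statistic, as scalars (ROI) or searchlight maps.

The statistic of interest is, for each target person, the mean pairwise
correlation distance (1 − Pearson r) among that target's state-specific
activity patterns, computed from the lower triangle of the condition
RDM.  Higher values mean the target's mental states evoke more
differentiated patterns.  The searchlight variant evaluates the
statistic in an approximately spherical neighborhood (default radius 4
voxels) centered at every in-mask voxel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from .volumes import Condition, PatternSet

__all__ = [
    "RDM",
    "DistinctivenessMap",
    "compute_rdm",
    "average_target_dissimilarity",
    "sphere_offsets",
    "searchlight_centers",
    "searchlight_distinctiveness",
    "roi_distinctiveness",
    "correct_block_structure",
]

logger = logging.getLogger(__name__)

#: searchlight neighborhoods with fewer in-mask voxels than this are
#: skipped (value undefined / NaN) and excluded from group maps.
MIN_SEARCHLIGHT_VOXELS = 30

#: a neighborhood that loses more than this fraction of conditions to
#: constant (zero-variance) patterns is skipped entirely.
MAX_DROPPED_FRACTION = 0.10

_VAR_REL_TOL = 1e-10  # relative tolerance for declaring a pattern constant


@dataclass
class RDM:
    """Labeled square matrix of pairwise pattern dissimilarities (1 − r)."""

    conditions: list[Condition]
    matrix: np.ndarray
    dropped: list[Condition] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != len(self.conditions):
            raise ValueError("label count must equal matrix dimension")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if m.size and (m.min() < -1e-10 or m.max() > 2 + 1e-10):
            raise ValueError("correlation distances must lie in [0, 2]")
        self.matrix = m

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{t}:{s}" for t, s in self.conditions]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def similarity(self) -> np.ndarray:
        """Companion similarity (Pearson r) form, unit diagonal."""
        s = 1.0 - self.matrix
        np.fill_diagonal(s, 1.0)
        return s


@dataclass
class DistinctivenessMap:
    """Per-subject, per-target mean within-target pattern dissimilarity.

    ``values`` is either a 3-D volume (searchlight) or a scalar array
    (ROI).  NaN marks voxels whose searchlight was skipped.  The
    companion mean-correlation form is r̄ = 1 − value.
    """

    subject: str | int
    target: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-8 or finite.max() > 2 + 1e-8):
            raise ValueError("distinctiveness values must lie in [0, 2]")
        self.values = v

    @property
    def mean_correlation(self) -> np.ndarray:
        return 1.0 - self.values


def compute_rdm(patterns: dict[Condition, np.ndarray] | PatternSet,
                voxel_index: np.ndarray | None = None) -> RDM:
    """Pairwise correlation-distance matrix over condition patterns.

    ``patterns`` maps conditions to 1-D vectors (or is a PatternSet, in
    which case ``voxel_index`` selects the voxels as a boolean grid mask).
    Constant (zero-variance) patterns cannot enter a Pearson correlation;
    the affected conditions are dropped and recorded in ``RDM.dropped``.
    """
    if isinstance(patterns, PatternSet):
        if voxel_index is None:
            raise ValueError("a voxel mask is required with a PatternSet input")
        mat = patterns.flatten(voxel_index)
        conditions = list(patterns.conditions)
    else:
        conditions = [tuple(c) for c in patterns]
        if len(conditions) < 2:
            raise ValueError("need at least 2 conditions")
        mat = np.asarray([np.asarray(patterns[c], dtype=float).ravel()
                          for c in conditions])
    if mat.shape[1] < 3:
        raise ValueError("patterns must have length >= 3 voxels")

    centered = mat - mat.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    scale = (mat**2).sum(axis=1)
    constant = ss <= _VAR_REL_TOL * np.maximum(scale, 1e-30)
    dropped = [c for c, bad in zip(conditions, constant) if bad]
    if dropped:
        logger.warning("dropping constant-pattern conditions: %s", dropped)
        keep = ~constant
        conditions = [c for c, ok in zip(conditions, keep) if ok]
        centered, ss = centered[keep], ss[keep]
    if len(conditions) < 2:
        raise ValueError("fewer than 2 non-constant conditions remain")

    norm = centered / np.sqrt(ss)[:, None]
    r = np.clip(norm @ norm.T, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(conditions=conditions, matrix=d, dropped=dropped)


def average_target_dissimilarity(rdm: RDM, target: str) -> float:
    """Mean of the within-target lower-triangle distances.

    Only the C(n_states, 2) unordered within-target pairs contribute;
    cross-target entries and the diagonal never do.
    """
    idx = [i for i, (t, _) in enumerate(rdm.conditions) if t == target]
    if len(idx) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 states in this RDM")
    pairs = list(combinations(idx, 2))
    return float(np.mean([rdm.matrix[i, j] for i, j in pairs]))


# ---------------------------------------------------------------------
# searchlight machinery
# ---------------------------------------------------------------------

def sphere_offsets(radius: float) -> np.ndarray:
    """Integer-lattice offsets with Euclidean norm ≤ radius, shape (k, 3)."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _neighbor_matrix(mask: np.ndarray, radius: float) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse (n_mask, n_mask) indicator of in-mask neighbors per center.

    Row i of the returned matrix marks, for the i-th in-mask voxel taken
    as a searchlight center, which in-mask voxels fall within the sphere.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)  # (n, 3)
    n = len(coords)
    flat_of = -np.ones(mask.shape, dtype=np.int64)
    flat_of[mask] = np.arange(n)
    offs = sphere_offsets(radius)
    rows, cols = [], []
    shape = mask.shape
    for off in offs:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = flat_of[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
        valid = idx >= 0
        rows.append(np.nonzero(ok)[0][valid])
        cols.append(idx[valid])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return K, coords


def searchlight_centers(
    mask: np.ndarray,
    radius: float = 4.0,
    min_voxels: int = MIN_SEARCHLIGHT_VOXELS,
) -> tuple[list[tuple[tuple[int, int, int], np.ndarray]], list[tuple[int, int, int]]]:
    """Enumerate searchlight neighborhoods over an in-mask lattice.

    Returns ``(centers, skipped)`` where ``centers`` is a list of
    ``(center_ijk, neighbor_coords)`` pairs — neighbors being the in-mask
    voxels within Euclidean distance ``radius`` (in voxel units) — and
    ``skipped`` lists centers whose neighborhood fell below
    ``min_voxels``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    K, coords = _neighbor_matrix(mask, radius)
    centers, skipped = [], []
    for i in range(len(coords)):
        nbr = coords[K.indices[K.indptr[i]: K.indptr[i + 1]]]
        c = tuple(int(x) for x in coords[i])
        if len(nbr) < min_voxels:
            skipped.append(c)
        else:
            centers.append((c, nbr))
    if skipped:
        logger.warning("skipped %d searchlights below %d voxels", len(skipped), min_voxels)
    return centers, skipped


def _within_target_pairs(conditions: list[Condition]) -> dict[str, list[tuple[int, int]]]:
    by_target: dict[str, list[int]] = {}
    for i, (t, _) in enumerate(conditions):
        by_target.setdefault(t, []).append(i)
    out = {}
    for t, idx in by_target.items():
        if len(idx) >= 2:
            out[t] = list(combinations(idx, 2))
    return out


def searchlight_distinctiveness(
    patterns: PatternSet,
    mask: np.ndarray,
    radius: float = 4.0,
    min_voxels: int = MIN_SEARCHLIGHT_VOXELS,
    neighbor_matrix: sparse.csr_matrix | None = None,
) -> dict[str, DistinctivenessMap]:
    """Whole-volume maps of mean within-target pattern dissimilarity.

    At every in-mask center, the condition RDM is computed over the
    spherical neighborhood and the within-target lower-triangle mean is
    taken per target.  Implemented with sparse neighborhood sums, which
    is algebraically identical to calling :func:`compute_rdm` per center.

    Neighborhoods below ``min_voxels``, and neighborhoods where more
    than 10% of conditions have constant patterns, are NaN.  Passing a
    precomputed ``neighbor_matrix`` (from a previous call with the same
    mask/radius) skips its reconstruction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    pair_sets = _within_target_pairs(patterns.conditions)
    if not pair_sets:
        raise ValueError("no target has >= 2 states")

    if neighbor_matrix is None:
        neighbor_matrix, _ = _neighbor_matrix(mask, radius)
    K = neighbor_matrix
    X = patterns.flatten(mask)  # (n_cond, n_vox)
    n_cond = X.shape[0]

    N = np.asarray(K @ np.ones(X.shape[1]))  # voxels per neighborhood
    S = np.asarray(K @ X.T)                  # (n_centers, n_cond) sums
    Q = np.asarray(K @ (X**2).T)             # sums of squares
    var_n = N[:, None] * Q - S**2            # n·Σx² − (Σx)², ∝ variance
    const = var_n <= _VAR_REL_TOL * np.maximum(N[:, None] * Q, 1e-30)

    small = N < min_voxels
    frac_dropped = const.mean(axis=1)
    bad_center = small | (frac_dropped > MAX_DROPPED_FRACTION)
    n_const = int((const & ~small[:, None]).any(axis=1).sum())
    if n_const:
        logger.warning("%d searchlights contained constant-pattern conditions", n_const)

    out: dict[str, DistinctivenessMap] = {}
    for target, pairs in pair_sets.items():
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        P = np.asarray(K @ (X[ia] * X[ib]).T)       # (n_centers, n_pairs)
        cov = N[:, None] * P - S[:, ia] * S[:, ib]
        denom = var_n[:, ia] * var_n[:, ib]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = cov / np.sqrt(denom)
        r = np.clip(r, -1.0, 1.0)
        d = 1.0 - r
        d[const[:, ia] | const[:, ib]] = np.nan     # pairs with a dropped condition
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(d, axis=1)
        vals[bad_center] = np.nan
        vol = np.full(mask.shape, np.nan)
        vol[mask] = vals
        out[target] = DistinctivenessMap(
            subject=patterns.subject, target=target, values=vol
        )
    return out


def roi_distinctiveness(
    patterns: PatternSet, roi_mask: np.ndarray
) -> dict[str, float]:
    """Scalar distinctiveness per target over one fixed voxel set."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() < 3:
        raise ValueError("ROI must contain at least 3 voxels")
    rdm = compute_rdm(patterns, voxel_index=roi_mask)
    pair_sets = _within_target_pairs(rdm.conditions)
    if not pair_sets:
        raise ValueError("no target has >= 2 states after RDM computation")
    return {t: average_target_dissimilarity(rdm, t) for t in pair_sets}


# ---------------------------------------------------------------------
# block-design correction
# ---------------------------------------------------------------------

def correct_block_structure(
    similarity: pd.DataFrame, induced: pd.DataFrame
) -> pd.DataFrame:
    """Residualize neural similarities on design-induced estimator correlations.

    Blocked trial designs make the beta estimators of conditions sharing
    a block correlated, which leaks into measured pattern similarity.
    The off-diagonal similarities are regressed (with intercept) on the
    matching off-diagonal induced correlations across condition pairs and
    replaced by the residuals; the diagonal is untouched.  With an
    orthogonal design (identity induced matrix) this reduces to centering
    the off-diagonals.
    """
    if list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity matrix must have matching index/columns")
    if list(similarity.index) != list(induced.index) or list(induced.index) != list(
        induced.columns
    ):
        raise ValueError("similarity and induced matrices must share labels")
    s = similarity.to_numpy(dtype=float)
    g = induced.to_numpy(dtype=float)
    n = s.shape[0]
    iu = np.triu_indices(n, k=1)
    y = s[iu]
    x = g[iu]
    if np.ptp(x) <= 1e-12:  # constant predictor: intercept-only fit
        resid = y - y.mean()
    else:
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    out = s.copy()
    out[iu] = resid
    out.T[iu] = resid
    return pd.DataFrame(out, index=similarity.index, columns=similarity.columns)
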