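"""Group-level inference on distinctiveness maps.

Implements the full map-level pipeline: Gaussian smoothing of the
per-subject maps, voxelwise paired t / repeated-measures ANOVA,
threshold-free cluster enhancement (TFCE), and family-wise error
control via maximal-statistic permutation testing (sign flips for the
paired t, within-subject target relabelings for the ANOVA), plus
ROI-level pairwise target tests with paired Cohen's d and Bonferroni
adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations as iperm

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StatMap",
    "TFCEParams",
    "PermutationScheme",
    "CorrectedPMap",
    "PairwiseComparison",
    "smooth_map",
    "paired_t_map",
    "repeated_anova_map",
    "tfce_enhance",
    "permutation_fwe",
    "pairwise_target_tests",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StatMap:
    """A voxelwise statistic volume with its degrees of freedom."""

    values: np.ndarray
    kind: str  # "t" or "F"
    df: float | tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        dfs = self.df if isinstance(self.df, tuple) else (self.df,)
        if any(d <= 0 for d in dfs):
            raise ValueError("degrees of freedom must be positive")


@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings: enhanced(v) = Σ_h e(h)^E · h^H · dh.

    Defaults are the field-standard E=0.5, H=2 with 26-connectivity and
    a step of max(stat)/100.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None → max(stat)/n_steps per map
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be nonnegative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation plan; the identity permutation is always included."""

    n_perms: int = 5000
    seed: int = 0
    kind: str = "sign-flip"  # or "target-relabel"

    def __post_init__(self) -> None:
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        if self.kind not in ("sign-flip", "target-relabel"):
            raise ValueError(f"unknown permutation kind {self.kind!r}")


@dataclass
class CorrectedPMap:
    """FWE-corrected p values from maximal-statistic permutation + TFCE."""

    p: np.ndarray
    stat: StatMap
    enhanced: np.ndarray
    null_max: np.ndarray
    scheme: PermutationScheme
    tfce: TFCEParams
    n_perms_used: int
    exhaustive: bool
    bonferroni_factor: int = 1

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.p < alpha


@dataclass
class PairwiseComparison:
    """Paired comparison of one target pair on an ROI scalar.

    ``mean_diff`` is mean(a − b) on the dissimilarity scale for pair
    (a, b); ``delta_r`` is the same difference expressed as mean pattern
    correlation r̄ = 1 − d (so delta_r = −mean_diff).
    """

    pair: tuple[str, str]
    mean_diff: float
    delta_r: float
    cohen_d: float
    t: float
    df: float
    p: float
    p_adjusted: float


# ---------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------

def smooth_map(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Separable Gaussian smoothing, σ = FWHM / (2√(2 ln 2)) per axis.

    Boundary handling is reflective, which preserves the volume's total
    mass for the symmetric kernel.  NaN voxels (e.g. skipped
    searchlights) are handled by normalized convolution: values are
    smoothed with the NaN set zero-filled and renormalized by the
    smoothed validity indicator; NaN positions stay NaN.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (volume.ndim,))
    sigma = fwhm_mm * FWHM_TO_SIGMA / vs
    valid = np.isfinite(volume)
    if valid.all():
        return ndimage.gaussian_filter(volume, sigma=sigma, mode="reflect")
    filled = np.where(valid, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="reflect")
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma, mode="reflect")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = num / den
    out[~valid] = np.nan
    return out


# ---------------------------------------------------------------------
# voxelwise statistics
# ---------------------------------------------------------------------

def _nan_or(x: np.ndarray, cond: np.ndarray) -> np.ndarray:
    x = x.copy()
    x[cond] = np.nan
    return x


def paired_t_map(maps_a: np.ndarray, maps_b: np.ndarray) -> StatMap:
    """Voxelwise paired t on within-subject differences, df = n − 1.

    Inputs are (n_subjects, ...) stacks from the same subjects on the
    same grid.  Voxels with zero-variance differences are undefined
    (NaN) and logged.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must share shape (same subjects and grid)")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        logger.warning("paired t: %d voxels with zero-variance differences", zero.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = mean / (sd / np.sqrt(n))
    return StatMap(values=_nan_or(t, zero), kind="t", df=float(n - 1))


def repeated_anova_map(maps_by_target: dict[str, np.ndarray] | np.ndarray) -> StatMap:
    """Voxelwise one-way repeated-measures F across targets.

    Input is either a dict target → (n_subjects, ...) stack or a
    (k, n_subjects, ...) array.  df = (k−1, (k−1)(n−1)).
    """
    if isinstance(maps_by_target, dict):
        data = np.stack([np.asarray(v, dtype=float) for v in maps_by_target.values()])
    else:
        data = np.asarray(maps_by_target, dtype=float)
    k, n = data.shape[0], data.shape[1]
    if k < 2:
        raise ValueError("need at least 2 levels")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean(axis=(0, 1))
    ss_cond = n * ((data.mean(axis=1) - grand) ** 2).sum(axis=0)
    ss_subj = k * ((data.mean(axis=0) - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    zero = ss_err <= 1e-300
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = (ss_cond / df1) / (ss_err / df2)
    return StatMap(values=_nan_or(f, zero), kind="F", df=(float(df1), float(df2)))


# ---------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------

def _conn_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def _tfce_pos(stat: np.ndarray, params: TFCEParams, mask: np.ndarray) -> np.ndarray:
    """Enhance the nonnegative part of a statistic volume."""
    s = np.where(mask & np.isfinite(stat), np.clip(stat, 0.0, None), 0.0)
    peak = s.max()
    out = np.zeros_like(s)
    if peak <= 0:
        return out
    structure = _conn_structure(params.connectivity)
    if params.dh is None:
        dh = peak / params.n_steps
        # exact fractions of the peak so the top threshold equals it
        heights = peak * (np.arange(1, params.n_steps + 1) / params.n_steps)
    else:
        dh = params.dh
        heights = np.arange(1, int(np.floor(peak / dh + 1e-9)) + 1) * dh
    for h in heights:
        sup = s >= h
        lab, n_lab = ndimage.label(sup, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(lab.ravel())
        out[sup] += (sizes[lab[sup]] ** params.E) * (h**params.H) * dh
    return out


def tfce_enhance(
    stat: StatMap | np.ndarray,
    params: TFCEParams = TFCEParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic volume.

    For each voxel the suprathreshold connected-component extent e(h)
    and height h are integrated over thresholds in steps of dh.
    Negative statistics are enhanced separately on −stat, and the result
    is returned signed: enhance(stat⁺) − enhance((−stat)⁺).
    """
    values = stat.values if isinstance(stat, StatMap) else np.asarray(stat, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    return _tfce_pos(values, params, mask) - _tfce_pos(-values, params, mask)


def _tfce_max_batch(
    stack: np.ndarray, params: TFCEParams, mask: np.ndarray
) -> np.ndarray:
    """Maximum enhanced value per map for a (P, nx, ny, nz) stack.

    Exploits TFCE's homogeneity: scaling a map by α scales its enhanced
    values by α^(H+1) when dh = max/n_steps scales along.  All maps are
    normalized to unit peak, enhanced jointly per threshold with a 4-D
    label whose structure never connects different maps, and rescaled.
    Identical to per-map :func:`tfce_enhance` with the default dh.
    """
    if params.dh is not None:
        return np.array(
            [_tfce_pos(m, params, mask) .max() for m in stack]
        )
    s = np.where(mask[None] & np.isfinite(stack), np.clip(stack, 0.0, None), 0.0)
    peaks = s.reshape(len(s), -1).max(axis=1)
    ok = peaks > 0
    out_max = np.zeros(len(s))
    if not ok.any():
        return out_max
    norm = s[ok] / peaks[ok][:, None, None, None]
    st4 = np.zeros((3, 3, 3, 3), dtype=bool)
    st4[1] = _conn_structure(params.connectivity)
    acc = np.zeros_like(norm)
    dh = 1.0 / params.n_steps
    for k in range(1, params.n_steps + 1):
        h = k * dh
        sup = norm >= h
        lab, n_lab = ndimage.label(sup, structure=st4)
        if n_lab == 0:
            break
        sizes = np.bincount(lab.ravel())
        acc[sup] += (sizes[lab[sup]] ** params.E) * (h**params.H) * dh
    out_max[ok] = acc.reshape(ok.sum(), -1).max(axis=1) * peaks[ok] ** (params.H + 1.0)
    return out_max


# ---------------------------------------------------------------------
# maximal-statistic permutation FWE
# ---------------------------------------------------------------------

def _sign_flips(n: int, scheme: PermutationScheme) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix, identity first and closed under negation.

    Negation closure makes the negative-tail null maximum distribution
    exactly the positive-tail one (flipping all signs negates the t
    map), so only one tail's null needs enhancing.
    """
    total = 2**n
    if total <= scheme.n_perms:
        logger.warning(
            "requested %d permutations but only %d distinct sign flips exist; "
            "enumerating exhaustively",
            scheme.n_perms,
            total,
        )
        bits = (np.arange(total)[:, None] >> np.arange(n)) & 1
        return 1.0 - 2.0 * bits, True
    rng = np.random.default_rng(scheme.seed)
    half = (scheme.n_perms - 2) // 2
    draws = rng.choice([-1.0, 1.0], size=(half, n))
    flips = np.vstack(
        [np.ones((1, n)), -np.ones((1, n)), draws, -draws]
    )[: scheme.n_perms]
    return flips, False


def _perm_t_maps(d_flat: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t maps for every sign-flip pattern; d_flat is (n, n_vox)."""
    n = d_flat.shape[0]
    ss = (d_flat**2).sum(axis=0)  # invariant under sign flips
    m = flips @ d_flat / n
    var = (ss[None] - n * m**2) / (n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = m / np.sqrt(var / n)
    t[:, var.min(axis=0) <= 0] = np.nan
    return t


def _pmap_from_null(
    obs: np.ndarray, null_max: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    srt = np.sort(null_max)
    n = len(srt)
    p = np.full(obs.shape, np.nan)
    vals = obs[mask]
    # p = (# null maxima >= observed) / n, identity included in the null set
    counts = n - np.searchsorted(srt, vals, side="left")
    p[mask] = counts / n
    return p


def permutation_fwe(
    data,
    contrast: str = "paired-t",
    tfce: TFCEParams = TFCEParams(),
    scheme: PermutationScheme = PermutationScheme(),
    mask: np.ndarray | None = None,
) -> CorrectedPMap:
    """FWE-corrected p map via maximal-statistic permutation + TFCE.

    ``contrast="paired-t"``: ``data`` is a pair (A, B) of
    (n_subjects, nx, ny, nz) stacks; the permutation group is
    per-subject sign flips of the difference maps, and the test is
    two-sided — each tail is enhanced separately, compared with its own
    null maximum distribution, and the tail p values are
    Bonferroni-combined (×2).

    ``contrast="anova"``: ``data`` is a dict target → stack (or a
    (k, n, ...) array); permutations independently relabel targets
    within each subject, and the one-sided F tail is used.

    Each voxel's corrected p is the fraction of permutations (identity
    included) whose image-wide maximum enhanced statistic reaches that
    voxel's observed enhanced value.
    """
    if contrast == "paired-t":
        a, b = data
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired stacks must share shape")
        diffs = a - b
        shape = diffs.shape[1:]
        if mask is None:
            mask = np.all(np.isfinite(diffs), axis=0)
        else:
            mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(diffs), axis=0)
        n = diffs.shape[0]
        d_flat = diffs[:, mask]
        flips, exhaustive = _sign_flips(n, scheme)
        t_flat = _perm_t_maps(d_flat, flips)
        t_flat = np.nan_to_num(t_flat, nan=0.0)

        stack = np.zeros((len(flips), *shape))
        stack[:, mask] = t_flat
        obs = stack[0]
        null_pos = _tfce_max_batch(stack, tfce, mask)
        # the flip set is negation-closed, so the multiset of negative-tail
        # maxima equals the positive-tail one exactly
        null_neg = null_pos
        enh_pos = _tfce_pos(obs, tfce, mask)
        enh_neg = _tfce_pos(-obs, tfce, mask)
        p_pos = _pmap_from_null(enh_pos, null_pos, mask)
        p_neg = _pmap_from_null(enh_neg, null_neg, mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))
        stat = StatMap(values=_nan_or(obs, ~mask), kind="t", df=float(n - 1))
        return CorrectedPMap(
            p=p,
            stat=stat,
            enhanced=enh_pos - enh_neg,
            null_max=np.maximum(null_pos, null_neg),
            scheme=scheme,
            tfce=tfce,
            n_perms_used=len(flips),
            exhaustive=exhaustive,
            bonferroni_factor=2,
        )

    if contrast != "anova":
        raise ValueError(f"unknown contrast {contrast!r}")

    if isinstance(data, dict):
        cube = np.stack([np.asarray(v, dtype=float) for v in data.values()])
    else:
        cube = np.asarray(data, dtype=float)
    k, n = cube.shape[0], cube.shape[1]
    shape = cube.shape[2:]
    if mask is None:
        mask = np.all(np.isfinite(cube), axis=(0, 1))
    else:
        mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(cube), axis=(0, 1))
    flat = cube[:, :, mask]  # (k, n, n_vox)

    n_distinct = math_factorial_pow(k, n)
    rng = np.random.default_rng(scheme.seed)
    if n_distinct <= scheme.n_perms:
        logger.warning(
            "requested %d permutations but only %d distinct relabelings exist; "
            "enumerating exhaustively",
            scheme.n_perms,
            n_distinct,
        )
        perms_list = _all_relabelings(k, n)
        exhaustive = True
    else:
        perms_list = [np.tile(np.arange(k), (n, 1))]  # identity
        for _ in range(scheme.n_perms - 1):
            perms_list.append(
                np.array([rng.permutation(k) for _ in range(n)])
            )
        exhaustive = False

    def f_of(relab: np.ndarray) -> np.ndarray:
        sel = flat[relab.T, np.arange(n)[None, :], :]  # (k, n, v)
        grand = sel.mean(axis=(0, 1))
        ss_cond = n * ((sel.mean(axis=1) - grand) ** 2).sum(axis=0)
        ss_subj = k * ((sel.mean(axis=0) - grand) ** 2).sum(axis=0)
        ss_tot = ((sel - grand) ** 2).sum(axis=(0, 1))
        ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 1e-300)
        return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))

    stack = np.zeros((len(perms_list), *shape))
    for i, relab in enumerate(perms_list):
        stack[i][mask] = f_of(relab)
    obs = stack[0]
    null_max = _tfce_max_batch(stack, tfce, mask)
    enh = _tfce_pos(obs, tfce, mask)
    p = _pmap_from_null(enh, null_max, mask)
    stat = StatMap(
        values=_nan_or(obs, ~mask),
        kind="F",
        df=(float(k - 1), float((k - 1) * (n - 1))),
    )
    return CorrectedPMap(
        p=p,
        stat=stat,
        enhanced=enh,
        null_max=null_max,
        scheme=scheme,
        tfce=tfce,
        n_perms_used=len(perms_list),
        exhaustive=exhaustive,
        bonferroni_factor=1,
    )


def math_factorial_pow(k: int, n: int) -> int:
    """Number of distinct within-subject relabelings: (k!)^n (capped)."""
    import math

    return min(math.factorial(k) ** n, 10**9)


def _all_relabelings(k: int, n: int) -> list[np.ndarray]:
    opts = [np.array(p) for p in iperm(range(k))]
    out = []

    def rec(i: int, acc: list[np.ndarray]) -> None:
        if i == n:
            out.append(np.array(acc))
            return
        for p in opts:
            rec(i + 1, acc + [p])

    rec(0, [])
    return out


# ---------------------------------------------------------------------
# ROI pairwise tests
# ---------------------------------------------------------------------

def pairwise_target_tests(
    roi_scalars: dict[str, np.ndarray],
    bonferroni_m: int | None = None,
) -> list[PairwiseComparison]:
    """Paired t tests between all target pairs on ROI distinctiveness.

    ``roi_scalars`` maps each target to its per-subject scalar
    dissimilarities (aligned across targets).  For pair (a, b):
    diff = a − b, t and two-sided p from the paired t test,
    Cohen's d = mean(diff)/sd(diff), and Δr = −mean(diff) (the same
    contrast on the mean-correlation scale r̄ = 1 − d̄).  Raw p values
    are Bonferroni-multiplied by ``bonferroni_m`` (default: the number
    of pairs), capped at 1.
    """
    targets = list(roi_scalars)
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    arrays = {t: np.asarray(v, dtype=float) for t, v in roi_scalars.items()}
    n = len(next(iter(arrays.values())))
    if any(len(v) != n for v in arrays.values()):
        raise ValueError("all targets must have the same subjects")
    pairs = list(combinations(targets, 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    out = []
    for a, b in pairs:
        diff = arrays[a] - arrays[b]
        sd = diff.std(ddof=1)
        if sd <= 0:
            if np.allclose(diff, 0):
                out.append(
                    PairwiseComparison(
                        pair=(a, b), mean_diff=0.0, delta_r=0.0, cohen_d=0.0,
                        t=0.0, df=float(n - 1), p=1.0, p_adjusted=1.0,
                    )
                )
                continue
            raise ValueError(f"zero-variance differences for pair {(a, b)}")
        mean = diff.mean()
        d = mean / sd
        t = d * np.sqrt(n)
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        out.append(
            PairwiseComparison(
                pair=(a, b),
                mean_diff=float(mean),
                delta_r=float(-mean),
                cohen_d=float(d),
                t=float(t),
                df=float(n - 1),
                p=float(p),
                p_adjusted=float(min(1.0, m * p)),
            )
        )
    return out
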