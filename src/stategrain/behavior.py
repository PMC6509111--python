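"""Mixed-effects analysis of explicit state-similarity ratings.

Participants rate, on a 6-point scale, how similar each pair of mental
states feels for a given target person.  The question is whether rated
similarity rises with the target's social distance — i.e. whether
people differentiate their own states more than others'.  The model
is::

    rating ~ target_code + (target_code | participant) + (target_code | state_pair)

a maximal random-effects structure with random intercepts and target
slopes for both participants and state pairs, Satterthwaite df for the
fixed effect, a standardized coefficient from the z-scored refit, and
marginal / conditional R² variance decompositions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import ConvergenceError, MixedLMResult, RandomTerm, fit_lmm

__all__ = [
    "LMMResult",
    "fit_state_similarity_lmm",
    "lsmeans_posthoc",
    "social_distance_composite",
    "r2_nakagawa",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = {"participant", "target", "state_i", "state_j", "rating"}


@dataclass
class LMMResult:
    """Fixed-effect estimates and fit diagnostics for the rating model.

    ``b`` is the unstandardized coefficient on the rating scale; ``beta``
    the standardized coefficient from refitting with z-scored response
    and predictor; ``df`` the Satterthwaite degrees of freedom.
    """

    fixed: pd.DataFrame  # rows: name, b, se, t, df, p
    beta_std: float
    variance_components: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    converged: bool
    singular: bool
    random_structure: str
    fallback_log: list[str] = field(default_factory=list)
    model: MixedLMResult | None = None
    model_std: MixedLMResult | None = None

    @property
    def b(self) -> float:
        return float(self.fixed.iloc[-1]["b"])

    @property
    def t(self) -> float:
        return float(self.fixed.iloc[-1]["t"])

    @property
    def df(self) -> float:
        return float(self.fixed.iloc[-1]["df"])

    @property
    def p(self) -> float:
        return float(self.fixed.iloc[-1]["p"])

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the (last) fixed slope, using its t df."""
        row = self.fixed.iloc[-1]
        half = stats.t.ppf(0.5 + level / 2.0, df=row["df"]) * row["se"]
        return float(row["b"] - half), float(row["b"] + half)


def _validate_ratings(data: pd.DataFrame) -> pd.DataFrame:
    missing = REQUIRED_COLUMNS - set(data.columns)
    if missing:
        raise ValueError(f"rating table lacks columns {sorted(missing)}")
    if (data["state_i"] == data["state_j"]).any():
        raise ValueError("self-pairs (state_i == state_j) are not allowed")
    data = data.copy()
    if "pair" not in data.columns:
        ab = np.sort(data[["state_i", "state_j"]].to_numpy(dtype=object), axis=1)
        data["pair"] = [f"{a}|{b}" for a, b in ab]
    if data.duplicated(subset=["participant", "target", "pair"]).any():
        raise ValueError("duplicate (participant, target, pair) rows")
    return data


def _codes(series: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(series))
    idx = {v: i for i, v in enumerate(levels)}
    return np.array([idx[v] for v in series]), levels


def _fixed_code(data: pd.DataFrame, fixed: str) -> tuple[np.ndarray, str]:
    targets = list(dict.fromkeys(data["target"]))
    if fixed == "self-vs-other":
        if "self" not in targets or len(targets) < 2:
            raise ValueError("self-vs-other coding needs a 'self' target plus others")
        return (data["target"] != "self").astype(float).to_numpy(), "other_vs_self"
    if fixed == "close-vs-far":
        if not {"close", "far"} <= set(targets):
            raise ValueError("close-vs-far coding needs 'close' and 'far' targets")
        sub = data["target"].map({"close": 0.0, "far": 1.0})
        if sub.isna().any():
            raise ValueError("close-vs-far coding allows only those two targets")
        return sub.to_numpy(), "far_vs_close"
    if fixed == "continuous-distance":
        if "distance" not in data.columns:
            raise ValueError(
                "continuous-distance coding needs a 'distance' column "
                "(see social_distance_composite)"
            )
        z = data["distance"].to_numpy(dtype=float)
        sd = z.std(ddof=1)
        if sd <= 0:
            raise ValueError("distance has zero variance")
        return (z - z.mean()) / sd, "distance_z"
    raise ValueError(f"unknown fixed coding {fixed!r}")


_STRUCTURES = [
    ("maximal", False, True, True),          # correlated slopes, both factors
    ("no-correlation", True, True, True),    # diagonal covariances
    ("no-pair-slope", True, False, True),    # pair: intercept only
    ("no-participant-slope", True, False, False),  # intercepts only
]


def _build_terms(
    part: np.ndarray, pair: np.ndarray, code_cols: np.ndarray,
    diagonal: bool, pair_slope: bool, part_slope: bool,
) -> list[RandomTerm]:
    n = len(part)
    ones = np.ones((n, 1))
    part_design = np.hstack([ones, code_cols]) if part_slope else ones
    pair_design = np.hstack([ones, code_cols]) if pair_slope else ones
    return [
        RandomTerm("participant", part, part_design, diagonal=diagonal),
        RandomTerm("pair", pair, pair_design, diagonal=diagonal),
    ]


def _fit_ladder(y, X, names, part, pair, code_cols, fallback_log):
    last_exc: Exception | None = None
    for label, diagonal, pair_slope, part_slope in _STRUCTURES:
        terms = _build_terms(part, pair, code_cols, diagonal, pair_slope, part_slope)
        try:
            res = fit_lmm(y, X, names, terms)
        except Exception as exc:  # numerical failure: try the next rung
            fallback_log.append(f"{label}: failed ({exc})")
            last_exc = exc
            continue
        if res.converged and not res.singular:
            return res, label
        fallback_log.append(
            f"{label}: {'singular fit' if res.singular else 'non-convergence'}"
        )
        if label == _STRUCTURES[-1][0] and res.converged:
            return res, label  # smallest structure: accept even if singular
    raise ConvergenceError(
        f"mixed model failed at every random structure; log: {fallback_log}"
    ) from last_exc


def fit_state_similarity_lmm(
    data: pd.DataFrame,
    fixed: str = "self-vs-other",
    standardize: bool = True,
) -> LMMResult:
    """Fit the state-similarity mixed model.

    ``fixed`` selects the social-distance predictor: ``"self-vs-other"``
    (0 = self, 1 = other), ``"close-vs-far"`` (0 = close, 1 = far), or
    ``"continuous-distance"`` (a z-scored composite in a ``distance``
    column).  The random structure starts maximal — intercept and target
    slope for participant and for state pair, with correlations — and
    falls back on singular fits or non-convergence by dropping
    correlations, then the pair slope, then the participant slope; every
    step is recorded.
    """
    data = _validate_ratings(data)
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if data["pair"].nunique() < 2:
        raise ValueError("need at least 2 state pairs")
    code, code_name = _fixed_code(data, fixed)
    if np.ptp(code) == 0:
        raise ValueError("fixed-effect code is constant (only one target level?)")

    y = data["rating"].to_numpy(dtype=float)
    part, _ = _codes(data["participant"])
    pair, _ = _codes(data["pair"])
    X = np.column_stack([np.ones(len(y)), code])
    names = ["intercept", code_name]
    fallback_log: list[str] = []
    res, structure = _fit_ladder(y, X, names, part, pair, code[:, None], fallback_log)

    # standardized coefficient: z-score response and predictor, refit
    res_z, beta_std = None, float("nan")
    if standardize:
        yz = (y - y.mean()) / y.std(ddof=1)
        cz = (code - code.mean()) / code.std(ddof=1)
        Xz = np.column_stack([np.ones(len(y)), cz])
        try:
            res_z, _ = _fit_ladder(yz, Xz, names, part, pair, cz[:, None], [])
            beta_std = float(res_z.beta[1])
        except ConvergenceError:
            logger.warning("standardized refit failed; reporting NaN beta")

    fixed_table = pd.DataFrame(
        {
            "name": res.fixed_names,
            "b": res.beta,
            "se": res.se,
            "t": res.t,
            "df": res.df,
            "p": res.p,
        }
    )
    r2m, r2c = _nakagawa_from_model(res, X)
    return LMMResult(
        fixed=fixed_table,
        beta_std=beta_std,
        variance_components=res.variance_components(),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=res.converged,
        singular=res.singular,
        random_structure=structure,
        fallback_log=fallback_log,
        model=res,
        model_std=res_z,
    )


# ---------------------------------------------------------------------
# R² decomposition
# ---------------------------------------------------------------------

def _nakagawa_from_model(res: MixedLMResult, X: np.ndarray) -> tuple[float, float]:
    var_fixed = float(np.var(X @ res.beta))
    var_random = 0.0
    for term in res.terms:
        cov = res.term_cov[term.name]
        W = term.design
        var_random += float(np.mean(np.einsum("ij,jk,ik->i", W, cov, W)))
    total = var_fixed + var_random + res.sigma2
    return var_fixed / total, (var_fixed + var_random) / total


def r2_nakagawa(result: LMMResult) -> tuple[float, float]:
    """Marginal and conditional R² of a fitted rating model.

    Marginal R² is the fixed-effect variance over the total (fixed +
    random + residual); conditional R² adds the random-effect variance
    to the numerator.  Random-effect variance is the average
    observation-level variance contributed by each term's covariance.
    """
    return result.r2_marginal, result.r2_conditional


# ---------------------------------------------------------------------
# post-hoc least-squares means
# ---------------------------------------------------------------------

def lsmeans_posthoc(
    data: pd.DataFrame, adjust: str = "none"
) -> pd.DataFrame:
    """Estimated marginal means per target and all pairwise contrasts.

    Refits the model with the target factor dummy coded (first level as
    reference) and the same coding in the random slopes, then reports
    each target's estimated marginal mean and every pairwise difference
    with its SE, t, Satterthwaite df and p (optionally Bonferroni
    adjusted).  In a balanced design the LS means equal the raw target
    means.
    """
    data = _validate_ratings(data)
    targets = list(dict.fromkeys(data["target"]))
    if len(targets) < 2:
        raise ValueError("need at least 2 target levels")
    y = data["rating"].to_numpy(dtype=float)
    part, _ = _codes(data["participant"])
    pair, _ = _codes(data["pair"])
    dummies = np.column_stack(
        [(data["target"] == t).astype(float) for t in targets[1:]]
    )
    X = np.column_stack([np.ones(len(y)), dummies])
    names = ["intercept"] + [f"target[{t}]" for t in targets[1:]]
    fallback_log: list[str] = []
    res, structure = _fit_ladder(y, X, names, part, pair, dummies, fallback_log)

    k = len(targets)
    L = np.zeros((k, k))  # row per target: intercept + its dummy
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    emmeans = L @ res.beta

    rows = []
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    for i, j in pairs:
        c = L[j] - L[i]
        est, se, tval, df, pval = res.contrast(c)
        p_adj = min(1.0, m * pval) if adjust == "bonferroni" else pval
        rows.append((targets[i], targets[j], emmeans[i], emmeans[j],
                     est, se, tval, df, pval, p_adj))
    out = pd.DataFrame(
        rows,
        columns=["target_a", "target_b", "emmean_a", "emmean_b",
                 "difference", "se", "t", "df", "p", "p_adjusted"],
    )
    out.attrs["emmeans"] = dict(zip(targets, emmeans))
    out.attrs["random_structure"] = structure
    return out


# ---------------------------------------------------------------------
# social-distance composite
# ---------------------------------------------------------------------

def social_distance_composite(
    scores: pd.DataFrame, as_distance: bool = False
) -> pd.DataFrame:
    """Average similarity, familiarity and closeness into one composite.

    ``scores`` has one row per participant × target with columns
    ``similarity``, ``familiarity``, ``closeness`` (higher = closer to
    self).  Returns the input plus a ``composite`` column (their
    arithmetic mean; negated when ``as_distance=True`` so larger = more
    distant) and records the mean pairwise Pearson correlation among
    the three scores in ``.attrs["mean_r"]``.
    """
    components = ["similarity", "familiarity", "closeness"]
    missing = [c for c in components if c not in scores.columns]
    if missing:
        raise ValueError(f"missing component scores: {missing}")
    vals = scores[components].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("component scores contain missing values")
    out = scores.copy()
    comp = vals.mean(axis=1)
    out["composite"] = -comp if as_distance else comp
    rs = [
        stats.pearsonr(vals[:, i], vals[:, j])[0]
        for i, j in combinations(range(3), 2)
    ]
    out.attrs["mean_r"] = float(np.mean(rs))
    return out
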