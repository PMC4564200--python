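"""Multiple-comparison families: Tukey all-pairs and Dunnett many-to-one.

Family-wise adjusted p-values are computed from the Monte-Carlo distribution
of the maximum absolute statistic under the joint multivariate-t null implied
by the fitted model (shared residual-variance estimate, contrast correlation
matrix).  With a fixed seed the adjustment is bit-reproducible; the default
draw count keeps the MC standard error on an adjusted p near 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import InvalidInputError
from .linear import LinearModelResults

DEFAULT_MC_DRAWS = 100_000
DEFAULT_SEED = 20150909


@dataclass(frozen=True)
class ContrastResult:
    """One contrast of a simultaneous family."""

    label: str
    estimate: float
    se: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    method: str  # "tukey" | "dunnett"
    mc_draws: int
    seed: int


def _max_abs_t_draws(corr: np.ndarray, df: int, mc_draws: int, seed: int) -> np.ndarray:
    """Draws of max_j |T_j| for T multivariate-t(corr, df) via a common
    chi-square scale.  Singular correlation matrices (overcomplete contrast
    families) are handled through the eigendecomposition."""
    rng = np.random.default_rng(seed)
    k = corr.shape[0]
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((mc_draws, k)) @ root.T
    if np.isfinite(df) and df > 0:
        s = np.sqrt(rng.chisquare(df, size=mc_draws) / df)
        z = z / s[:, None]
    return np.max(np.abs(z), axis=1)


def _adjust_family(estimates, ses, df, corr, labels, method,
                   mc_draws, seed) -> list[ContrastResult]:
    if mc_draws < 10_000:
        warnings.warn(
            f"mc_draws={mc_draws} below 10000; adjusted p-values will carry "
            "noticeable Monte-Carlo error",
            stacklevel=3,
        )
    tstats, p_unadj = [], []
    for est, se in zip(estimates, ses):
        if se > 0:
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), df) if df > 0 else 2.0 * stats.norm.sf(abs(t))
        else:
            t = 0.0 if est == 0 else math.inf * math.copysign(1.0, est)
            p = 1.0 if est == 0 else 0.0
        tstats.append(t)
        p_unadj.append(p)

    k = len(tstats)
    if k == 1:
        p_adj = list(p_unadj)  # a single-contrast family needs no adjustment
    else:
        maxt = _max_abs_t_draws(corr, df, mc_draws, seed)
        p_adj = [
            max(float(np.mean(maxt >= abs(t))), pu) if math.isfinite(t)
            else (0.0 if abs(t) == math.inf else 1.0)
            for t, pu in zip(tstats, p_unadj)
        ]
    return [
        ContrastResult(
            label=lab, estimate=float(est), se=float(se), statistic=float(t),
            p_unadjusted=float(pu), p_adjusted=float(pa),
            method=method, mc_draws=mc_draws, seed=seed,
        )
        for lab, est, se, t, pu, pa in zip(labels, estimates, ses, tstats, p_unadj, p_adj)
    ]


def _level_contrast_rows(results: LinearModelResults, factor: str):
    design = results.design
    if factor not in design.categories:
        raise InvalidInputError(
            f"factor {factor!r} is not a categorical term of the fitted model"
        )
    levels, _ = design.categories[factor]
    rows = {}
    for lvl in levels:
        a = design.baseline_assignments()
        a[factor] = {lvl: 1.0}
        rows[lvl] = design.row(a)
    return levels, rows


def _family_from_contrast_matrix(results, contrasts, labels, method, mc_draws, seed):
    cov = results.cov_params.to_numpy()
    beta = results.params.to_numpy()
    C = np.vstack(contrasts)
    est = C @ beta
    V = C @ cov @ C.T
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    denom = np.outer(se, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, V / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    return _adjust_family(est, se, results.df_resid, corr, labels, method,
                          mc_draws, seed)


def tukey_contrasts(results: LinearModelResults, factor: str,
                    mc_draws: int = DEFAULT_MC_DRAWS,
                    seed: int = DEFAULT_SEED) -> list[ContrastResult]:
    """All pairwise level contrasts of ``factor`` with family-wise MC-adjusted p.

    Estimates are differences of covariate-adjusted level means (covariates
    cancel in the difference for additive models).
    """
    levels, rows = _level_contrast_rows(results, factor)
    if len(levels) < 2:
        raise InvalidInputError(f"factor {factor!r} needs at least 2 levels")
    contrasts, labels = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            contrasts.append(rows[levels[j]] - rows[levels[i]])
            labels.append(f"{levels[j]} - {levels[i]}")
    return _family_from_contrast_matrix(results, contrasts, labels, "tukey",
                                        mc_draws, seed)


def dunnett_many_to_one(groups_or_results, control: str, factor: str | None = None,
                        mc_draws: int = DEFAULT_MC_DRAWS,
                        seed: int = DEFAULT_SEED) -> list[ContrastResult]:
    """Contrasts of every non-control group against a control group.

    Accepts either a fitted :class:`LinearModelResults` (with ``factor``
    naming the term whose levels are compared) or a mapping
    ``{label: array-of-values}`` treated as a one-way layout with a pooled
    variance estimate.  Family adjustment is the same MC multivariate-t
    machinery as :func:`tukey_contrasts`.
    """
    if isinstance(groups_or_results, LinearModelResults):
        results = groups_or_results
        if factor is None:
            raise InvalidInputError("factor is required when passing a fitted model")
        levels, rows = _level_contrast_rows(results, factor)
        if control not in levels:
            raise InvalidInputError(
                f"control level {control!r} not among {', '.join(levels)}"
            )
        contrasts, labels = [], []
        for lvl in levels:
            if lvl == control:
                continue
            contrasts.append(rows[lvl] - rows[control])
            labels.append(f"{lvl} - {control}")
        return _family_from_contrast_matrix(results, contrasts, labels, "dunnett",
                                            mc_draws, seed)

    groups = {k: np.asarray(v, dtype=float) for k, v in groups_or_results.items()}
    if control not in groups:
        raise InvalidInputError(
            f"control group {control!r} not among {', '.join(groups)}"
        )
    if any(g.size < 2 for g in groups.values()):
        raise InvalidInputError("every group needs at least 2 observations")
    labels_all = [k for k in groups if k != control]
    ns = {k: g.size for k, g in groups.items()}
    n_total = sum(ns.values())
    k_groups = len(groups)
    df = n_total - k_groups
    pooled = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups.values()) / df

    est = np.array([groups[k].mean() - groups[control].mean() for k in labels_all])
    se = np.sqrt(pooled * np.array([1.0 / ns[k] + 1.0 / ns[control] for k in labels_all]))
    m = len(labels_all)
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if se[i] > 0 and se[j] > 0:
                corr[i, j] = corr[j, i] = (pooled / ns[control]) / (se[i] * se[j])
    return _adjust_family(
        est, se, df, corr, [f"{k} - {control}" for k in labels_all],
        "dunnett", mc_draws, seed,
    )
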