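"""Ordinary least squares / ANCOVA with mass-adjusted means and stepwise AIC.

The model layer follows the Model → fit() → Results convention: build a
:class:`LinearModel` from a DataFrame and a formula, call :meth:`fit`, and
work with the returned :class:`LinearModelResults` (coefficients, covariance,
``summary()``, adjusted means).  Everything is computed directly from the
least-squares solution — no model-fitting library underneath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import InvalidInputError
from .design import DesignInfo, build_design, parse_formula

_LOG_2PI = math.log(2.0 * math.pi)


class LinearModel:
    """Gaussian linear model (OLS / ANCOVA) specified by a formula.

    Parameters
    ----------
    data : DataFrame
        One row per observation; rows with a missing response are dropped.
    formula : str
        e.g. ``"rmr_kj_d ~ mass_kg + season"``.
    references : dict, optional
        Factor reference levels overriding the package defaults.
    """

    def __init__(self, data: pd.DataFrame, formula: str, references: dict | None = None):
        response, terms = parse_formula(formula)
        if response not in data.columns:
            raise InvalidInputError(f"response {response!r} not found in the data")
        data = data.loc[data[response].notna()].reset_index(drop=True)
        self.formula = formula
        self.response = response
        self.terms = terms
        self.data = data
        self.exog, self.design = build_design(data, terms, references)
        self.endog = data[response].to_numpy(dtype=float)
        n, p = self.exog.shape
        if n <= p:
            raise InvalidInputError(
                f"n={n} observations cannot identify {p} coefficients"
            )
        rank = np.linalg.matrix_rank(self.exog)
        if rank < p:
            # name the columns that add no rank, via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(self.exog, mode="economic", pivoting=True)
            bad = [self.design.column_names[piv[i]] for i in range(rank, p)]
            raise InvalidInputError(
                f"design matrix is rank deficient; collinear terms: {', '.join(bad)}"
            )

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, **kw) -> "LinearModel":
        return cls(data, formula, **kw)

    def fit(self) -> "LinearModelResults":
        X, y = self.exog, self.endog
        n, p = X.shape
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df_resid = n - p
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        # Full Gaussian log-likelihood at the MLE variance (RSS/n), so the AIC
        # matches the standard definition; only AIC differences matter for
        # selection, where the constant cancels.
        loglik = -0.5 * n * (_LOG_2PI + math.log(rss / n) + 1.0)
        aic = -2.0 * loglik + 2.0 * (p + 1)
        return LinearModelResults(
            model=self,
            params=pd.Series(beta, index=self.design.column_names),
            cov_params=pd.DataFrame(
                sigma2 * xtx_inv,
                index=self.design.column_names,
                columns=self.design.column_names,
            ),
            sigma2=sigma2,
            df_resid=df_resid,
            n=n,
            r2=r2,
            aic=float(aic),
            loglik=float(loglik),
            resid=resid,
        )


@dataclass
class LinearModelResults:
    """Estimates, uncertainty and diagnostics of a fitted linear model."""

    model: LinearModel
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    df_resid: int
    n: int
    r2: float
    aic: float
    loglik: float
    resid: np.ndarray

    @property
    def design(self) -> DesignInfo:
        return self.model.design

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df_resid),
            index=self.params.index,
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params.to_numpy()

    def predict_row(self, assignments: dict) -> tuple[float, float]:
        """Fitted value and SE at one design-row assignment."""
        x = self.design.row(assignments)
        est = float(x @ self.params.to_numpy())
        se = float(math.sqrt(max(x @ self.cov_params.to_numpy() @ x, 0.0)))
        return est, se

    def summary(self) -> str:
        lines = [
            f"Linear model: {self.model.formula}",
            f"n = {self.n}, residual df = {self.df_resid}, "
            f"R² = {self.r2:.4f}, AIC = {self.aic:.2f}",
            f"residual SD = {math.sqrt(self.sigma2):.4g}",
            "",
            f"{'term':<28}{'estimate':>12}{'SE':>12}{'t':>9}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class AdjustedMeanTable:
    """Factor-level means predicted at a common covariate value.

    ``means`` maps level → (adjusted mean, standard error).  ``evaluated_at``
    records the covariate values used (numeric grand means unless
    overridden), so the table is self-describing.
    """

    factor: str
    means: dict
    evaluated_at: dict
    n_by_level: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"level": lvl, "adjusted_mean": m, "se": se,
                 "n": self.n_by_level.get(lvl)}
                for lvl, (m, se) in self.means.items()
            ]
        )


def adjusted_means(results: LinearModelResults, factor: str,
                   at_mass: float | None = None,
                   mass_var: str = "mass_kg") -> AdjustedMeanTable:
    """Mass-adjusted (covariate-adjusted) means ± SE per level of ``factor``.

    Each level's mean is the fitted response with the factor set to that
    level, numeric covariates at their grand means over the fitted data
    (``at_mass`` overrides the body-mass covariate), and any *other* factors
    averaged over at their observed level proportions.  The SE comes from the
    coefficient covariance of the corresponding linear combination.
    """
    design = results.design
    if factor not in design.categories:
        raise InvalidInputError(
            f"factor {factor!r} is not a categorical term of the fitted model"
        )
    overrides = {}
    if at_mass is not None:
        if not at_mass > 0:
            raise InvalidInputError(f"at_mass must be positive, got {at_mass!r}")
        if mass_var not in design.numeric_means:
            raise InvalidInputError(
                f"covariate {mass_var!r} is not a numeric term of the fitted model"
            )
        overrides[mass_var] = at_mass

    levels, _ = design.categories[factor]
    counts = results.model.data[factor].astype(str).value_counts()
    means = {}
    for lvl in levels:
        a = design.baseline_assignments(overrides)
        a[factor] = {lvl: 1.0}
        means[lvl] = results.predict_row(a)
    evaluated_at = dict(design.numeric_means)
    evaluated_at.update(overrides)
    return AdjustedMeanTable(
        factor=factor,
        means=means,
        evaluated_at=evaluated_at,
        n_by_level={lvl: int(counts.get(lvl, 0)) for lvl in levels},
    )


def stepwise_aic(data: pd.DataFrame, response: str, candidates: list[str],
                 include: tuple = (), references: dict | None = None):
    """Bidirectional stepwise selection minimising AIC.

    Starts from the intercept-only model (plus any forced ``include`` terms)
    and repeatedly applies the single add/drop move that lowers AIC most,
    respecting marginality: an interaction ``a:b`` can only enter once both
    main effects are present, and a main effect cannot leave while an
    interaction containing it remains.  Deterministic given the data — ties
    are broken alphabetically by term.

    Returns
    -------
    (results, trace) : LinearModelResults, list[dict]
        Final fit and the visited path as ``{"action", "term", "aic"}`` steps.
    """
    if not candidates:
        raise InvalidInputError("candidate term set is empty")

    def _fit(terms):
        rhs = " + ".join(terms) if terms else "1"
        return LinearModel(data, f"{response} ~ {rhs}", references=references).fit()

    current = list(include)
    res = _fit(current)
    trace = [{"action": "start", "term": "", "aic": res.aic}]
    while True:
        moves = []
        for term in sorted(candidates):
            if term in current:
                continue
            parts = term.split(":")
            if len(parts) > 1 and not all(p in current for p in parts):
                continue
            moves.append(("add", term, current + [term]))
        for term in sorted(current):
            if term in include:
                continue
            if any(term in t.split(":") for t in current if t != term and ":" in t):
                continue
            moves.append(("drop", term, [t for t in current if t != term]))
        best = None
        for action, term, terms in moves:
            cand = _fit(terms)
            if cand.aic < res.aic - 1e-9 and (best is None or cand.aic < best[3].aic):
                best = (action, term, terms, cand)
        if best is None:
            break
        action, term, current, res = best
        trace.append({"action": action, "term": term, "aic": res.aic})
    return res, trace
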