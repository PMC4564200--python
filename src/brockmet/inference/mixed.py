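"""One-factor random-intercept linear mixed model fitted by REML.

The model is ``y = Xβ + b_g + ε`` with a random intercept ``b_g ~ N(0, σ_b²)``
per group (here: repeated measurements on the same animal) and residual
``ε ~ N(0, σ_e²)``.  The REML criterion is profiled down to a one-dimensional
optimisation over the variance ratio λ = σ_b²/σ_e²: for a given λ the fixed
effects are the GLS solution and σ_e² has a closed form, and the block
structure of ``V = I + λ·ZZᵀ`` makes every quantity a per-group sum — no
general matrix inversion is needed.  At λ = 0 the fit collapses exactly to
ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..errors import InvalidInputError
from .design import build_design, parse_formula

_LOG_2PI = math.log(2.0 * math.pi)


class RandomInterceptModel:
    """``response ~ fixed terms + (1 | group)`` specified on a DataFrame.

    Parameters
    ----------
    data : DataFrame
    formula : str
        Fixed-effects formula, e.g. ``"rmr_kj_d ~ mass_kg + state"``.
    group : str
        Column identifying the grouping factor (e.g. ``"animal_id"``).
    """

    def __init__(self, data: pd.DataFrame, formula: str, group: str,
                 references: dict | None = None):
        response, terms = parse_formula(formula)
        if group not in data.columns:
            raise InvalidInputError(f"group column {group!r} not found in the data")
        data = data.loc[data[response].notna()].reset_index(drop=True)
        self.formula = formula
        self.group = group
        self.data = data
        self.exog, self.design = build_design(data, terms, references)
        self.endog = data[response].to_numpy(dtype=float)
        codes, self.group_labels = pd.factorize(data[group].astype(str))
        self.group_codes = codes
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise InvalidInputError("need at least 2 groups for a random intercept")
        self._sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        if not np.any(self._sizes >= 2):
            warnings.warn(
                "all groups are singletons; between-group variance is not "
                "identifiable and the fit reduces to OLS",
                stacklevel=2,
            )

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, group: str, **kw):
        return cls(data, formula, group, **kw)

    # -- profiled REML pieces ------------------------------------------------

    def _gls(self, lam: float):
        """GLS β, REML σ̂², and the profiled restricted log-likelihood at λ."""
        X, y, g = self.exog, self.endog, self.group_codes
        n, p = X.shape
        shrink = lam / (1.0 + lam * self._sizes)  # per-group V⁻¹ rank-1 weight

        sx = np.zeros((self.n_groups, p))
        sy = np.zeros(self.n_groups)
        np.add.at(sx, g, X)
        np.add.at(sy, g, y)
        xtvx = X.T @ X - (sx * shrink[:, None]).T @ sx
        xtvy = X.T @ y - sx.T @ (shrink * sy)
        beta = np.linalg.solve(xtvx, xtvy)
        r = y - X @ beta
        sr = np.zeros(self.n_groups)
        np.add.at(sr, g, r)
        rvr = float(r @ r - shrink @ sr**2)
        sigma2 = rvr / (n - p)
        logdet_v = float(np.sum(np.log1p(lam * self._sizes)))
        sign, logdet_xvx = np.linalg.slogdet(xtvx)
        loglik = -0.5 * (
            (n - p) * (math.log(sigma2) + 1.0 + _LOG_2PI)
            + logdet_v
            + logdet_xvx
        )
        return beta, sigma2, xtvx, loglik, sr, shrink

    def fit(self) -> "RandomInterceptResults":
        # optimise over log-λ with an explicit λ=0 boundary check
        def neg(loglam):
            return -self._gls(math.exp(loglam))[3]

        res = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam_hat = math.exp(res.x)
        ll_hat = -res.fun
        ll0 = self._gls(0.0)[3]
        if ll0 >= ll_hat:
            lam_hat, ll_hat = 0.0, ll0

        beta, sigma2, xtvx, loglik, sr, shrink = self._gls(lam_hat)
        cov = sigma2 * np.linalg.inv(xtvx)
        # b̂_g = λ·n_g·r̄_g/(1 + λ·n_g) = shrink_g · Σ r_g
        blups = shrink * sr
        names = self.design.column_names
        return RandomInterceptResults(
            model=self,
            fe_params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            sigma2_between=lam_hat * sigma2,
            sigma2_resid=sigma2,
            variance_ratio=lam_hat,
            n=len(self.endog),
            n_groups=self.n_groups,
            df_resid=len(self.endog) - len(names),
            loglik_reml=float(loglik),
            random_effects=pd.Series(blups, index=list(self.group_labels)),
        )


@dataclass
class RandomInterceptResults:
    """REML estimates: fixed effects, variance components, BLUPs."""

    model: RandomInterceptModel
    fe_params: pd.Series
    cov_params: pd.DataFrame
    sigma2_between: float
    sigma2_resid: float
    variance_ratio: float
    n: int
    n_groups: int
    df_resid: int
    loglik_reml: float
    random_effects: pd.Series

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.fe_params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.fe_params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Wald p-values on a t reference with n − p denominator df.

        The exact small-sample df for mixed models is convention-dependent;
        the residual-df choice used here is conservative relative to a normal
        reference and is stated in the summary.
        """
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df_resid),
            index=self.fe_params.index,
        )

    def summary(self) -> str:
        lines = [
            f"Random-intercept model (REML): {self.model.formula} "
            f"+ (1 | {self.model.group})",
            f"n = {self.n} observations, {self.n_groups} groups",
            f"between-group SD = {math.sqrt(self.sigma2_between):.4g}, "
            f"residual SD = {math.sqrt(self.sigma2_resid):.4g}, "
            f"REML loglik = {self.loglik_reml:.2f}",
            f"Wald tests on t({self.df_resid})",
            "",
            f"{'term':<28}{'estimate':>12}{'SE':>12}{'t':>9}{'p':>10}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"{name:<28}{self.fe_params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)
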