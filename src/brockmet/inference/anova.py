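"""Welch-corrected one-way analysis of variance.

Welch's F test compares group means without assuming equal variances: groups
are weighted by ``n/s²`` and the denominator degrees of freedom follow the
Welch–Satterthwaite approximation.  With equal group variances and sizes it
coincides with the classical one-way ANOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import InvalidInputError


@dataclass(frozen=True)
class WelchAnovaResult:
    f: float
    df1: float
    df2: float
    p: float

    def __iter__(self):  # allow tuple unpacking (f, df1, df2, p)
        return iter((self.f, self.df1, self.df2, self.p))


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA across ``groups``.

    Parameters
    ----------
    groups : sequence of array-like
        At least two groups, each with ≥ 2 observations and positive variance.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InvalidInputError("welch_anova needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise InvalidInputError("every group needs at least 2 observations")
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.any(v <= 0):
        raise InvalidInputError(
            "a group has zero variance; Welch weights are undefined"
        )
    k = len(gs)
    w = n / v
    sw = w.sum()
    grand = float((w * m).sum() / sw)
    a = float((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = float((((1.0 - w / sw) ** 2) / (n - 1.0)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    f = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return WelchAnovaResult(f=float(f), df1=df1, df2=float(df2), p=p)
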