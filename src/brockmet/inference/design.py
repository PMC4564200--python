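"""Design-matrix construction from a minimal formula language.

Supports what the study's models need: a numeric response regressed on
numeric covariates, treatment-coded factors, and pairwise interactions
(``y ~ mass_kg + season + mass_kg:season``).  Factors are dummy-coded against
a stated reference level; the defaults follow the study conventions (summer,
before-anaesthesia, female, adult) and are overridable per model.

The :class:`DesignInfo` produced alongside the matrix can evaluate a single
design *row* from an assignment of covariate values and factor-level weights,
which is what adjusted means and contrast vectors are built from: a factor
level is an indicator weight of 1, while "average over the other factors"
uses the observed level proportions as fractional weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidInputError, VocabularyError

SEASONS = ("summer", "autumn", "winter")
STATES = ("before", "during", "after", "none")
SEXES = ("M", "F")
AGE_CLASSES = ("cub", "adult")

#: Default reference levels for treatment coding.
DEFAULT_REFERENCES = {
    "season": "summer",
    "state": "before",
    "sex": "F",
    "age_class": "adult",
}


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's metadata and (optionally) its measured RMR."""

    id: str
    sex: str
    age_class: str
    season: str
    mass_kg: float
    state: str = "none"
    rmr_kj_d: float | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise VocabularyError(f"sex={self.sex!r}; allowed: {', '.join(SEXES)}")
        if self.age_class not in AGE_CLASSES:
            raise VocabularyError(
                f"age_class={self.age_class!r}; allowed: {', '.join(AGE_CLASSES)}"
            )
        if self.season not in SEASONS:
            raise VocabularyError(f"season={self.season!r}; allowed: {', '.join(SEASONS)}")
        if self.state not in STATES:
            raise VocabularyError(f"state={self.state!r}; allowed: {', '.join(STATES)}")
        if not self.mass_kg > 0:
            raise InvalidInputError(f"mass_kg must be positive, got {self.mass_kg!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Animal records → tidy DataFrame with one row per record."""
    return pd.DataFrame(
        {
            "animal_id": [r.id for r in records],
            "sex": [r.sex for r in records],
            "age_class": [r.age_class for r in records],
            "season": [r.season for r in records],
            "mass_kg": [r.mass_kg for r in records],
            "state": [r.state for r in records],
            "rmr_kj_d": [r.rmr_kj_d for r in records],
        }
    )


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """``"y ~ a + b + a:b"`` → (response, [terms]).  ``"y ~ 1"`` → (y, [])."""
    if "~" not in formula:
        raise InvalidInputError(f"formula {formula!r} lacks '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not response:
        raise InvalidInputError(f"formula {formula!r} lacks a response")
    terms = []
    for raw in rhs.split("+"):
        term = ":".join(p.strip() for p in raw.strip().split(":"))
        if term in ("", "1"):
            continue
        if term not in terms:
            terms.append(term)
    return response, terms


@dataclass
class DesignInfo:
    """Column bookkeeping for a fitted design matrix.

    Each column is a product of components; a component is ``(var, None)``
    for a numeric variable or ``(var, level)`` for a factor indicator.
    """

    terms: list
    columns: list  # [(name, [(var, level_or_None), ...]), ...]
    categories: dict  # var -> (levels tuple, reference)
    numeric_means: dict = field(default_factory=dict)
    level_props: dict = field(default_factory=dict)  # var -> {level: proportion}

    @property
    def column_names(self) -> list:
        return [name for name, _ in self.columns]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.empty((n, len(self.columns)))
        for j, (_, comps) in enumerate(self.columns):
            col = np.ones(n)
            for var, level in comps:
                if level is None:
                    col = col * df[var].to_numpy(dtype=float)
                else:
                    col = col * (df[var].astype(str).to_numpy() == level).astype(float)
            X[:, j] = col
        return X

    def row(self, assignments: dict) -> np.ndarray:
        """One design row from var → value (numeric) or var → {level: weight}."""
        x = np.empty(len(self.columns))
        for j, (_, comps) in enumerate(self.columns):
            v = 1.0
            for var, level in comps:
                a = assignments[var]
                if level is None:
                    v *= float(a)
                else:
                    v *= float(a.get(level, 0.0))
            x[j] = v
        return x

    def baseline_assignments(self, overrides: dict | None = None) -> dict:
        """Effects-style evaluation point: numeric vars at their training
        means, factors at their observed level proportions."""
        a = {var: mean for var, mean in self.numeric_means.items()}
        a.update({var: dict(props) for var, props in self.level_props.items()})
        if overrides:
            a.update(overrides)
        return a


def build_design(df: pd.DataFrame, terms: list[str],
                 references: dict | None = None) -> tuple[np.ndarray, DesignInfo]:
    """Build the intercepted design matrix for ``terms`` over ``df``.

    Factors (non-numeric columns) are treatment-coded; the reference level
    comes from ``references``, falling back to :data:`DEFAULT_REFERENCES`,
    falling back to the first level in sorted order.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)

    variables: list[str] = []
    for term in terms:
        for var in term.split(":"):
            if var not in df.columns:
                raise InvalidInputError(f"variable {var!r} not found in the data")
            if var not in variables:
                variables.append(var)

    categories, numeric_means, level_props = {}, {}, {}
    for var in variables:
        if pd.api.types.is_numeric_dtype(df[var]):
            numeric_means[var] = float(df[var].mean())
        else:
            levels = sorted(df[var].astype(str).unique())
            ref = refs.get(var, levels[0])
            if ref not in levels:
                ref = levels[0]
            ordered = (ref,) + tuple(l for l in levels if l != ref)
            categories[var] = (ordered, ref)
            counts = df[var].astype(str).value_counts(normalize=True)
            level_props[var] = {l: float(counts.get(l, 0.0)) for l in ordered}

    columns = [("Intercept", [])]
    for term in terms:
        comp_sets = []
        for var in term.split(":"):
            if var in categories:
                levels, ref = categories[var]
                comp_sets.append([(var, l) for l in levels if l != ref])
            else:
                comp_sets.append([(var, None)])
        # cartesian product of component choices
        combos = [[]]
        for choices in comp_sets:
            combos = [c + [ch] for c in combos for ch in choices]
        for comps in combos:
            name = ":".join(
                var if level is None else f"{var}[{level}]" for var, level in comps
            )
            columns.append((name, comps))

    info = DesignInfo(
        terms=list(terms),
        columns=columns,
        categories=categories,
        numeric_means=numeric_means,
        level_props=level_props,
    )
    return info.matrix(df), info
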