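"""Richness regressions and variance partitioning.

Species richness per territorial unit is screened against each predictor
with linear, quadratic and cubic polynomial fits (area as its natural
logarithm), significant terms per predictor *set* — area (A), environment
(E), spatial position (S) — are pruned by backward stepwise elimination,
and the explained variance of the seven set-combination models (A, E, S,
A+E, A+S, E+S, A+E+S) is decomposed by inclusion–exclusion into unique and
shared fractions.  Shared fractions may be negative; that is a documented
property of R^2-based partitioning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_io import SiteTable

__all__ = [
    "Term",
    "RegressionModel",
    "PartitionResult",
    "polynomial_screen",
    "backward_stepwise",
    "fit_terms",
    "partition_richness",
    "SET_KEYS",
    "FRACTION_KEYS",
]

SET_KEYS = ("A", "E", "S", "A+E", "A+S", "E+S", "A+E+S")
FRACTION_KEYS = ("A", "E", "S", "A&E", "A&S", "E&S", "A&E&S", "residual")

# predictor sets as published: area alone, environment, spatial position
SET_A = ("log(Area)",)
SET_E = ("Alt", "Alt_ran", "T_ann", "T_ran", "T_max", "T_min",
         "P_ann", "P_ran", "P_dri", "P_drn")
SET_S = ("Long", "Long_min", "Long_max", "Long_ran",
         "Lat", "Lat_min", "Lat_max", "Lat_ran")


@dataclass(frozen=True, order=True)
class Term:
    """One design column: a predictor raised to a degree, or its log."""

    variable: str
    degree: int = 1        # 1..3
    log: bool = False      # natural log of the raw variable (degree ignored)

    def label(self) -> str:
        if self.log:
            return f"log({self.variable})"
        return self.variable if self.degree == 1 else f"{self.variable}^{self.degree}"

    def column(self, table: SiteTable) -> np.ndarray:
        v = table[self.variable]
        if self.log:
            if (v <= 0).any():
                raise ValueError(f"log of non-positive {self.variable}")
            return np.log(v)
        return v ** self.degree


def _design(table: SiteTable, terms: Sequence[Term]) -> np.ndarray:
    cols = [t.column(table) for t in terms]
    return sm.add_constant(np.column_stack(cols)) if cols else np.ones((table.n_sites, 1))


@dataclass(frozen=True)
class RegressionModel:
    """An OLS fit of richness on a set of polynomial terms."""

    response: str
    terms: tuple[Term, ...]
    function: str                  # "linear (+)", "quadratic (+,-)", "ns", ...
    coefficients: tuple[float, ...]
    variance_pct: float            # unadjusted R^2 x 100
    adj_variance_pct: float
    F: float
    df: tuple[int, int]
    p: float
    term_p: tuple[float, ...] = ()

    def to_report_rows(self):
        return [{
            "Variable": " + ".join(t.label() for t in self.terms) or "(intercept)",
            "Function": self.function,
            "Variance (%)": self.variance_pct,
            "F": self.F,
            "d.f.": f"{self.df[0]}; {self.df[1]}",
            "p": self.p,
        }]


def fit_terms(
    richness: np.ndarray, table: SiteTable, terms: Sequence[Term],
    response: str = "richness", function: str = "",
) -> RegressionModel:
    """Plain OLS of richness on the given terms (with intercept).

    Aliased (rank-deficient) columns are dropped with a warning, keeping the
    earliest occurrence of each direction.
    """
    y = np.asarray(richness, dtype=float)
    terms = list(terms)
    X = _design(table, terms)
    # drop aliased columns (keep first of each linearly dependent group)
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        elif j > 0:
            warnings.warn(f"dropping aliased term {terms[j - 1].label()}")
    terms = [terms[j - 1] for j in keep if j > 0]
    X = X[:, keep]
    res = sm.OLS(y, X).fit()
    q = X.shape[1] - 1
    n = len(y)
    if q == 0:
        return RegressionModel(response, (), function or "intercept-only",
                               tuple(res.params), 0.0, 0.0, 0.0, (0, n - 1), 1.0)
    return RegressionModel(
        response=response,
        terms=tuple(terms),
        function=function,
        coefficients=tuple(res.params),
        variance_pct=100.0 * res.rsquared,
        adj_variance_pct=100.0 * res.rsquared_adj,
        F=float(res.fvalue),
        df=(q, n - q - 1),
        p=float(res.f_pvalue),
        term_p=tuple(res.pvalues[1:]),
    )


def _sign_pattern(coefs: Sequence[float]) -> str:
    return ",".join("+" if c >= 0 else "-" for c in coefs)


def polynomial_screen(
    richness: np.ndarray,
    table: SiteTable,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    max_degree: int = 3,
    log_variables: Sequence[str] = ("Area",),
) -> list[RegressionModel]:
    """Screen every predictor independently with polynomial fits.

    For each variable, degrees 1..max_degree are fitted and the highest
    degree whose top-order coefficient is significant at ``alpha`` is
    reported ("linear (-)", "quadratic (+,-)", ...); if no degree qualifies
    the linear fit is reported as "ns".  Variables in ``log_variables``
    (area by default) enter as natural logs, reported "logarithmic".
    Constant predictors are skipped with a warning.
    """
    y = np.asarray(richness, dtype=float)
    if len(y) != table.n_sites:
        raise ValueError("richness vector not aligned with the site table")
    if variables is None:
        variables = [c for c in table.data.columns if c in
                     set(SET_A) | set(SET_E) | set(SET_S) | {"Area"}]
    out: list[RegressionModel] = []
    for var in variables:
        v = table[var]
        if np.ptp(v) == 0:
            warnings.warn(f"skipping constant predictor {var!r}")
            continue
        if var in log_variables:
            m = fit_terms(y, table, [Term(var, log=True)], function="logarithmic")
            sig = m.p < alpha
            label = f"logarithmic ({_sign_pattern(m.coefficients[1:])})" if sig else "ns"
            out.append(RegressionModel(**{**vars(m), "function": label}))
            continue
        fits = []
        for deg in range(1, max_degree + 1):
            terms = [Term(var, d) for d in range(1, deg + 1)]
            fits.append(fit_terms(y, table, terms))
        chosen = None
        for deg in range(max_degree, 0, -1):
            m = fits[deg - 1]
            if m.term_p and m.term_p[-1] < alpha:
                chosen = m
                break
        if chosen is None:
            m = fits[0]
            out.append(RegressionModel(**{**vars(m), "function": "ns"}))
        else:
            name = {1: "linear", 2: "quadratic", 3: "cubic"}[len(chosen.terms)]
            label = f"{name} ({_sign_pattern(chosen.coefficients[1:])})"
            out.append(RegressionModel(**{**vars(chosen), "function": label}))
    return out


def backward_stepwise(
    richness: np.ndarray,
    table: SiteTable,
    candidate_terms: Sequence[Term],
    alpha_stay: float = 0.05,
    response: str = "richness",
) -> RegressionModel:
    """Backward elimination: drop the worst-p term until all survive at
    ``alpha_stay``, never dropping a term that still has a higher-degree
    sibling in the model (polynomial hierarchy).  Ties break toward the
    higher degree, then lexicographically by label — deterministic.
    Returns the intercept-only model if nothing survives.
    """
    y = np.asarray(richness, dtype=float)
    terms = list(candidate_terms)
    while terms:
        model = fit_terms(y, table, terms, response=response)
        terms = list(model.terms)
        droppable = []
        for t, p in zip(terms, model.term_p):
            has_child = any(
                u.variable == t.variable and not u.log and u.degree > t.degree
                for u in terms
            )
            if not has_child:
                droppable.append((t, p))
        if not droppable:
            break
        worst_p = max(p for _, p in droppable)
        if worst_p < alpha_stay:
            break
        ties = [t for t, p in droppable if p == worst_p]
        victim = sorted(ties, key=lambda t: (-t.degree, t.label()))[0]
        terms.remove(victim)
    return fit_terms(y, table, terms, response=response,
                     function="stepwise" if terms else "intercept-only")


@dataclass(frozen=True)
class PartitionResult:
    """Unique/shared variance fractions among the A, E and S predictor sets."""

    fractions: dict            # FRACTION_KEYS -> percent of variance
    source_r2: dict            # SET_KEYS -> R^2 x 100 of each fitted model
    dropped_terms: tuple[str, ...] = ()

    def to_report_rows(self):
        return [{"Fraction": k, "Variance (%)": self.fractions[k]} for k in FRACTION_KEYS]


# rows: R^2 of A, E, S, A+E, A+S, E+S, A+E+S; columns: the 7 disjoint
# fractions A, E, S, A&E, A&S, E&S, A&E&S (membership of each fraction in
# each model's explained share)
_INCLUSION = np.array(
    [
        # A  E  S  AE AS ES AES
        [1, 0, 0, 1, 1, 0, 1],   # R2(A)
        [0, 1, 0, 1, 0, 1, 1],   # R2(E)
        [0, 0, 1, 0, 1, 1, 1],   # R2(S)
        [1, 1, 0, 1, 1, 1, 1],   # R2(A+E)
        [1, 0, 1, 1, 1, 1, 1],   # R2(A+S)
        [0, 1, 1, 1, 1, 1, 1],   # R2(E+S)
        [1, 1, 1, 1, 1, 1, 1],   # R2(A+E+S)
    ],
    dtype=float,
)


def partition_from_r2(r2: dict) -> dict:
    """Solve the inclusion–exclusion system mapping the seven model R^2
    values (percent) to the seven disjoint fractions plus the residual."""
    rhs = np.array([r2[k] for k in SET_KEYS], dtype=float)
    frac = np.linalg.solve(_INCLUSION, rhs)
    out = dict(zip(FRACTION_KEYS[:7], frac))
    out["residual"] = 100.0 - r2["A+E+S"]
    return out


def partition_richness(
    richness: np.ndarray,
    table: SiteTable,
    A_terms: Sequence[Term],
    E_terms: Sequence[Term],
    S_terms: Sequence[Term],
) -> PartitionResult:
    """Fit the seven set-combination models and decompose explained variance."""
    y = np.asarray(richness, dtype=float)
    sets = {"A": list(A_terms), "E": list(E_terms), "S": list(S_terms)}
    r2: dict = {}
    models: dict = {}
    for key in SET_KEYS:
        terms = [t for part in key.split("+") for t in sets[part]]
        m = fit_terms(y, table, terms)
        models[key] = m
        r2[key] = m.variance_pct
    return PartitionResult(fractions=partition_from_r2(r2), source_r2=r2)
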