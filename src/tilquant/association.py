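"""Association analyses: logistic regression for pCR, Kruskal-Wallis
covariate tests, and ER-stratified Cox proportional-hazards models.

The surface follows the statsmodels convention: a model object is built
from a DataFrame plus a term list, ``fit()`` returns a results object with
coefficients, Wald standard errors, exp-scale effect measures (OR or HR)
with 95% CIs and p-values, and ``summary()`` renders a table.

Coding conventions: categorical covariates are dummy-coded with the first
listed level as the reference (Negative for ER and nodes, BEV+D FEC for the
treatment arm, <=50 mm for tumour size); age and grade enter as continuous.
Missing data are handled by complete-case deletion per model, with the
per-model n reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .config import CATEGORY_LEVELS
from .errors import ContractViolation, FitError

_Z95 = scipy.stats.norm.ppf(0.975)  # 1.959964...


@dataclass
class PatientRecord:
    """One trial patient: covariates, outcome, survival and density slots."""

    patient_id: str
    age: float
    grade: float
    er_status: str
    node_status: str
    tumour_size_cat: str
    arm: str
    pcr: int
    os_time: float = float("nan")
    os_event: int = 0
    dfs_time: float = float("nan")
    dfs_event: int = 0
    pre_density: float = float("nan")
    delta_density: float = float("nan")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, terms: Sequence[str],
                 levels: Optional[dict] = None) -> pd.DataFrame:
    """Dummy-code a term list against reference categories.

    Numeric columns enter as-is; string/categorical columns produce one
    indicator per non-reference level named ``col[level]``.  The level
    order comes from ``levels`` (default: the package's clinical coding),
    falling back to sorted unique values.
    """
    levels = {**CATEGORY_LEVELS, **(levels or {})}
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        if term not in data.columns:
            raise ContractViolation(f"unknown model term {term!r}")
        col = data[term]
        if pd.api.types.is_numeric_dtype(col):
            cols[term] = col.to_numpy(dtype=float)
        else:
            lvls = list(levels.get(term) or sorted(col.dropna().unique()))
            observed = set(col.dropna().unique()) - set(lvls)
            if observed:
                raise ContractViolation(f"{term}: unexpected levels {sorted(observed)}")
            for lvl in lvls[1:]:
                cols[f"{term}[{lvl}]"] = np.where(col.isna(), np.nan,
                                                  (col == lvl).astype(float))
    return pd.DataFrame(cols, index=data.index)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResults:
    """A fitted logistic model: log-odds scale estimates and OR table."""

    terms: list[str]
    params: np.ndarray  # log-odds, intercept first
    bse: np.ndarray
    n_observations: int
    converged: bool
    llf: float = float("nan")
    outcome: str = "pcr"
    flag: Optional[str] = None  # e.g. "perfect_separation", "constant_outcome"

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params[1:])

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.params[1:] - _Z95 * self.bse[1:])
        hi = np.exp(self.params[1:] + _Z95 * self.bse[1:])
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params[1:] / self.bse[1:]
        return 2.0 * scipy.stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.params[1:],
                "se": self.bse[1:],
                "odds_ratio": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": self.pvalues,
                "n": self.n_observations,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Logistic regression of {self.outcome}  "
            f"(n = {self.n_observations}, converged = {self.converged})"
        ]
        if self.flag:
            lines.append(f"flag: {self.flag}")
        if self.converged:
            lines.append(format_fit_table(self).to_string(index=False))
        return "\n".join(lines)


class LogisticModel:
    """Maximum-likelihood logistic regression of a binary outcome.

    Thin, convention-enforcing wrapper around statsmodels' Newton solver:
    complete-case deletion, reference-category dummy coding, Wald CIs
    exp(beta +/- 1.96 SE), and explicit non-convergence flags for perfect
    separation or a constant outcome.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms: Sequence[str],
                 levels: Optional[dict] = None):
        if len(terms) < 1:
            raise ContractViolation("need at least one model term")
        self.outcome = outcome
        self.term_spec = list(terms)
        design = build_design(data, terms, levels)
        y = data[outcome].to_numpy(dtype=float)
        keep = np.isfinite(y) & np.isfinite(design.to_numpy(dtype=float)).all(axis=1)
        self._y = y[keep]
        self._X = design.to_numpy(dtype=float)[keep]
        self.terms = list(design.columns)
        if len(self._y) < len(self.terms) + 1:
            raise FitError(
                f"only {len(self._y)} complete cases for {len(self.terms)} terms"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str = "pcr",
                       terms: Sequence[str] = ("pre_density",), **kw) -> "LogisticModel":
        return cls(data, outcome, terms, **kw)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> LogisticResults:
        y, X = self._y, self._X
        n = len(y)
        k = X.shape[1] + 1
        if len(np.unique(y)) < 2:
            return LogisticResults(self.terms, np.full(k, np.nan), np.full(k, np.nan),
                                   n, converged=False, outcome=self.outcome,
                                   flag="constant_outcome")
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.Logit(y, Xc)
        try:
            with np.errstate(all="ignore"):
                res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0,
                                warn_convergence=False)
        except Exception:
            return LogisticResults(self.terms, np.full(k, np.nan), np.full(k, np.nan),
                                   n, converged=False, outcome=self.outcome,
                                   flag="perfect_separation")
        converged = bool(res.mle_retvals.get("converged", False))
        bse = np.asarray(res.bse)
        # Diverging coefficients with exploding SEs indicate separation.
        if not np.all(np.isfinite(bse)) or np.any(np.abs(res.params) > 1e3):
            return LogisticResults(self.terms, np.asarray(res.params), bse, n,
                                   converged=False, outcome=self.outcome,
                                   flag="perfect_separation")
        return LogisticResults(self.terms, np.asarray(res.params), bse, n,
                               converged=converged, llf=float(res.llf),
                               outcome=self.outcome)


def fit_logistic(cohort: pd.DataFrame, outcome: str = "pcr",
                 terms: Sequence[str] = ("pre_density",), **kw) -> LogisticResults:
    """Functional facade over :class:`LogisticModel`."""
    return LogisticModel(cohort, outcome, terms, **kw).fit()


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return f"{p:.2g}" if p >= 1e-5 else "<0.00001"


_VARIABLE_LABELS = {
    "pre_density": ("Median lymphocyte density", "Continuous"),
    "delta_density": ("Change in lymphocyte density", "Continuous"),
    "grade": ("Grade", "1,2,3"),
    "age": ("Age", "Continuous"),
    "er_status[Positive]": ("ER status", "Negative, Positive"),
    "node_status[Positive]": ("Node status", "Negative, Positive"),
    "arm[D FEC]": ("Chemotherapy", "BEV+D FEC, D FEC"),
    "tumour_size_cat[>50 mm]": ("Tumour size", "<=50 mm, >50 mm"),
}


def format_fit_table(fit: LogisticResults) -> pd.DataFrame:
    """Human-readable OR table: effect measures to 2 decimal places, the CI
    rendered as "low-high", and the per-model n."""
    if not fit.converged:
        raise ContractViolation("cannot format a non-converged fit")
    ci = fit.conf_int
    rows = []
    for i, term in enumerate(fit.terms):
        variable, categories = _VARIABLE_LABELS.get(term, (term, ""))
        rows.append(
            {
                "variable": variable,
                "categories": categories,
                "odds_ratio": f"{fit.odds_ratios[i]:.2f}",
                "ci_95": f"{ci[i, 0]:.2f}–{ci[i, 1]:.2f}",
                "p_value": _fmt_p(fit.pvalues[i]),
                "n": fit.n_observations,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate input in which every value is identical gives H = 0, p = 1
    (no rank variation to explain).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ContractViolation("values and groups differ in length")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ContractViolation("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ContractViolation("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResults:
    """An ER-stratum Cox fit: log-hazard estimates and HR table."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    n_observations: int
    n_events: int
    stratum: Optional[str] = None
    endpoint: str = "os"

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.params - _Z95 * self.bse)
        hi = np.exp(self.params + _Z95 * self.bse)
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2.0 * scipy.stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.params,
                "se": self.bse,
                "hazard_ratio": self.hazard_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": self.pvalues,
                "n": self.n_observations,
                "n_events": self.n_events,
            }
        )

    def summary(self) -> str:
        head = (
            f"Cox PH ({self.endpoint.upper()}"
            + (f", stratum {self.stratum}" if self.stratum else "")
            + f"; n = {self.n_observations}, events = {self.n_events})"
        )
        return head + "\n" + self.to_frame().to_string(index=False)


class CoxModel:
    """Cox proportional-hazards regression with Efron tie handling.

    Follow-up starts at surgery; the endpoint is overall survival (OS,
    all-cause mortality) or disease-free survival (DFS, first relapse or
    death without relapse).  Fits are run within one ER stratum because the
    proportional-hazards assumption is known to fail across ER groups.
    """

    def __init__(self, data: pd.DataFrame, endpoint: str = "os",
                 terms: Sequence[str] = ("pre_density",),
                 stratum: Optional[tuple[str, str]] = None,
                 levels: Optional[dict] = None):
        endpoint = endpoint.lower()
        if endpoint not in ("os", "dfs"):
            raise ContractViolation(f"endpoint must be 'os' or 'dfs', got {endpoint!r}")
        self.endpoint = endpoint
        self.stratum_label = None
        if stratum is not None:
            col, level = stratum
            data = data[data[col] == level]
            self.stratum_label = f"{col}={level}"
        if len(data) == 0:
            raise FitError("stratum subset is empty")
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        design = build_design(data, terms, levels)
        t = data[tcol].to_numpy(dtype=float)
        e = data[ecol].to_numpy(dtype=float)
        keep = (np.isfinite(t) & np.isfinite(e)
                & np.isfinite(design.to_numpy(dtype=float)).all(axis=1))
        if np.any(t[keep] <= 0):
            raise ContractViolation("survival times must be positive")
        self._frame = design.loc[keep].copy()
        self.terms = list(design.columns)
        self._frame["_time"] = t[keep]
        self._frame["_event"] = e[keep]
        if len(self._frame) < 2:
            raise FitError("need at least 2 observations")
        if self._frame["_event"].sum() < 1:
            raise FitError("no events in stratum")

    def fit(self) -> SurvivalResults:
        cph = CoxPHFitter()  # Efron partial likelihood for ties (default)
        cph.fit(self._frame, duration_col="_time", event_col="_event")
        params = cph.params_.reindex(self.terms).to_numpy()
        bse = cph.standard_errors_.reindex(self.terms).to_numpy()
        return SurvivalResults(
            terms=self.terms, params=params, bse=bse,
            n_observations=len(self._frame),
            n_events=int(self._frame["_event"].sum()),
            stratum=self.stratum_label, endpoint=self.endpoint,
        )


def fit_cox(cohort: pd.DataFrame, endpoint: str = "os",
            stratum: Optional[tuple[str, str]] = None,
            terms: Sequence[str] = ("pre_density",), **kw) -> SurvivalResults:
    """Functional facade over :class:`CoxModel`."""
    return CoxModel(cohort, endpoint=endpoint, terms=terms, stratum=stratum, **kw).fit()


#: Table-1-style model specifications: univariable models per variable and
#: the multivariable model adjusted for the clinical covariates.
ADJUSTMENT_TERMS = ("grade", "er_status", "age", "node_status", "arm", "tumour_size_cat")


def table1_models(cohort: pd.DataFrame, density_term: str = "pre_density"
                  ) -> dict[str, LogisticResults]:
    """Fit the univariable and multivariable pCR models."""
    out: dict[str, LogisticResults] = {}
    out["univariable"] = fit_logistic(cohort, "pcr", (density_term,))
    out["multivariable"] = fit_logistic(cohort, "pcr", (density_term,) + ADJUSTMENT_TERMS)
    return out
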