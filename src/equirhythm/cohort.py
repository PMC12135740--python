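"""Cohort-level descriptive tables and association analyses.

Builds the group x workout-type summary table (counts, prevalences and
median [range] heart-rate metrics over included workouts), Spearman rank
correlations with qualitative strength bands, and mixed-effects logistic /
Poisson regressions with a random intercept per horse, applying a
collinearity screen to the fixed terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import fit_random_intercept
from .io import WORKOUT_TYPES

GROUP_CARDIAC = "CARDIAC"
GROUP_NON_CARDIAC = "NON_CARDIAC"
GROUP_ALL = "ALL"

#: Chan's qualitative interpretation of |rho|, right-open intervals.
CHAN_BANDS = (
    ("None", 0.0, 0.0),
    ("Poor", 0.0, 0.2),
    ("Fair", 0.2, 0.6),
    ("Moderate", 0.6, 0.8),
    ("Strong", 0.8, 1.0),
    ("Perfect", 1.0, 1.0),
)

FLAG_COLUMNS = ("arrhythmia", "arrhythmia_deceleration", "arrhythmia_complex")


class DegenerateModelError(ValueError):
    """Raised when a model cannot be fitted on the given data."""


class SeparationError(DegenerateModelError):
    """Raised on (quasi-)complete separation in a logistic model."""


# ---------------------------------------------------------------------------
# Prevalence and percentages
# ---------------------------------------------------------------------------


def prevalence(count: int, n: int) -> float:
    """Exact percentage ``100 * count / n`` (full precision)."""
    if n <= 0:
        raise ValueError("prevalence undefined for n <= 0")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    return 100.0 * count / n


def round_pct(value: float, decimals: int = 1) -> float:
    """Half-up rounding for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def render_pct(value: float, decimals: int = 1) -> str:
    """Render a percentage to ``decimals`` places, dropping a trailing .0."""
    rounded = round_pct(value, decimals)
    if rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.{decimals}f}"


# ---------------------------------------------------------------------------
# Group summary table
# ---------------------------------------------------------------------------


@dataclass
class GroupSummaryRow:
    """One line of the group x workout-type summary table."""

    group: str
    type: str  # a workout type or "Total"
    n: int
    npc_median: float
    npc_min: int
    npc_max: int
    arrhythmia_count: int
    arrhythmia_pct: float
    deceleration_count: int
    deceleration_pct: float
    complex_count: int
    complex_pct: float
    hr_peak_median: float
    hr_peak_min: float
    hr_peak_max: float
    hr_mean_median: float
    hr_mean_min: float
    hr_mean_max: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _summary_row(group: str, type_label: str, sub: pd.DataFrame) -> GroupSummaryRow:
    n = len(sub)
    counts = {flag: int(sub[flag].astype(bool).sum()) for flag in FLAG_COLUMNS}
    return GroupSummaryRow(
        group=group,
        type=type_label,
        n=n,
        npc_median=float(sub["n_pc"].median()),
        npc_min=int(sub["n_pc"].min()),
        npc_max=int(sub["n_pc"].max()),
        arrhythmia_count=counts["arrhythmia"],
        arrhythmia_pct=round_pct(prevalence(counts["arrhythmia"], n)),
        deceleration_count=counts["arrhythmia_deceleration"],
        deceleration_pct=round_pct(prevalence(counts["arrhythmia_deceleration"], n)),
        complex_count=counts["arrhythmia_complex"],
        complex_pct=round_pct(prevalence(counts["arrhythmia_complex"], n)),
        hr_peak_median=float(sub["hr_peak"].median()),
        hr_peak_min=float(sub["hr_peak"].min()),
        hr_peak_max=float(sub["hr_peak"].max()),
        hr_mean_median=float(sub["hr_mean"].median()),
        hr_mean_min=float(sub["hr_mean"].min()),
        hr_mean_max=float(sub["hr_mean"].max()),
    )


def build_group_summary(
    results: pd.DataFrame, included_only: bool = True
) -> list[GroupSummaryRow]:
    """Summarise the cohort results per group x workout type plus totals.

    Groups are CARDIAC / NON_CARDIAC (from the ``cardiac`` column) and an
    ALL block.  Only included workouts enter the table by default.
    """
    if results.empty:
        raise ValueError("results table is empty")
    unknown = set(results["type"].unique()) - set(WORKOUT_TYPES)
    if unknown:
        raise ValueError(f"unknown workout type(s) in results: {sorted(unknown)}")
    frame = results[results["included"].astype(bool)] if included_only else results
    if frame.empty:
        raise ValueError("no included workouts to summarise")

    rows: list[GroupSummaryRow] = []
    blocks = (
        (GROUP_CARDIAC, frame[frame["cardiac"].astype(bool)]),
        (GROUP_NON_CARDIAC, frame[~frame["cardiac"].astype(bool)]),
        (GROUP_ALL, frame),
    )
    for group, block in blocks:
        if block.empty:
            continue
        for wtype in WORKOUT_TYPES:
            sub = block[block["type"] == wtype]
            if not sub.empty:
                rows.append(_summary_row(group, wtype, sub))
        rows.append(_summary_row(group, "Total", block))
    return rows


def summary_to_frame(rows: list[GroupSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


# ---------------------------------------------------------------------------
# Spearman correlation with Chan bands
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    band: str
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def chan_band(rho: float) -> str:
    """Qualitative strength of |rho| (right-open interval convention)."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    a = abs(rho)
    if a == 0.0:
        return "None"
    if a >= 1.0 - 1e-12:  # tolerate floating-point rank arithmetic
        return "Perfect"
    for name, lo, hi in CHAN_BANDS[1:-1]:
        if lo <= a < hi:
            return name
    raise AssertionError("unreachable")


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for small samples."""
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    yp = yr[perms]  # (n!, n)
    xc = xr - xr.mean()
    denom = np.sqrt((xc**2).sum() * ((yp - yp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    rhos = (yp - yp.mean(axis=1, keepdims=True)) @ xc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x, y, x_name: str = "x", y_name: str = "y", exact_max_n: int = 9
) -> AssociationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the large-sample t approximation, or exact
    permutation when ``n <= exact_max_n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if x.size <= exact_max_n:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, rho)
    return AssociationResult(
        x_name=x_name, y_name=y_name, rho=rho, p_value=float(p),
        band=chan_band(rho), n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Design matrices and collinearity
# ---------------------------------------------------------------------------

TYPE_REFERENCE = "Flat"
CONTINUOUS_TERMS = frozenset({"age", "level", "season", "duration_min", "hr_peak"})


def build_design(results: pd.DataFrame, fixed_terms: list[str]) -> pd.DataFrame:
    """Assemble the fixed-effects design matrix (no intercept column).

    ``type`` expands to treatment-coded indicator columns with
    ``Flat`` as the reference level; ``cardiac`` becomes a 0/1 indicator;
    remaining terms are carried as continuous covariates.
    """
    cols: dict[str, np.ndarray] = {}
    for term in fixed_terms:
        if term == "type":
            for wtype in WORKOUT_TYPES:
                if wtype == TYPE_REFERENCE:
                    continue
                cols[f"type[{wtype}]"] = (
                    (results["type"] == wtype).astype(float).to_numpy()
                )
        elif term == "cardiac":
            cols["cardiac"] = results["cardiac"].astype(float).to_numpy()
        else:
            cols[term] = results[term].astype(float).to_numpy()
    return pd.DataFrame(cols, index=results.index)


def collinearity_screen(
    design: pd.DataFrame, r2_threshold: float = 0.8
) -> list[tuple[str, float]]:
    """Flag continuous terms nearly determined by the remaining terms.

    Greedy screen: repeatedly regress each continuous column on all other
    columns (with intercept); drop the worst offender with R-squared above
    the threshold (VIF > 5) and repeat.  Returns ``(term, r2)`` flags in
    drop order.
    """
    flagged: list[tuple[str, float]] = []
    remaining = design.copy()
    continuous = [
        c for c in design.columns if c in CONTINUOUS_TERMS or
        not set(np.unique(design[c])) <= {0.0, 1.0}
    ]
    while True:
        worst: tuple[str, float] | None = None
        for col in continuous:
            if col not in remaining.columns:
                continue
            y = remaining[col].to_numpy(dtype=float)
            others = remaining.drop(columns=[col]).to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(y)), others])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            tss = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 if tss == 0 else 1.0 - float((resid**2).sum()) / tss
            if r2 > r2_threshold and (worst is None or r2 > worst[1]):
                worst = (col, r2)
        if worst is None:
            return flagged
        flagged.append(worst)
        remaining = remaining.drop(columns=[worst[0]])


# ---------------------------------------------------------------------------
# Mixed-effects models
# ---------------------------------------------------------------------------


@dataclass
class TermEstimate:
    name: str
    ratio: float  # odds ratio or incidence-rate ratio
    ci_low: float
    ci_high: float
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ModelResult:
    outcome: str
    family: str
    terms: list[TermEstimate]
    random_effect_sd: float
    loglike: float
    n_obs: int
    n_groups: int
    dropped_terms: list[dict] = field(default_factory=list)
    pooled_fallback: bool = False
    converged: bool = True
    reference_levels: dict = field(default_factory=dict)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "terms": [t.to_dict() for t in self.terms],
            "random_effect_sd": self.random_effect_sd,
            "loglike": self.loglike,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "dropped_terms": self.dropped_terms,
            "pooled_fallback": self.pooled_fallback,
            "converged": self.converged,
            "reference_levels": self.reference_levels,
        }


def _pooled_glm(y, X, family):
    import statsmodels.api as sm

    fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=fam).fit(maxiter=200)


def _fit_mixed(
    results: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    group: str,
    family: str,
    screen: bool,
) -> ModelResult:
    y = results[outcome].to_numpy(dtype=float)
    if family == "binomial":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise DegenerateModelError(f"outcome {outcome!r} is not binary")
        if y.min() == y.max():
            raise DegenerateModelError(
                f"outcome {outcome!r} is constant; nothing to model"
            )
    else:
        if np.any(y < 0) or np.any(y != np.rint(y)):
            raise DegenerateModelError(
                f"outcome {outcome!r} must be non-negative integer counts"
            )
        if y.max() == 0:
            raise DegenerateModelError(f"outcome {outcome!r} is all zeros")
    groups = results[group].to_numpy()
    if np.unique(groups).size < 2:
        raise DegenerateModelError("need at least 2 grouping units")

    design = build_design(results, fixed_terms)
    dropped: list[dict] = []
    if screen:
        for term, r2 in collinearity_screen(design):
            design = design.drop(columns=[term])
            dropped.append({"term": term, "reason": f"collinear (R2={r2:.3f})"})
    names = ["intercept", *design.columns]
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])

    fit = fit_random_intercept(y, X, groups, family=family)
    pooled_fallback = False
    if fit.singular or not fit.converged:
        warnings.warn(
            f"random-intercept variance for {outcome!r} is singular or the fit "
            "did not converge; falling back to the pooled model",
            stacklevel=2,
        )
        glm = _pooled_glm(y, X, family)
        beta, beta_se = np.asarray(glm.params), np.asarray(glm.bse)
        loglike, sigma, pooled_fallback = float(glm.llf), 0.0, True
    else:
        beta, beta_se, loglike, sigma = fit.beta, fit.beta_se, fit.loglike, fit.sigma

    if family == "binomial" and np.any(np.abs(beta[1:]) > 15):
        bad = names[1:][int(np.argmax(np.abs(beta[1:])))]
        raise SeparationError(
            f"complete separation suspected for term {bad!r}; "
            "remove the term or merge sparse categories"
        )

    z = 1.959963984540054
    terms = []
    for name, b, se in zip(names, beta, beta_se):
        wald = b / se if se > 0 else np.nan
        terms.append(
            TermEstimate(
                name=name,
                ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * se)),
                ci_high=float(np.exp(b + z * se)),
                p_value=float(2 * stats.norm.sf(abs(wald))) if np.isfinite(wald) else np.nan,
            )
        )
    return ModelResult(
        outcome=outcome,
        family=family,
        terms=terms,
        random_effect_sd=float(sigma),
        loglike=loglike,
        n_obs=int(len(y)),
        n_groups=int(np.unique(groups).size),
        dropped_terms=dropped,
        pooled_fallback=pooled_fallback,
        converged=True,
        reference_levels={"type": TYPE_REFERENCE} if "type" in fixed_terms else {},
    )


def fit_mixed_logistic(
    results: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    group: str = "horse_id",
    screen: bool = True,
) -> ModelResult:
    """Random-intercept-per-horse logistic regression; estimates as ORs."""
    return _fit_mixed(results, outcome, fixed_terms, group, "binomial", screen)


def fit_mixed_poisson(
    results: pd.DataFrame,
    outcome: str = "n_pc",
    fixed_terms: list[str] = (),
    group: str = "horse_id",
    screen: bool = True,
) -> ModelResult:
    """Random-intercept-per-horse Poisson count model; estimates as IRRs.

    No exposure offset is used: the outcome is the per-workout count.
    """
    return _fit_mixed(results, outcome, list(fixed_terms), group, "poisson", screen)
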