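"""Time-cohort survival analyses.

Runs the univariate / multivariate / interaction Cox models over the
declared landmark windows, with proportional-hazards diagnostics and
per-group Kaplan-Meier and kernel hazard curves, and assembles everything
into a single report object with explicit failure records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import REFERENCE_GROUP
from .survival import (
    EVENT_COL,
    TIME_COL,
    CoxResult,
    HazardCurve,
    KMCurve,
    PHTestResult,
    SurvivalError,
    TimeWindow,
    cox_fit,
    kernel_hazard,
    km_estimate,
    landmark_restrict,
    make_dummies,
    schoenfeld_ph_test,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (
    TimeWindow(0.0, 10.0),
    TimeWindow(0.0, 5.0),
    TimeWindow(5.0, 10.0),
    TimeWindow(0.0, 2.5),
    TimeWindow(2.5, 5.0),
)

#: reference level per categorical clinical variable
DEFAULT_REFERENCES = {
    "group": REFERENCE_GROUP,
    "stage": "T1",
    "nodal": "negative",
    "grade": "1",
    "her2": "negative",
    "mks_level": "low",
    "ers_level": "low",
}

CONTINUOUS_VARIABLES = ("age", "mks_score", "ers_score")


@dataclass
class AnalysisPlan:
    windows: tuple[TimeWindow, ...] = DEFAULT_WINDOWS
    univariate: tuple[str, ...] = ("age", "stage", "nodal", "grade", "her2",
                                   "mks_level", "ers_level", "group")
    multivariate: tuple[str, ...] = ("age", "stage", "nodal", "grade", "her2",
                                     "group")
    stratify_by: str | None = None
    references: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    bandwidth: float | None = None
    group_column: str = "group"

    def validate(self, records: pd.DataFrame) -> "AnalysisPlan":
        missing = [v for v in (*self.univariate, *self.multivariate)
                   if v not in records.columns]
        if missing:
            raise SurvivalError(f"plan covariates missing from table: {missing}")
        if self.stratify_by is not None and self.stratify_by not in records.columns:
            raise SurvivalError(f"stratification variable {self.stratify_by!r} missing")
        return self


@dataclass
class AnalysisReport:
    """All requested window/model results plus curve coordinates.

    ``rows`` mirrors a Table-2/3 layout (one row per contrast per window);
    failures are recorded explicitly, never silently dropped.
    """

    rows: pd.DataFrame
    km_curves: dict[tuple[str, str], KMCurve]
    hazard_curves: dict[str, HazardCurve]
    failures: list[dict] = field(default_factory=list)


def _is_continuous(records: pd.DataFrame, variable: str) -> bool:
    return (variable in CONTINUOUS_VARIABLES
            or pd.api.types.is_numeric_dtype(records[variable]))


def _expand(records: pd.DataFrame, variable: str,
            references: dict[str, str]) -> tuple[pd.DataFrame, list[str]]:
    """Design columns for one variable: itself if continuous, else dummies."""
    if _is_continuous(records, variable):
        return records, [variable]
    ref = references.get(variable)
    if ref is None:
        raise SurvivalError(f"no reference level declared for {variable!r}")
    return make_dummies(records, variable, ref)


def _drop_constant(design: pd.DataFrame, columns: list[str]) -> list[str]:
    kept = []
    for c in columns:
        vals = design[c].dropna()
        if vals.nunique() <= 1:
            logger.info("dropping constant covariate %s", c)
        else:
            kept.append(c)
    return kept


def _na_rows(variable: str, columns: list[str], window: TimeWindow,
             reason: str) -> list[dict]:
    return [{
        "variable": variable, "contrast": c, "window": window.label,
        "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "p": np.nan, "ph_p": np.nan, "global_ph_p": np.nan,
        "n": np.nan, "n_events": np.nan, "status": f"NA: {reason}",
    } for c in (columns or [variable])]


def _result_rows(variable: str, fit: CoxResult, ph: PHTestResult | None,
                 window: TimeWindow) -> list[dict]:
    rows = []
    for k, name in enumerate(fit.names):
        rows.append({
            "variable": variable, "contrast": name, "window": window.label,
            "hr": fit.hr[k], "ci_low": fit.ci_low[k], "ci_high": fit.ci_high[k],
            "p": fit.p[k],
            "ph_p": ph.p[k] if ph is not None else np.nan,
            "global_ph_p": ph.global_p if ph is not None else np.nan,
            "n": fit.n, "n_events": fit.n_events,
            "status": "; ".join(fit.warnings) if fit.warnings else "ok",
        })
    return rows


def _fit_with_ph(records: pd.DataFrame, columns: list[str],
                 window: TimeWindow) -> tuple[CoxResult, PHTestResult | None]:
    fit = cox_fit(records, columns, window=window)
    try:
        ph = schoenfeld_ph_test(fit, records)
    except SurvivalError as exc:
        logger.info("PH test unavailable (%s)", exc)
        ph = None
    return fit, ph


def run_univariate(records: pd.DataFrame, variable: str,
                   windows: tuple[TimeWindow, ...] = DEFAULT_WINDOWS,
                   references: dict[str, str] | None = None) -> pd.DataFrame:
    """One Cox fit (plus PH diagnostic) per window for a single variable.

    Categorical variables expand into contrasts against the declared
    reference level; windows with no usable events yield NA rows, as the
    published tables print NA for inestimable strata.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    rows: list[dict] = []
    for window in windows:
        try:
            design, cols = _expand(records, variable, references)
            cols = _drop_constant(design.dropna(subset=cols), cols)
            if not cols:
                raise SurvivalError("all contrasts constant")
            fit, ph = _fit_with_ph(design, cols, window)
            rows.extend(_result_rows(variable, fit, ph, window))
        except SurvivalError as exc:
            rows.extend(_na_rows(variable, [], window, str(exc)))
    return pd.DataFrame(rows)


def run_multivariate(records: pd.DataFrame, covariate_set: tuple[str, ...],
                     window: TimeWindow,
                     references: dict[str, str] | None = None) -> CoxResult:
    """Joint (adjusted) Cox fit over one window, complete-case.

    Grade collapses to "2 or 3 vs 1" in the joint model; covariates that
    are constant in the analysis subset are dropped with a log entry.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    design = records.copy()
    all_cols: list[str] = []
    for variable in covariate_set:
        if variable == "grade":
            design["grade23"] = design["grade"].map(
                lambda g: np.nan if pd.isna(g) else float(str(g) in ("2", "3")))
            all_cols.append("grade23")
            continue
        design, cols = _expand(design, variable, references)
        all_cols.extend(cols)
    complete = design.dropna(subset=[TIME_COL, EVENT_COL, *all_cols])
    n_dropped = len(design) - len(complete)
    if n_dropped:
        logger.info("run_multivariate: %d records dropped (complete-case)", n_dropped)
    kept = _drop_constant(complete, all_cols)
    if not kept:
        raise SurvivalError("no usable covariates after constant-drop")
    return cox_fit(complete, kept, window=window)


def run_interaction(records: pd.DataFrame, score_a: str, score_b: str,
                    window: TimeWindow) -> CoxResult:
    """Continuous two-score model with product term.

    Both scores are centered at their pooled medians before the product is
    formed, so main effects are interpretable at the median and the product
    coefficient is invariant to further centering shifts.
    """
    design = records.copy()
    for col in (score_a, score_b):
        if not pd.api.types.is_numeric_dtype(design[col]):
            raise SurvivalError(f"{col!r} must be continuous")
        design[f"_{col}_c"] = design[col] - design[col].median()
    design["_interaction"] = design[f"_{score_a}_c"] * design[f"_{score_b}_c"]
    fit = cox_fit(design, [f"_{score_a}_c", f"_{score_b}_c", "_interaction"],
                  window=window)
    fit.names = [score_a, score_b, f"{score_a}:{score_b}"]
    return fit


def _curves_by_group(records: pd.DataFrame, group_column: str,
                     windows: tuple[TimeWindow, ...],
                     bandwidth: float | None,
                     failures: list[dict]):
    km: dict[tuple[str, str], KMCurve] = {}
    hz: dict[str, HazardCurve] = {}
    for g, sub in records.groupby(group_column, sort=True):
        for window in windows:
            try:
                km[(str(g), window.label)] = km_estimate(
                    landmark_restrict(sub, window))
            except SurvivalError as exc:
                failures.append({"stage": "km", "group": str(g),
                                 "window": window.label, "error": str(exc)})
        try:
            hz[str(g)] = kernel_hazard(sub, bandwidth=bandwidth)
        except SurvivalError as exc:
            failures.append({"stage": "hazard", "group": str(g),
                             "error": str(exc)})
    return km, hz


def run_time_cohort_suite(records: pd.DataFrame,
                          plan: AnalysisPlan | None = None) -> AnalysisReport:
    """Execute the full windowed analysis plan.

    Univariate models (with PH diagnostics) for every planned variable and
    window, the adjusted joint model, and per-group landmark KM and kernel
    hazard curves.  Deterministic given (records, plan).  When a
    stratification variable is declared the whole suite runs per stratum
    and rows gain a ``stratum`` column.
    """
    plan = (plan or AnalysisPlan()).validate(records)
    if plan.stratify_by is not None:
        frames = []
        all_km: dict[tuple[str, str], KMCurve] = {}
        all_hz: dict[str, HazardCurve] = {}
        failures: list[dict] = []
        strat_plan = AnalysisPlan(
            windows=plan.windows, univariate=plan.univariate,
            multivariate=plan.multivariate, stratify_by=None,
            references=plan.references, bandwidth=plan.bandwidth,
            group_column=plan.group_column)
        for stratum, sub in records.groupby(plan.stratify_by, sort=True):
            rep = run_time_cohort_suite(sub, strat_plan)
            rows = rep.rows.copy()
            rows.insert(0, "stratum", str(stratum))
            frames.append(rows)
            all_km.update({(f"{stratum}|{g}", w): c
                           for (g, w), c in rep.km_curves.items()})
            all_hz.update({f"{stratum}|{g}": c
                           for g, c in rep.hazard_curves.items()})
            failures.extend({**f, "stratum": str(stratum)} for f in rep.failures)
        return AnalysisReport(pd.concat(frames, ignore_index=True),
                              all_km, all_hz, failures)

    failures: list[dict] = []
    rows = []
    for variable in plan.univariate:
        rows.append(run_univariate(records, variable, plan.windows,
                                   plan.references))
    uni = pd.concat(rows, ignore_index=True)
    uni.insert(0, "model", "univariate")

    multi_rows = []
    for window in plan.windows:
        try:
            fit = run_multivariate(records, plan.multivariate, window,
                                   plan.references)
            multi_rows.extend(_result_rows("adjusted", fit, None, window))
        except SurvivalError as exc:
            failures.append({"stage": "multivariate", "window": window.label,
                             "error": str(exc)})
            multi_rows.extend(_na_rows("adjusted", [], window, str(exc)))
    multi = pd.DataFrame(multi_rows)
    multi.insert(0, "model", "multivariate")

    km, hz = _curves_by_group(records, plan.group_column, plan.windows,
                              plan.bandwidth, failures)
    return AnalysisReport(pd.concat([uni, multi], ignore_index=True),
                          km, hz, failures)
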