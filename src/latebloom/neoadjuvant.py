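"""Neoadjuvant endocrine-therapy response analysis.

Clinical response is a volume reduction strictly greater than 50% over the
treatment period; molecular response is the change in the proliferation
(MKS) score at day 14 and day 90 relative to baseline.  The association
between baseline ERS level and clinical response is assessed on a 2x2
table, and day-14/day-90 proliferation is compared between ERS levels with
the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import (
    ExpressionMatrix,
    GeneSet,
    SignatureScore,
    compute_score,
)
from .survival import SurvivalError, contingency_test, wilcoxon_ranksum

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
UNKNOWN = "unknown"

TIMEPOINTS = (0, 14, 90)


class ResponseError(ValueError):
    pass


def classify_clinical_response(volume_change_percent: float | None) -> str:
    """Label from signed percent volume reduction (reduction positive).

    Strictly more than 50% reduction is a responder; exactly 50% or less
    is a non-responder; missing is unknown.
    """
    if volume_change_percent is None or (
            isinstance(volume_change_percent, float)
            and np.isnan(volume_change_percent)):
        return UNKNOWN
    return RESPONDER if volume_change_percent > 50.0 else NON_RESPONDER


@dataclass
class LongitudinalExpression:
    """Expression matrices keyed by day in {0, 14, 90} over one gene space."""

    matrices: dict[int, ExpressionMatrix]

    def __post_init__(self) -> None:
        unknown = set(self.matrices) - set(TIMEPOINTS)
        if unknown:
            raise ResponseError(f"unexpected timepoints {sorted(unknown)}")
        if 0 not in self.matrices or len(self.matrices) < 2:
            raise ResponseError("need day 0 plus at least one later timepoint")

    def samples_at(self, day: int) -> list[str]:
        return list(self.matrices[day].sample_ids)


def molecular_response(longi: LongitudinalExpression,
                       mks_gene_set: GeneSet) -> pd.DataFrame:
    """Per-sample MKS change at day 14 and day 90 (negative = downregulation).

    Delta_t = MKS(day t) - MKS(day 0); samples absent at a timepoint get a
    missing delta for it (logged).
    """
    base = compute_score(longi.matrices[0], mks_gene_set).as_series()
    out = pd.DataFrame({"sample_id": base.index, "mks_day0": base.to_numpy()})
    for day in (14, 90):
        col = f"delta_mks_{day}"
        if day not in longi.matrices:
            out[col] = np.nan
            logger.info("molecular_response: no day-%d expression", day)
            continue
        later = compute_score(longi.matrices[day], mks_gene_set).as_series()
        delta = later.reindex(base.index) - base
        n_missing = int(delta.isna().sum())
        if n_missing:
            logger.info("molecular_response: %d samples missing at day %d",
                        n_missing, day)
        out[f"mks_day{day}"] = later.reindex(base.index).to_numpy()
        out[col] = delta.to_numpy()
    return out


def compare_response_by_ers(records: pd.DataFrame,
                            high_mks_only: bool = True,
                            association_method: str = "chi2_cc") -> dict:
    """Response rates and tests by baseline ERS level.

    ``records`` needs columns ``ers_level`` (low/high), ``mks_level``,
    ``clinical_response`` and, for the rank-sum comparisons, ``mks_day14``
    and ``mks_day90``.  Unknown responses are excluded from rate
    denominators (logged).  Returns rates per level, the association p on
    the responder/non-responder 2x2 table (continuity-corrected chi-square
    by default, Fisher exact alongside), and Wilcoxon p-values comparing
    absolute day-14/day-90 MKS between ERS levels (delta comparisons are
    emitted as secondary outputs).
    """
    sub = records
    if high_mks_only:
        sub = sub[sub["mks_level"] == "high"]
    for level in ("low", "high"):
        if (sub["ers_level"] == level).sum() == 0:
            raise ResponseError(f"no samples with ERS level {level!r}")
    known = sub[sub["clinical_response"] != UNKNOWN]
    n_unknown = len(sub) - len(known)
    if n_unknown:
        logger.info("compare_response_by_ers: %d unknown responses excluded "
                    "from rate denominators", n_unknown)

    counts = {}
    rates = {}
    for level in ("low", "high"):
        grp = known[known["ers_level"] == level]
        n_resp = int((grp["clinical_response"] == RESPONDER).sum())
        counts[level] = (n_resp, len(grp) - n_resp)
        rates[level] = 100.0 * n_resp / len(grp) if len(grp) else np.nan
    table = [list(counts["low"]), list(counts["high"])]
    try:
        p_assoc = contingency_test(table, method=association_method)
        p_fisher = contingency_test(table, method="fisher")
    except SurvivalError as exc:
        raise ResponseError(str(exc)) from exc

    out = {
        "n": int(len(sub)),
        "n_unknown_response": int(n_unknown),
        "counts_low_ers": counts["low"],
        "counts_high_ers": counts["high"],
        "rate_low_ers": rates["low"],
        "rate_high_ers": rates["high"],
        "p_association": p_assoc,
        "p_association_fisher": p_fisher,
        "association_method": association_method,
    }
    for day in (14, 90):
        for col, key in ((f"mks_day{day}", f"p_wilcoxon_{day}"),
                         (f"delta_mks_{day}", f"p_wilcoxon_delta_{day}")):
            if col in sub.columns:
                lo = sub.loc[sub["ers_level"] == "low", col].dropna()
                hi = sub.loc[sub["ers_level"] == "high", col].dropna()
                out[key] = (wilcoxon_ranksum(lo, hi)
                            if len(lo) and len(hi) else np.nan)
            else:
                out[key] = np.nan
    return out


def build_response_records(longi: LongitudinalExpression,
                           clinical: pd.DataFrame,
                           mks_gene_set: GeneSet,
                           ers_gene_set: GeneSet,
                           mks_cutpoint: float | None = None,
                           ers_cutpoint: float | None = None) -> pd.DataFrame:
    """Assemble per-sample response records from raw inputs.

    Baseline MKS/ERS levels come from the supplied cutpoints (defaults:
    baseline medians of this arm); clinical response derives from
    ``volume_change_percent`` in ``clinical``.
    """
    base = longi.matrices[0]
    mks0 = compute_score(base, mks_gene_set).as_series()
    ers0 = compute_score(base, ers_gene_set).as_series()
    mks_cut = float(np.median(mks0)) if mks_cutpoint is None else mks_cutpoint
    ers_cut = float(np.median(ers0)) if ers_cutpoint is None else ers_cutpoint
    deltas = molecular_response(longi, mks_gene_set).set_index("sample_id")
    vol = clinical.set_index("sample_id")["volume_change_percent"].reindex(mks0.index)
    table = pd.DataFrame({
        "sample_id": mks0.index,
        "mks_baseline": mks0.to_numpy(),
        "ers_baseline": ers0.to_numpy(),
        "mks_level": np.where(mks0.to_numpy() > mks_cut, "high", "low"),
        "ers_level": np.where(ers0.to_numpy() > ers_cut, "high", "low"),
        "volume_change_percent": vol.to_numpy(),
        "clinical_response": [classify_clinical_response(v) for v in vol],
    })
    for col in ("mks_day14", "mks_day90", "delta_mks_14", "delta_mks_90"):
        if col in deltas.columns:
            table[col] = deltas[col].reindex(mks0.index).to_numpy()
    return table
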