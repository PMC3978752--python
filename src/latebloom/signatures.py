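"""Gene-set signature scoring and biomarker group assignment.

A signature score is the per-sample arithmetic mean of log-scale expression
over a named gene set.  Scores are turned into discrete levels by median
split (low/high) or tertiles (T1/T2/T3) against cutpoints computed on a
declared reference cohort, and the two binary levels combine into a 2x2
biomarker group whose reference category is ``lowMKS/highERS``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default mitotic-kinase proliferation gene set (overridable via config).
DEFAULT_MKS_GENES = (
    "AURKA", "AURKB", "BUB1", "BUB1B", "CDK1", "CHEK1",
    "MELK", "NEK2", "PBK", "PLK1", "PLK4", "TTK",
)

#: Default estrogen-related gene set (ER-associated module; overridable).
DEFAULT_ERS_GENES = ("ESR1", "PGR", "BCL2", "SCUBE2")

GROUP_LABELS = (
    "lowMKS/highERS",
    "lowMKS/lowERS",
    "highMKS/highERS",
    "highMKS/lowERS",
)

#: Reference category used when the 2x2 group enters a regression model.
REFERENCE_GROUP = "lowMKS/highERS"


class SignatureError(ValueError):
    """Raised for invalid scoring inputs (e.g. no matching genes)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of gene identifiers."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise SignatureError("gene set name must be non-empty")
        if not self.gene_ids:
            raise SignatureError(f"gene set {self.name!r} has no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SignatureError(f"gene set {self.name!r} has duplicate gene ids")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


def default_gene_sets() -> dict[str, GeneSet]:
    return {
        "MKS": GeneSet("MKS", DEFAULT_MKS_GENES),
        "ERS": GeneSet("ERS", DEFAULT_ERS_GENES),
    }


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous log-scale expression.

    Rows sharing a gene id are collapsed by mean at construction (probe-set
    to gene collapsing); duplicated sample ids are an error.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise SignatureError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise SignatureError("expression matrix needs >=1 gene and >=1 sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SignatureError("duplicated sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            df = pd.DataFrame(self.values, index=self.gene_ids)
            n_dup = len(self.gene_ids) - df.index.nunique()
            logger.warning("collapsing %d duplicated gene rows by mean", n_dup)
            collapsed = df.groupby(level=0, sort=False).mean()
            self.gene_ids = list(collapsed.index)
            self.values = collapsed.to_numpy()
        if not np.all(np.isfinite(self.values)):
            raise SignatureError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SignatureScore:
    """Per-sample mean expression over a gene set."""

    signature_name: str
    sample_ids: list[str]
    scores: np.ndarray
    genes_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise SignatureError("one score per sample required")
        if not np.all(np.isfinite(self.scores)):
            raise SignatureError("scores must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.signature_name)


@dataclass(frozen=True)
class ScoreThreshold:
    """Cutpoint(s) computed on a declared reference cohort.

    ``kind`` is ``"median"`` (one cutpoint) or ``"tertile"`` (two strictly
    increasing cutpoints).  The samples that defined the cutpoints are
    recorded for provenance.
    """

    signature_name: str
    kind: str
    cutpoints: tuple[float, ...]
    reference_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("median", "tertile"):
            raise SignatureError(f"unknown threshold kind {self.kind!r}")
        if any(not np.isfinite(c) for c in self.cutpoints):
            raise SignatureError("cutpoints must be finite")
        if self.kind == "median" and len(self.cutpoints) != 1:
            raise SignatureError("median threshold needs exactly one cutpoint")
        if self.kind == "tertile":
            if len(self.cutpoints) != 2:
                raise SignatureError("tertile threshold needs two cutpoints")
            if not self.cutpoints[0] < self.cutpoints[1]:
                raise SignatureError("tertile cutpoints must be strictly ordered")

    @property
    def cutpoint(self) -> float:
        return self.cutpoints[0]


@dataclass(frozen=True)
class BiomarkerGroup:
    """One cell of the 2x2 proliferation x estrogen grouping."""

    mks_level: str
    ers_level: str

    def __post_init__(self) -> None:
        for lvl in (self.mks_level, self.ers_level):
            if lvl not in ("low", "high"):
                raise SignatureError(f"level must be low|high, got {lvl!r}")

    @property
    def label(self) -> str:
        return f"{self.mks_level}MKS/{self.ers_level}ERS"

    @property
    def is_reference(self) -> bool:
        return self.label == REFERENCE_GROUP


def compute_score(expr: ExpressionMatrix, gene_set: GeneSet) -> SignatureScore:
    """Score every sample as the mean expression of the matched set genes.

    Genes of the set absent from the matrix are dropped with a warning;
    if none match a :class:`SignatureError` is raised naming the set.
    """
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    matched = [g for g in gene_set.gene_ids if g in index]
    missing = [g for g in gene_set.gene_ids if g not in index]
    if not matched:
        raise SignatureError(
            f"no genes of set {gene_set.name!r} found in expression matrix; "
            f"missing: {sorted(missing)}"
        )
    if missing:
        logger.warning(
            "gene set %s: %d of %d genes missing from matrix (%s)",
            gene_set.name, len(missing), len(gene_set.gene_ids), ", ".join(missing),
        )
    rows = [index[g] for g in matched]
    scores = expr.values[rows, :].mean(axis=0)
    return SignatureScore(gene_set.name, list(expr.sample_ids), scores,
                          genes_used=tuple(matched))


def compute_threshold(scores: SignatureScore,
                      reference_samples: list[str] | None = None,
                      kind: str = "median") -> ScoreThreshold:
    """Compute median or tertile cutpoints over the reference samples.

    Percentiles use linear interpolation (the 50th percentile of an
    even-sized sample is the midpoint of the central pair).
    """
    if reference_samples is None:
        reference_samples = list(scores.sample_ids)
    if len(reference_samples) == 0:
        raise SignatureError("reference sample set is empty")
    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    unknown = [s for s in reference_samples if s not in pos]
    if unknown:
        raise SignatureError(f"reference samples not scored: {unknown[:5]}")
    vals = scores.scores[[pos[s] for s in reference_samples]]
    if kind == "median":
        if len(vals) < 2:
            raise SignatureError("median threshold needs >=2 reference samples")
        cut = (float(np.percentile(vals, 50.0)),)
    elif kind == "tertile":
        if len(vals) < 3:
            raise SignatureError("tertile threshold needs >=3 reference samples")
        lo = float(np.percentile(vals, 100.0 / 3.0))
        hi = float(np.percentile(vals, 200.0 / 3.0))
        if not lo < hi:
            raise SignatureError(
                "degenerate tertile cutpoints (scores too concentrated)"
            )
        cut = (lo, hi)
    else:
        raise SignatureError(f"unknown threshold kind {kind!r}")
    return ScoreThreshold(scores.signature_name, kind, cut, tuple(reference_samples))


def dichotomize(scores: SignatureScore, threshold: ScoreThreshold) -> pd.Series:
    """Median-split levels: strictly above the cutpoint is ``high``.

    A score equal to the cutpoint is ``low`` ("above the median" defines
    high; equality is not above).
    """
    if threshold.kind != "median":
        raise SignatureError("dichotomize requires a median threshold")
    levels = np.where(scores.scores > threshold.cutpoint, "high", "low")
    return pd.Series(levels, index=scores.sample_ids, name=f"{scores.signature_name}_level")


def tertile_assign(scores: SignatureScore, threshold: ScoreThreshold) -> pd.Series:
    """Tertile levels T1 (lowest) to T3; boundary values go to the lower tertile."""
    if threshold.kind != "tertile":
        raise SignatureError("tertile_assign requires a tertile threshold")
    lo, hi = threshold.cutpoints
    s = scores.scores
    levels = np.where(s <= lo, "T1", np.where(s <= hi, "T2", "T3"))
    if len(set(levels)) == 1:
        logger.warning("degenerate tertile assignment: all samples in %s", levels[0])
    return pd.Series(levels, index=scores.sample_ids, name=f"{scores.signature_name}_tertile")


def assign_group(mks_level: str, ers_level: str) -> BiomarkerGroup:
    """Deterministic 2x2 mapping of (MKS level, ERS level) to a group."""
    return BiomarkerGroup(mks_level=mks_level, ers_level=ers_level)


def assign_groups(mks_levels: pd.Series, ers_levels: pd.Series) -> pd.Series:
    """Vectorized group labels for aligned per-sample level series."""
    if not mks_levels.index.equals(ers_levels.index):
        ers_levels = ers_levels.reindex(mks_levels.index)
        if ers_levels.isna().any():
            raise SignatureError("MKS and ERS level series cover different samples")
    labels = [assign_group(m, e).label for m, e in zip(mks_levels, ers_levels)]
    return pd.Series(labels, index=mks_levels.index, name="group")


@dataclass
class ScoredCohort:
    """Convenience bundle: scores, levels, and groups for one cohort."""

    mks: SignatureScore
    ers: SignatureScore
    mks_threshold: ScoreThreshold
    ers_threshold: ScoreThreshold
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        mks_level = dichotomize(self.mks, self.mks_threshold)
        ers_level = dichotomize(self.ers, self.ers_threshold)
        self.table = pd.DataFrame({
            "sample_id": self.mks.sample_ids,
            "mks_score": self.mks.scores,
            "ers_score": self.ers.scores,
            "mks_level": mks_level.to_numpy(),
            "ers_level": ers_level.to_numpy(),
            "group": assign_groups(mks_level, ers_level).to_numpy(),
        })


def score_cohort(expr: ExpressionMatrix,
                 gene_sets: dict[str, GeneSet] | None = None,
                 reference_samples: list[str] | None = None) -> ScoredCohort:
    """Score MKS and ERS, compute median thresholds on ``reference_samples``
    (default: all samples), and assemble the per-sample group table."""
    sets = gene_sets or default_gene_sets()
    mks = compute_score(expr, sets["MKS"])
    ers = compute_score(expr, sets["ERS"])
    mks_thr = compute_threshold(mks, reference_samples, kind="median")
    ers_thr = compute_threshold(ers, reference_samples, kind="median")
    return ScoredCohort(mks, ers, mks_thr, ers_thr)
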