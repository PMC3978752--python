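"""Synthetic cohort generation.

Generates cohorts with the statistical structure the analysis pipeline
assumes: group-conditional continuous MKS/ERS scores back-filled into a
gene-level expression matrix, clinical covariates, piecewise-constant
group-specific relapse hazards with administrative and dropout censoring,
and a three-timepoint neoadjuvant arm with a clinical-response label.

Random streams are derived per component from the master seed (scores,
survival, dropout, covariates, letrozole), so adding one component never
perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signatures import (
    DEFAULT_ERS_GENES,
    DEFAULT_MKS_GENES,
    GROUP_LABELS,
    ExpressionMatrix,
)

_STREAMS = ("groups", "scores", "survival", "dropout", "covariates",
            "letrozole", "genes")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupScoreModel:
    """Per-group normal means/sds for the two signature scores."""

    mks_mean: float
    ers_mean: float
    mks_sd: float = 0.5
    ers_sd: float = 0.5


@dataclass(frozen=True)
class LetrozoleGroupModel:
    """Per-ERS-level MKS change at day 14/90 and volume-response link."""

    delta14_mean: float
    delta90_mean: float
    delta_sd: float = 0.4


@dataclass
class SimulationConfig:
    n: int = 1000
    seed: int = 0
    group_proportions: dict[str, float] = field(default_factory=lambda: {
        "lowMKS/highERS": 0.30,
        "lowMKS/lowERS": 0.25,
        "highMKS/highERS": 0.25,
        "highMKS/lowERS": 0.20,
    })
    # score means chosen so the median split recovers the generating label
    # with high probability (|Delta mean| = 2.5 sd by default)
    score_model: dict[str, GroupScoreModel] = field(default_factory=lambda: {
        "lowMKS/highERS": GroupScoreModel(mks_mean=-0.625, ers_mean=0.625),
        "lowMKS/lowERS": GroupScoreModel(mks_mean=-0.625, ers_mean=-0.625),
        "highMKS/highERS": GroupScoreModel(mks_mean=0.625, ers_mean=0.625),
        "highMKS/lowERS": GroupScoreModel(mks_mean=0.625, ers_mean=-0.625),
    })
    #: piecewise-constant hazard rates per group (events/year per segment)
    hazard_segments: tuple[float, ...] = (2.5, 5.0, 10.0)
    hazard_rates: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "lowMKS/highERS": (0.010, 0.010, 0.010),
        "lowMKS/lowERS": (0.015, 0.025, 0.035),
        "highMKS/highERS": (0.012, 0.030, 0.070),
        "highMKS/lowERS": (0.110, 0.060, 0.030),
    })
    horizon: float = 10.0
    dropout_prob: float = 0.10
    gene_noise_sd: float = 0.3
    n_decoy_genes: int = 50
    #: covariate prevalences by group: (node_positive, stage_t23, grade2, grade3, her2)
    covariate_model: dict[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: {
            "lowMKS/highERS": (0.20, 0.35, 0.45, 0.08, 0.01),
            "lowMKS/lowERS": (0.20, 0.35, 0.45, 0.13, 0.03),
            "highMKS/highERS": (0.21, 0.35, 0.45, 0.25, 0.03),
            "highMKS/lowERS": (0.22, 0.40, 0.35, 0.37, 0.15),
        })
    letrozole_model: dict[str, LetrozoleGroupModel] = field(default_factory=lambda: {
        "high": LetrozoleGroupModel(delta14_mean=-0.8, delta90_mean=-1.2),
        "low": LetrozoleGroupModel(delta14_mean=-0.1, delta90_mean=-0.2),
    })
    #: volume reduction (%) = intercept - slope * delta90 + noise
    volume_link: tuple[float, float, float] = (35.0, 35.0, 18.0)

    def validate(self) -> "SimulationConfig":
        if self.n <= 0:
            raise SimulationError("n must be positive")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise SimulationError("group proportions must sum to 1")
        if set(self.group_proportions) != set(GROUP_LABELS):
            raise SimulationError("group proportions must cover the four groups")
        cuts = self.hazard_segments
        if any(b <= a for a, b in zip(cuts, cuts[1:])) or cuts[0] <= 0:
            raise SimulationError("hazard segment cutpoints must be increasing")
        for g, rates in self.hazard_rates.items():
            if len(rates) != len(cuts):
                raise SimulationError(f"group {g}: need one rate per segment")
            if any(r < 0 for r in rates):
                raise SimulationError("hazard rates must be >= 0")
        for m in self.score_model.values():
            if m.mks_sd <= 0 or m.ers_sd <= 0:
                raise SimulationError("score sds must be > 0")
        return self

    def rng(self, stream: str) -> np.random.Generator:
        if stream not in _STREAMS:
            raise SimulationError(f"unknown random stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[
                _STREAMS.index(stream)]
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def default_time_varying_config(n: int = 2000, seed: int = 0) -> SimulationConfig:
    """Config whose generating window hazard ratios (vs lowMKS/highERS)
    are largest early for highMKS/lowERS, largest late for highMKS/highERS,
    and lowest throughout for the reference group."""
    cfg = SimulationConfig(n=n, seed=seed).validate()
    hr = generating_window_hrs(cfg)
    early = {g: hr[g][0] for g in hr}
    late = {g: hr[g][-1] for g in hr}
    assert max(early, key=early.get) == "highMKS/lowERS"
    assert max(late, key=late.get) == "highMKS/highERS"
    assert all(min(hr[g]) >= 1.0 for g in hr)
    return cfg


def generating_window_hrs(config: SimulationConfig,
                          reference: str = "lowMKS/highERS"
                          ) -> dict[str, tuple[float, ...]]:
    """True per-segment hazard ratios of each group vs the reference."""
    ref = config.hazard_rates[reference]
    return {
        g: tuple(r / r0 for r, r0 in zip(rates, ref))
        for g, rates in config.hazard_rates.items() if g != reference
    }


def piecewise_survival(t: float, rates: tuple[float, ...],
                       cutpoints: tuple[float, ...]) -> float:
    """Closed-form S(t) = exp(-sum_j lambda_j * overlap(t, segment j)).

    Beyond the last cutpoint the final rate continues indefinitely.
    """
    bounds = (0.0, *cutpoints)
    cum = 0.0
    for j, lam in enumerate(rates):
        lo = bounds[j]
        hi = bounds[j + 1] if j + 1 < len(bounds) else np.inf
        cum += lam * max(0.0, min(t, hi) - lo)
    return float(np.exp(-cum))


def _draw_piecewise_times(rng: np.random.Generator, n: int,
                          rates: tuple[float, ...],
                          cutpoints: tuple[float, ...]) -> np.ndarray:
    """Inverse-transform sampling from the piecewise-exponential model."""
    bounds = np.array((0.0, *cutpoints))
    lam = np.asarray(rates, dtype=float)
    widths = np.diff(bounds)  # one width per segment
    cum_at_bounds = np.concatenate([[0.0], np.cumsum(lam * widths)])
    target = -np.log(rng.uniform(size=n))  # cumulative hazard to reach
    times = np.full(n, np.inf)
    for j in range(len(lam)):
        in_seg = (target > cum_at_bounds[j]) & (target <= cum_at_bounds[j + 1])
        if lam[j] > 0:
            times[in_seg] = bounds[j] + (target[in_seg] - cum_at_bounds[j]) / lam[j]
    # beyond the last cutpoint the last rate continues indefinitely
    left = target > cum_at_bounds[-1]
    if np.any(left) and lam[-1] > 0:
        times[left] = bounds[-1] + (target[left] - cum_at_bounds[-1]) / lam[-1]
    return times


def draw_groups(config: SimulationConfig) -> np.ndarray:
    rng = config.rng("groups")
    labels = list(GROUP_LABELS)
    probs = [config.group_proportions[g] for g in labels]
    return rng.choice(labels, size=config.n, p=probs)


def simulate_scores_and_expression(
        config: SimulationConfig,
        groups: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw group-conditional scores and back-fill gene-level expression.

    Each signature gene's value is the sample's score plus independent
    N(0, gene_noise_sd) noise, so the gene-set mean recovers the score up
    to noise; decoy genes are pure noise.  Returns the matrix and a truth
    table (sample_id, group, true MKS/ERS score).
    """
    config.validate()
    if groups is None:
        groups = draw_groups(config)
    rng = config.rng("scores")
    grng = config.rng("genes")
    n = len(groups)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    mks = np.empty(n)
    ers = np.empty(n)
    for g, model in config.score_model.items():
        mask = groups == g
        k = int(mask.sum())
        mks[mask] = rng.normal(model.mks_mean, model.mks_sd, size=k)
        ers[mask] = rng.normal(model.ers_mean, model.ers_sd, size=k)
    gene_ids = list(DEFAULT_MKS_GENES) + list(DEFAULT_ERS_GENES) + [
        f"DECOY{i:03d}" for i in range(config.n_decoy_genes)]
    n_mks, n_ers = len(DEFAULT_MKS_GENES), len(DEFAULT_ERS_GENES)
    values = np.empty((len(gene_ids), n))
    values[:n_mks] = mks[None, :]
    values[n_mks:n_mks + n_ers] = ers[None, :]
    values[n_mks + n_ers:] = 0.0
    if config.gene_noise_sd > 0 or config.n_decoy_genes:
        noise = grng.normal(0.0, max(config.gene_noise_sd, 1e-12),
                            size=values.shape)
        if config.gene_noise_sd == 0:
            noise[:n_mks + n_ers] = 0.0
        values = values + noise
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "true_mks": mks,
        "true_ers": ers,
    })
    return ExpressionMatrix(gene_ids, sample_ids, values), truth


def simulate_survival(config: SimulationConfig,
                      groups: np.ndarray) -> pd.DataFrame:
    """Draw event/censoring times under the group-wise piecewise model.

    Events are drawn by inversion from the piecewise-exponential survival
    function; each sample is independently censored at the administrative
    horizon or, with probability ``dropout_prob``, at a uniform dropout
    time in (0, horizon).  ``censor_reason`` accounts for every record.
    """
    config.validate()
    rng = config.rng("survival")
    drng = config.rng("dropout")
    n = len(groups)
    event_time = np.empty(n)
    for g, rates in config.hazard_rates.items():
        mask = groups == g
        event_time[mask] = _draw_piecewise_times(
            rng, int(mask.sum()), rates, config.hazard_segments)
    dropout = np.where(drng.uniform(size=n) < config.dropout_prob,
                       drng.uniform(0.0, config.horizon, size=n), np.inf)
    censor_time = np.minimum(dropout, config.horizon)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    reason = np.where(event == 1, "event",
                      np.where(dropout < config.horizon, "dropout", "horizon"))
    # guard against zero times (possible only with infinite rates)
    observed = np.maximum(observed, 1e-9)
    return pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "time_years": observed,
        "event": event,
        "group": groups,
        "censor_reason": reason,
    })


def simulate_covariates(config: SimulationConfig,
                        groups: np.ndarray) -> pd.DataFrame:
    """Clinical covariates with group-dependent prevalences."""
    rng = config.rng("covariates")
    n = len(groups)
    age = np.round(rng.normal(58.0, 10.0, size=n), 1)
    node = np.empty(n, dtype=object)
    stage = np.empty(n, dtype=object)
    grade = np.empty(n, dtype=object)
    her2 = np.empty(n, dtype=object)
    for g, (p_node, p_t23, p_g2, p_g3, p_her2) in config.covariate_model.items():
        mask = groups == g
        k = int(mask.sum())
        node[mask] = np.where(rng.uniform(size=k) < p_node, "positive", "negative")
        stage[mask] = np.where(rng.uniform(size=k) < p_t23, "T2/3", "T1")
        u = rng.uniform(size=k)
        grade[mask] = np.where(u < p_g3, "3", np.where(u < p_g3 + p_g2, "2", "1"))
        her2[mask] = np.where(rng.uniform(size=k) < p_her2, "positive", "negative")
    return pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "age": age,
        "stage": stage,
        "nodal": node,
        "grade": grade,
        "her2": her2,
    })


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: expression, clinical table (survival + covariates),
    and the generating truth.  Byte-identical for identical (config, seed)."""
    config.validate()
    groups = draw_groups(config)
    expr, truth = simulate_scores_and_expression(config, groups)
    surv = simulate_survival(config, groups)
    cov = simulate_covariates(config, groups)
    clinical = surv.merge(cov, on="sample_id", validate="1:1")
    return SyntheticCohort(expr, clinical, truth, config)


def simulate_letrozole_arm(config: SimulationConfig,
                           n_per_level: int = 15
                           ) -> tuple[dict[int, ExpressionMatrix], pd.DataFrame]:
    """Three-timepoint neoadjuvant arm restricted to baseline high-MKS.

    Baseline high-MKS tumors are split by baseline ERS level; MKS changes
    at day 14/90 follow the per-level model, and the clinical-response
    label derives from a simulated volume change linked to the day-90
    change.  Returns expression matrices keyed by day {0, 14, 90} and a
    clinical table with ``volume_change_percent`` and baseline levels.
    """
    config.validate()
    rng = config.rng("letrozole")
    n = 2 * n_per_level
    sample_ids = [f"L{i:04d}" for i in range(n)]
    ers_level = np.array(["high"] * n_per_level + ["low"] * n_per_level)
    base_mks = rng.normal(1.0, 0.4, size=n)  # all high proliferation
    base_ers = np.where(ers_level == "high",
                        rng.normal(0.8, 0.4, size=n),
                        rng.normal(-0.8, 0.4, size=n))
    d14 = np.empty(n)
    d90 = np.empty(n)
    for lvl, model in config.letrozole_model.items():
        mask = ers_level == lvl
        k = int(mask.sum())
        d14[mask] = rng.normal(model.delta14_mean, model.delta_sd, size=k)
        d90[mask] = rng.normal(model.delta90_mean, model.delta_sd, size=k)
    a, b, noise_sd = config.volume_link
    volume_reduction = a - b * d90 + rng.normal(0.0, noise_sd, size=n)

    def _matrix(mks_vals: np.ndarray, ers_vals: np.ndarray) -> ExpressionMatrix:
        gene_ids = list(DEFAULT_MKS_GENES) + list(DEFAULT_ERS_GENES)
        vals = np.empty((len(gene_ids), n))
        vals[:len(DEFAULT_MKS_GENES)] = mks_vals[None, :]
        vals[len(DEFAULT_MKS_GENES):] = ers_vals[None, :]
        if config.gene_noise_sd > 0:
            vals = vals + rng.normal(0.0, config.gene_noise_sd, size=vals.shape)
        return ExpressionMatrix(gene_ids, list(sample_ids), vals)

    matrices = {
        0: _matrix(base_mks, base_ers),
        14: _matrix(base_mks + d14, base_ers),
        90: _matrix(base_mks + d90, base_ers),
    }
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "volume_change_percent": volume_reduction,
        "true_ers_level": ers_level,
        "true_mks_level": np.repeat("high", n),
        "true_delta14": d14,
        "true_delta90": d90,
    })
    return matrices, clinical
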