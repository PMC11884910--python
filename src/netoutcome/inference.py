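"""Bootstrap edge stability and odds-ratio translation of outcome edges.

Nonparametric case resampling (patients with replacement, same n) refits the
full estimation pipeline per resample; the fraction of resamples in which an
edge is nonzero is its inclusion proportion, and percentile bounds of the
resampled weights give bootstrapped intervals (bCI). Because the LASSO
shrinks every parameter toward zero, these bootstrapped sampling
distributions are biased and the bCIs are NOT coverage-valid confidence
intervals; they are descriptive only, and all outputs label them bCI.

Outcome-adjacent edges translate to per-point odds ratios by exponentiating
the raw-unit coefficient of the symptom in the outcome node's regression;
a symptom with no retained outcome edge contributes OR = 1 (weight 0), so
bootstrap OR intervals naturally hit the 1.00 boundary when an edge is
regularized out in part of the resamples.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import CohortTable, ValidationError
from .estimate import EstimationConfig, NetworkModel, estimate_network


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 500
    seed: int = 0
    percentile_low: float = 2.5
    percentile_high: float = 97.5

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not (0 <= self.percentile_low < self.percentile_high <= 100):
            raise ValidationError("need 0 <= percentile_low < percentile_high <= 100")


@dataclass
class BootstrapSummary:
    node_labels: list[str]
    inclusion_proportion: np.ndarray  # (m, m)
    weight_low: np.ndarray  # (m, m)
    weight_high: np.ndarray  # (m, m)
    or_low: np.ndarray  # (p,) odds-ratio scale, outcome-adjacent symptoms
    or_high: np.ndarray  # (p,)
    n_effective: int
    n_boot: int

    def edge_interval(self, i: int, j: int) -> tuple[float, float]:
        return float(self.weight_low[i, j]), float(self.weight_high[i, j])

    def or_interval(self, symptom: int) -> tuple[float, float]:
        return float(self.or_low[symptom]), float(self.or_high[symptom])


class BootstrapError(RuntimeError):
    """Every resample was degenerate; no summary can be formed."""


def bootstrap_network(
    cohort: CohortTable,
    est_config: EstimationConfig = EstimationConfig(),
    boot_config: BootstrapConfig = BootstrapConfig(),
) -> BootstrapSummary:
    """Case-resampling bootstrap of the full network estimation pipeline.

    Each resample gets a fresh CV fold seed derived deterministically from
    ``boot_config.seed``. Resamples in which only one outcome class appears
    are skipped and excluded from ``n_effective``.
    """
    n = cohort.n_patients
    rng = np.random.default_rng(boot_config.seed)
    m = cohort.scale.n_items + 1
    p = cohort.scale.n_items
    out_idx = m - 1

    weights = []
    ors = []
    labels = None
    for _ in range(boot_config.n_boot):
        idx = rng.integers(0, n, size=n)
        cv_seed = int(rng.integers(0, 2**31 - 1))
        sub = cohort.subset(idx)
        if len(np.unique(sub.outcome)) < 2:
            continue
        model = estimate_network(
            sub,
            EstimationConfig(
                n_folds=est_config.n_folds,
                lambda_grid_size=est_config.lambda_grid_size,
                lambda_min_ratio=est_config.lambda_min_ratio,
                edge_rule=est_config.edge_rule,
                cv_seed=cv_seed,
                standardize=est_config.standardize,
            ),
        )
        labels = model.node_labels
        weights.append(model.adjacency.copy())
        or_b = np.ones(p)
        raw = model.nodewise_fits[out_idx].coef_raw
        for s in model.outcome_edges():
            or_b[s] = math.exp(raw[s])
        ors.append(or_b)

    if not weights:
        raise BootstrapError("no bootstrap resample had both outcome classes")
    W = np.stack(weights)  # (B, m, m)
    O = np.stack(ors)  # (B, p)
    lo, hi = boot_config.percentile_low, boot_config.percentile_high
    return BootstrapSummary(
        node_labels=labels,
        inclusion_proportion=(W != 0.0).mean(axis=0),
        weight_low=np.percentile(W, lo, axis=0),
        weight_high=np.percentile(W, hi, axis=0),
        or_low=np.percentile(O, lo, axis=0),
        or_high=np.percentile(O, hi, axis=0),
        n_effective=len(weights),
        n_boot=boot_config.n_boot,
    )


@dataclass
class OddsRatioRow:
    symptom: str
    per_point_or: float
    direction: str  # "positive" | "negative" | "none"
    bci: tuple[float, float] | None = None
    inclusion: float | None = None


def odds_ratio_table(
    model: NetworkModel, bootstrap: BootstrapSummary | None = None
) -> list[OddsRatioRow]:
    """Per-point remission odds ratio for every symptom.

    The OR is exp(raw-unit coefficient of the symptom in the outcome node's
    regression) when the symptom-outcome edge is retained under the edge
    rule, and exactly 1 otherwise. Optional bootstrap bCIs and inclusion
    proportions are attached when a :class:`BootstrapSummary` is given.
    """
    out_idx = model.outcome_index
    if model.nodewise_fits is None:
        raise ValidationError("model has no nodewise fits")
    raw = model.nodewise_fits[out_idx].coef_raw
    present = set(int(i) for i in model.outcome_edges())
    rows = []
    for s in range(out_idx):
        if s in present:
            orr = math.exp(raw[s])
            direction = "positive" if orr > 1 else ("negative" if orr < 1 else "none")
        else:
            orr, direction = 1.0, "none"
        row = OddsRatioRow(model.node_labels[s], orr, direction)
        if bootstrap is not None:
            row.bci = bootstrap.or_interval(s)
            row.inclusion = float(bootstrap.inclusion_proportion[s, out_idx])
        rows.append(row)
    return rows


def cumulative_odds(per_point_or: float, k_points: int) -> tuple[float, float]:
    """Fold change in remission odds over a ``k_points`` score increase.

    Returns ``(fold_change, phrased_fold)`` where ``fold_change`` is
    ``per_point_or ** k_points`` and ``phrased_fold`` is the "times
    more/less likely" magnitude (the reciprocal when the fold change is
    below 1), rounded to one decimal for reporting.
    """
    if per_point_or <= 0:
        raise ValidationError("per_point_or must be positive")
    if k_points < 0:
        raise ValidationError("k_points must be >= 0")
    fold = per_point_or**k_points
    phrased = fold if fold >= 1 else 1.0 / fold
    return float(fold), round(float(phrased), 1)


def percent_odds_change(per_point_or: float) -> int:
    """Signed percent change in the odds per 1-point increase (0.75 -> -25)."""
    if per_point_or <= 0:
        raise ValidationError("per_point_or must be positive")
    return round((per_point_or - 1.0) * 100.0)
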