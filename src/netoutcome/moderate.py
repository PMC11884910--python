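"""Moderated network estimation: does a binary grouping variable (study)
change any pairwise relation?

Every nodewise regression is augmented with the moderator's main effect and
all (standardized predictor x moderator) product terms, all jointly
L1-penalized with the same cross-validated lambda selection as the base
estimator. A pair of nodes is reported as moderated when its interaction
term survives under the configured edge rule (AND by default: the j x m term
must be retained in node i's regression and the i x m term in node j's).
The moderator itself is left on its 0/1 coding so interaction weights read
as between-group differences in the (standardized-scale) pairwise weight.

A pair absent from ``moderated_pairs`` is a non-detection, not evidence that
the two groups share that edge weight.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CohortTable, ValidationError
from .estimate import (
    _EPS,
    EstimationConfig,
    EstimationError,
    cv_lasso,
    design_matrix,
)


@dataclass
class ModerationResult:
    node_labels: list[str]
    base_adjacency: np.ndarray
    moderation_terms: dict[tuple[int, int], float]
    moderated_pairs: list[tuple[int, int]]
    moderator_main_effects: np.ndarray  # per-node coefficient of the raw 0/1 moderator


def estimate_moderated_network(
    cohort: CohortTable, config: EstimationConfig = EstimationConfig()
) -> ModerationResult:
    """Fit the moderated mixed graphical model over all 18 network nodes."""
    if cohort.moderator is None:
        raise ValidationError("cohort has no moderator column")
    mod = cohort.moderator.astype(float)
    if len(np.unique(mod)) < 2:
        raise ValidationError("moderator must have both levels observed")
    if len(np.unique(cohort.outcome)) < 2:
        raise EstimationError("both outcome classes must be present")

    Z, labels, _ = design_matrix(cohort)
    m = Z.shape[1]

    # interaction coefficient of predictor j in the regression of node i
    inter = np.zeros((m, m))
    main = np.zeros((m, m))
    mod_main = np.zeros(m)

    for node in range(m):
        family = "binomial" if node == m - 1 else "gaussian"
        y = Z[:, node]
        others = [j for j in range(m) if j != node]
        X = Z[:, others]
        sds = X.std(axis=0)
        keep = sds > 0
        if not keep.all():
            warnings.warn(f"node {labels[node]}: constant predictors excluded", stacklevel=2)
        X = X[:, keep]
        kept = [o for o, k in zip(others, keep) if k]
        means, sds = X.mean(axis=0), sds[keep]
        Xs = (X - means) / sds if config.standardize else X
        Xint = Xs * mod[:, None]
        D = np.column_stack([Xs, mod, Xint])

        if family == "gaussian":
            my, sdy = float(y.mean()), float(y.std())
            if sdy == 0:
                continue
            fit = cv_lasso(D, (y - my) / sdy, family, config)
        else:
            fit = cv_lasso(D, y.astype(int), family, config)
        k = len(kept)
        for idx, o in enumerate(kept):
            main[node, o] = fit.coef[idx]
            inter[node, o] = fit.coef[k + 1 + idx]
        mod_main[node] = fit.coef[k]

    base_adj = _merge(main, config.edge_rule)
    inter_adj = _merge(inter, config.edge_rule)
    pairs = [
        (i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if inter_adj[i, j] != 0.0
    ]
    terms = {(i, j): float(inter_adj[i, j]) for (i, j) in pairs}
    return ModerationResult(
        node_labels=labels,
        base_adjacency=base_adj,
        moderation_terms=terms,
        moderated_pairs=pairs,
        moderator_main_effects=mod_main,
    )


def _merge(coefs: np.ndarray, rule: str) -> np.ndarray:
    """Same pairwise combination arithmetic as the base estimator."""
    m = coefs.shape[0]
    adj = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            bij, bji = coefs[i, j], coefs[j, i]
            ri, rj = abs(bij) > _EPS, abs(bji) > _EPS
            if rule == "AND":
                if not (ri and rj):
                    continue
                mag = 0.5 * (abs(bij) + abs(bji))
                w = float(np.sign(bij) * mag) if np.sign(bij) == np.sign(bji) else float(mag)
            else:
                if not (ri or rj):
                    continue
                w = float(0.5 * (bij + bji))
            adj[i, j] = adj[j, i] = w
    return adj
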