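"""Synthetic cohort generation with known ground truth.

Cohorts are drawn from a conditional-Gaussian pairwise model: each latent
continuous symptom is normal around ``intercept + sum_j w_ij * x_j`` with a
shared residual sd, which is exactly the model class the nodewise estimator
assumes, run forward. A binary remission outcome follows a logistic model on
a (sparse) subset of the recorded symptom scores, and an optional binary
moderator ("study") additively shifts selected pairwise weights and/or
outcome coefficients for its upper level. Latent symptoms are discretized to
the instrument's ordinal ranges by an affine map of +/-2.5 marginal sd onto
[min_score, max_score], rounded and clipped, which keeps all response
categories populated.

Sampling is by Gibbs: one chain per moderator level, retaining every
``thinning``-th sweep after ``burn_in``; each retained sweep is one patient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .data import CohortTable, SymptomScale, ValidationError, hrsd17
from .data import HYPOCHONDRIASIS, RETARDATION, SUICIDALITY

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@dataclass(frozen=True)
class ModeratorShift:
    """Additive shift applied when the moderator equals 1.

    ``kind`` is ``"edge"`` (shift pairwise weight (i, j)) or ``"outcome"``
    (shift the outcome log-odds coefficient of item ``i``).
    """

    kind: str
    i: int
    j: int | None = None
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("edge", "outcome"):
            raise ValidationError(f"unknown shift kind {self.kind!r}")
        if self.kind == "edge" and (self.j is None or self.i == self.j):
            raise ValidationError("edge shift needs two distinct item indices")


@dataclass
class GeneratingModel:
    """Ground-truth network + outcome model used by the simulator.

    The implied joint over latent symptoms has precision
    ``(I - pairwise_weights) / residual_sd**2``; positive definiteness of
    ``I - W`` is checked at construction (for both moderator levels when edge
    shifts are present) so an improper model fails loudly rather than
    diverging silently during sampling.
    """

    n_items: int
    pairwise_weights: np.ndarray
    item_intercepts: np.ndarray
    residual_sd: float
    outcome_intercept: float
    outcome_coefficients: np.ndarray
    moderator_shifts: tuple[ModeratorShift, ...] | None = None

    def __post_init__(self) -> None:
        self.pairwise_weights = np.asarray(self.pairwise_weights, dtype=float)
        self.item_intercepts = np.asarray(self.item_intercepts, dtype=float)
        self.outcome_coefficients = np.asarray(self.outcome_coefficients, dtype=float)
        p = self.n_items
        if self.pairwise_weights.shape != (p, p):
            raise ValidationError("pairwise_weights must be n_items x n_items")
        if not np.allclose(self.pairwise_weights, self.pairwise_weights.T):
            raise ValidationError("pairwise_weights must be symmetric")
        if np.any(np.diag(self.pairwise_weights) != 0):
            raise ValidationError("pairwise_weights must have a zero diagonal")
        if self.item_intercepts.shape != (p,) or self.outcome_coefficients.shape != (p,):
            raise ValidationError("intercepts/outcome_coefficients must have length n_items")
        if self.residual_sd <= 0:
            raise ValidationError("residual_sd must be positive")
        if self.moderator_shifts is not None:
            self.moderator_shifts = tuple(self.moderator_shifts)
            for s in self.moderator_shifts:
                for idx in (s.i, s.j):
                    if idx is not None and not (0 <= idx < p):
                        raise ValidationError(f"shift index {idx} out of range")
        for level in (0, 1) if self.moderator_shifts else (0,):
            w = self.weights_at(level)
            lo = np.linalg.eigvalsh(np.eye(p) - w)[0]
            if lo <= 1e-8:
                raise ValidationError(
                    f"improper model: I - W not positive definite at moderator={level} "
                    f"(min eigenvalue {lo:.3g})"
                )

    def weights_at(self, level: int) -> np.ndarray:
        """Pairwise weight matrix at a moderator level (0 = base)."""
        w = self.pairwise_weights.copy()
        if level == 1 and self.moderator_shifts:
            for s in self.moderator_shifts:
                if s.kind == "edge":
                    w[s.i, s.j] += s.delta
                    w[s.j, s.i] += s.delta
        return w

    def outcome_coefficients_at(self, level: int) -> np.ndarray:
        beta = self.outcome_coefficients.copy()
        if level == 1 and self.moderator_shifts:
            for s in self.moderator_shifts:
                if s.kind == "outcome":
                    beta[s.i] += s.delta
        return beta

    def marginal_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Model-implied marginal means and sds of the latent symptoms."""
        p = self.n_items
        prec_shape = np.eye(p) - self.pairwise_weights
        mu = np.linalg.solve(prec_shape, self.item_intercepts)
        cov = self.residual_sd**2 * np.linalg.inv(prec_shape)
        return mu, np.sqrt(np.diag(cov))

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_items": int(self.n_items),
            "pairwise_weights": self.pairwise_weights.tolist(),
            "item_intercepts": self.item_intercepts.tolist(),
            "residual_sd": float(self.residual_sd),
            "outcome_intercept": float(self.outcome_intercept),
            "outcome_coefficients": self.outcome_coefficients.tolist(),
        }
        if self.moderator_shifts is not None:
            d["moderator_shifts"] = [
                {"kind": s.kind, "i": s.i, "j": s.j, "delta": s.delta}
                for s in self.moderator_shifts
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingModel":
        shifts = d.get("moderator_shifts")
        if shifts is not None:
            shifts = tuple(ModeratorShift(**s) for s in shifts)
        return cls(
            n_items=d["n_items"],
            pairwise_weights=np.asarray(d["pairwise_weights"]),
            item_intercepts=np.asarray(d["item_intercepts"]),
            residual_sd=d["residual_sd"],
            outcome_intercept=d["outcome_intercept"],
            outcome_coefficients=np.asarray(d["outcome_coefficients"]),
            moderator_shifts=shifts,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratingModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    seed: int = 0
    burn_in: int = 200
    thinning: int = 5
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValidationError("burn_in must be >= 0 and thinning >= 1")


@njit(cache=True)
def _gibbs_kernel(w, b, sd, n_keep, burn_in, thinning, seed):  # pragma: no cover
    np.random.seed(seed)
    p = w.shape[0]
    x = b.copy()
    out = np.empty((n_keep, p))
    total = burn_in + n_keep * thinning
    k = 0
    for t in range(total):
        for i in range(p):
            m = b[i]
            for j in range(p):
                m += w[i, j] * x[j]
            x[i] = m + sd * np.random.normal()
        if t >= burn_in and (t - burn_in) % thinning == thinning - 1:
            out[k] = x
            k += 1
    return out


def _gibbs_py(w, b, sd, n_keep, burn_in, thinning, seed):
    """Pure-python fallback with the same update order and RNG stream."""
    np.random.seed(seed)
    p = w.shape[0]
    x = b.copy()
    out = np.empty((n_keep, p))
    total = burn_in + n_keep * thinning
    k = 0
    for t in range(total):
        for i in range(p):
            x[i] = b[i] + w[i] @ x + sd * np.random.normal()
        if t >= burn_in and (t - burn_in) % thinning == thinning - 1:
            out[k] = x
            k += 1
    return out


def _gibbs(w, b, sd, n_keep, burn_in, thinning, seed):
    fn = _gibbs_kernel if _HAVE_NUMBA else _gibbs_py
    return fn(
        np.ascontiguousarray(w, dtype=np.float64),
        np.ascontiguousarray(b, dtype=np.float64),
        float(sd),
        int(n_keep),
        int(burn_in),
        int(thinning),
        int(seed),
    )


def _discretize(latent: np.ndarray, mu: np.ndarray, sd: np.ndarray, scale: SymptomScale) -> np.ndarray:
    """Affine map [mu - 2.5 sd, mu + 2.5 sd] -> [0, max_score], round, clip."""
    lo = mu - 2.5 * sd
    span = 5.0 * sd
    mx = scale.max_scores
    scores = np.round((latent - lo) / span * mx)
    return np.clip(scores, 0.0, mx)


def sample_cohort(
    model: GeneratingModel, scale: SymptomScale, config: SimulationConfig
) -> CohortTable:
    """Draw a cohort from a :class:`GeneratingModel` by Gibbs sampling.

    When the model carries moderator shifts (even an empty collection) a
    Bernoulli(0.5) moderator is drawn per patient and each level is sampled
    from its own chain with its level-specific weights. The outcome is
    Bernoulli with ``logit = outcome_intercept + beta . scores`` computed on
    the recorded (discretized, unless ``discretize`` is off) scores, so the
    outcome coefficients are per-point log-odds contributions on the scale
    the analyst sees. Identical configs give identical cohorts.
    """
    if model.n_items != scale.n_items:
        raise ValidationError("model dimensions do not match scale")
    ss = np.random.SeedSequence(config.seed)
    gibbs_seeds = ss.generate_state(2) % np.uint32(2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n = config.n_patients
    has_mod = model.moderator_shifts is not None
    moderator = rng.binomial(1, 0.5, size=n) if has_mod else None

    latent = np.empty((n, model.n_items))
    levels = (0, 1) if has_mod else (0,)
    for level in levels:
        rows = np.flatnonzero(moderator == level) if has_mod else np.arange(n)
        if rows.size == 0:
            continue
        latent[rows] = _gibbs(
            model.weights_at(level),
            model.item_intercepts,
            model.residual_sd,
            rows.size,
            config.burn_in,
            config.thinning,
            gibbs_seeds[level],
        )

    if config.discretize:
        mu, marg_sd = model.marginal_moments()
        scores = _discretize(latent, mu, marg_sd, scale)
    else:
        scores = latent

    logit = model.outcome_intercept + scores @ model.outcome_coefficients
    if has_mod:
        extra = model.outcome_coefficients_at(1) - model.outcome_coefficients
        logit = logit + (moderator == 1) * (scores @ extra)
    prob = 1.0 / (1.0 + np.exp(-logit))
    outcome = rng.binomial(1, prob)

    return CohortTable(
        scores=scores,
        outcome=outcome,
        scale=scale,
        moderator=moderator,
        discrete=bool(config.discretize),
    )


# ---------------------------------------------------------------------------
# Reference generating models
# ---------------------------------------------------------------------------

#: Sparse symptom-symptom conditional weights for the default fixture:
#: mood/guilt/suicidality and anxiety/somatic clusters, an insomnia chain,
#: and retardation tied to work/activities. Weights are conditional-mean
#: slopes; row sums stay below 1 so I - W is diagonally dominant (proper).
_DEFAULT_EDGES: tuple[tuple[int, int, float], ...] = (
    (0, 1, 0.25),   # depressed mood - guilt
    (1, 2, 0.25),   # guilt - suicidality
    (0, 6, 0.20),   # depressed mood - work/activities
    (6, 7, 0.25),   # work/activities - retardation
    (3, 4, 0.25),   # early - middle insomnia
    (4, 5, 0.25),   # middle - late insomnia
    (8, 9, 0.25),   # agitation - psychic anxiety
    (9, 10, 0.20),  # psychic - somatic anxiety
    (10, 11, 0.20), # somatic anxiety - gastrointestinal
    (11, 12, 0.20), # gastrointestinal - general somatic
    (12, 14, 0.20), # general somatic - hypochondriasis
    (10, 14, 0.15), # somatic anxiety - hypochondriasis
    (12, 13, 0.15), # general somatic - genital
    (11, 15, 0.15), # gastrointestinal - weight loss
    (0, 9, 0.15),   # depressed mood - psychic anxiety
    (0, 16, 0.10),  # depressed mood - insight
)

#: Per-point odds ratios of the three outcome-adjacent symptoms in the
#: default fixture (suicidality, retardation, hypochondriasis).
DEFAULT_OUTCOME_ORS = {SUICIDALITY: 0.75, RETARDATION: 1.21, HYPOCHONDRIASIS: 1.31}


def default_study_model(seed: int = 0) -> GeneratingModel:
    """A 17-item fixture with exactly three outcome-adjacent symptoms.

    Suicidality carries a negative per-point log-odds of log(0.75), while
    retardation (log 1.21) and hypochondriasis (log 1.31) are positive; the
    remaining 14 outcome coefficients are exactly zero. Symptom-symptom edge
    weights get a small seed-dependent jitter so repeated studies are not
    identical fixtures; the outcome coefficients never vary.
    """
    rng = np.random.default_rng(seed)
    p = 17
    w = np.zeros((p, p))
    for i, j, wt in _DEFAULT_EDGES:
        wt = wt + rng.uniform(-0.03, 0.03)
        w[i, j] = w[j, i] = wt
    beta = np.zeros(p)
    for idx, orr in DEFAULT_OUTCOME_ORS.items():
        beta[idx] = math.log(orr)
    return GeneratingModel(
        n_items=p,
        pairwise_weights=w,
        item_intercepts=np.zeros(p),
        residual_sd=1.0,
        outcome_intercept=0.15,  # targets a ~62% marginal remission rate
        outcome_coefficients=beta,
    )


def independence_model(n_items: int = 17, outcome_intercept: float = 0.49) -> GeneratingModel:
    """All-zero network and outcome coefficients (pure-noise null)."""
    return GeneratingModel(
        n_items=n_items,
        pairwise_weights=np.zeros((n_items, n_items)),
        item_intercepts=np.zeros(n_items),
        residual_sd=1.0,
        outcome_intercept=outcome_intercept,
        outcome_coefficients=np.zeros(n_items),
    )


def with_moderator(
    model: GeneratingModel, shifts: tuple[ModeratorShift, ...] = ()
) -> GeneratingModel:
    """Attach a Bernoulli(0.5) moderator with the given (possibly empty) shifts."""
    return replace(model, moderator_shifts=tuple(shifts))


def study_shift_model(seed: int = 0, edge: tuple[int, int] = (3, 4), delta: float = 0.5) -> GeneratingModel:
    """Default fixture whose ``edge`` weight is ``delta`` larger when study = 1."""
    base = default_study_model(seed)
    return with_moderator(base, (ModeratorShift("edge", edge[0], edge[1], delta),))
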