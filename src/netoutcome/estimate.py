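"""Mixed graphical model estimation by nodewise L1-regularized regression.

Each node of the network (17 ordinal symptom items treated as continuous,
plus the binary remission outcome) is regressed on all other nodes with a
LASSO penalty. The penalty strength lambda is chosen per node by k-fold
cross-validation (stratified by outcome for the binomial node) over a
log-spaced grid from the node's lambda_max down to
``lambda_min_ratio * lambda_max``, minimizing mean out-of-fold prediction
error (squared error for continuous nodes, log-loss for the outcome node).
Ties are broken toward the larger (sparser) lambda. Nodewise fits are then
combined into one signed weighted adjacency by the AND rule (edge present
only if both regressions retain it) or the OR rule.

Predictors are standardized before penalization; coefficients are reported
on both the standardized scale (used for edge weights) and the raw item
scale (used for odds ratios).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

from .data import CohortTable, ValidationError

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_EPS = 1e-10

OUTCOME_LABEL = "remission"


class EstimationError(RuntimeError):
    """The nodewise estimation cannot proceed (e.g. single-class outcome)."""


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for nodewise LASSO estimation and edge combination."""

    n_folds: int = 10
    lambda_grid_size: int = 50
    lambda_min_ratio: float = 0.01
    edge_rule: str = "AND"
    cv_seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValidationError("lambda_min_ratio must be in (0, 1)")
        if self.edge_rule not in ("AND", "OR"):
            raise ValidationError("edge_rule must be 'AND' or 'OR'")


@dataclass
class NodewiseFit:
    """One node's regularized regression on all other nodes."""

    node: int
    family: str  # "gaussian" | "binomial"
    coef_std: np.ndarray  # standardized scale, length n_nodes, 0 at self
    coef_raw: np.ndarray  # raw item units
    intercept_raw: float
    selected_lambda: float
    cv_error_curve: tuple[tuple[float, float], ...]
    dropped: tuple[int, ...] = ()

    def retained(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.coef_std) > _EPS)


@dataclass
class NetworkModel:
    """A fitted symptom + outcome network."""

    node_labels: list[str]
    node_types: list[str]
    adjacency: np.ndarray
    sign_undefined: np.ndarray
    nodewise_fits: list[NodewiseFit] | None
    predictability: np.ndarray
    smallest_retained_weight: float | None

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def outcome_index(self) -> int:
        return self.node_labels.index(OUTCOME_LABEL)

    def outcome_edges(self) -> np.ndarray:
        """Indices of symptoms with a retained edge to the outcome node."""
        return np.flatnonzero(self.adjacency[:, self.outcome_index] != 0.0)


# ---------------------------------------------------------------------------
# Low-level penalized fit (shared with the moderation module)
# ---------------------------------------------------------------------------

def _lambda_grid(lmax: float, size: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, size)  # descending


def lambda_max(X: np.ndarray, y: np.ndarray, family: str) -> float:
    """Smallest penalty that zeroes every coefficient (KKT threshold).

    The gradient of the mean loss at the intercept-only solution is
    X'(y - ybar)/n for both families (for the binomial family the fitted
    intercept-only probability is exactly ybar), so one expression serves.
    """
    del family  # same bound for both families, kept for signature clarity
    r = y - y.mean()
    Xc = X - X.mean(axis=0)
    return float(np.max(np.abs(Xc.T @ r)) / len(y))


def _logistic_cd_path_py(X, y, lambdas, tol, max_outer):
    """L1 logistic path by IRLS + coordinate descent (numpy fallback).

    Minimizes (1/n) sum log(1 + exp(-(2y-1) eta)) + lam * ||beta||_1 with an
    unpenalized intercept, warm-starting along the (descending) lambda path.
    Soft-thresholding yields exact zeros.
    """
    n, p = X.shape
    L = len(lambdas)
    B = np.zeros((L, p))
    B0 = np.zeros(L)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = float(np.log(ybar / (1.0 - ybar)))
    for li in range(L):
        lam = lambdas[li]
        for _ in range(max_outer):
            eta = b0 + X @ beta
            pr = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(pr * (1.0 - pr), 1e-5)
            r = (y - pr) / w  # z - eta
            sw = w.sum()
            h = (w @ (X * X)) / n
            beta_old = beta.copy()
            b0_old = b0
            for _ in range(200):
                dmax = 0.0
                d0 = float(w @ r) / sw
                b0 += d0
                r -= d0
                dmax = max(dmax, abs(d0))
                for j in range(p):
                    num = float((w * X[:, j]) @ r) / n + h[j] * beta[j]
                    # relative slack keeps exact zeros at the KKT boundary
                    bnew = np.sign(num) * max(0.0, abs(num) - lam) / h[j]
                    if abs(num) <= lam * (1.0 + 1e-12):
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        r -= X[:, j] * d
                        dmax = max(dmax, abs(d))
                if dmax < tol:
                    break
            if max(np.max(np.abs(beta - beta_old)), abs(b0 - b0_old)) < tol:
                break
        B[li] = beta
        B0[li] = b0
    return B, B0


if _HAVE_NUMBA:

    @njit(cache=True)
    def _logistic_cd_path_nb(X, y, lambdas, tol, max_outer):  # pragma: no cover
        n, p = X.shape
        L = lambdas.shape[0]
        B = np.zeros((L, p))
        B0 = np.zeros(L)
        beta = np.zeros(p)
        ybar = y.mean()
        b0 = np.log(ybar / (1.0 - ybar))
        for li in range(L):
            lam = lambdas[li]
            for _outer in range(max_outer):
                pr = np.empty(n)
                w = np.empty(n)
                r = np.empty(n)
                for i in range(n):
                    eta_i = b0
                    for j in range(p):
                        eta_i += X[i, j] * beta[j]
                    pr_i = 1.0 / (1.0 + np.exp(-eta_i))
                    w_i = pr_i * (1.0 - pr_i)
                    if w_i < 1e-5:
                        w_i = 1e-5
                    pr[i] = pr_i
                    w[i] = w_i
                    r[i] = (y[i] - pr_i) / w_i
                sw = w.sum()
                h = np.zeros(p)
                for i in range(n):
                    for j in range(p):
                        h[j] += w[i] * X[i, j] * X[i, j]
                for j in range(p):
                    h[j] /= n
                beta_old = beta.copy()
                b0_old = b0
                for _inner in range(200):
                    dmax = 0.0
                    d0 = 0.0
                    for i in range(n):
                        d0 += w[i] * r[i]
                    d0 /= sw
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > dmax:
                        dmax = abs(d0)
                    for j in range(p):
                        num = 0.0
                        for i in range(n):
                            num += w[i] * X[i, j] * r[i]
                        num = num / n + h[j] * beta[j]
                        thr = lam * (1.0 + 1e-12)
                        if num > thr:
                            bnew = (num - lam) / h[j]
                        elif num < -thr:
                            bnew = (num + lam) / h[j]
                        else:
                            bnew = 0.0
                        d = bnew - beta[j]
                        if d != 0.0:
                            beta[j] = bnew
                            for i in range(n):
                                r[i] -= X[i, j] * d
                            if abs(d) > dmax:
                                dmax = abs(d)
                    if dmax < tol:
                        break
                chg = abs(b0 - b0_old)
                for j in range(p):
                    if abs(beta[j] - beta_old[j]) > chg:
                        chg = abs(beta[j] - beta_old[j])
                if chg < tol:
                    break
            B[li] = beta
            B0[li] = b0
        return B, B0


def _logistic_cd_path(X, y, lambdas, tol=1e-6, max_outer=50):
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    fn = _logistic_cd_path_nb if _HAVE_NUMBA else _logistic_cd_path_py
    return fn(X, y, lambdas, float(tol), int(max_outer))


def _fit_l1_logistic(X, y, lam):
    if lam <= 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", tol=1e-10, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        return clf.coef_.ravel().copy(), float(clf.intercept_[0])
    B, B0 = _logistic_cd_path(X, np.asarray(y, dtype=float), np.array([lam]), tol=1e-9, max_outer=200)
    return B[0], float(B0[0])


@dataclass
class PenalizedFit:
    coef: np.ndarray
    intercept: float
    selected_lambda: float
    cv_error_curve: tuple[tuple[float, float], ...]


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    config: EstimationConfig,
    fixed_lambda: float | None = None,
) -> PenalizedFit:
    """Cross-validated LASSO on a prepared design matrix.

    ``X`` columns are taken as-is (already on their penalization scale);
    ``y`` is the (standardized, for gaussian) response. ``fixed_lambda``
    skips CV; ``fixed_lambda=0`` fits the unpenalized model.
    """
    n = len(y)
    if family == "binomial" and len(np.unique(y)) < 2:
        raise EstimationError("outcome node has a single class")

    curve: tuple[tuple[float, float], ...] = ()
    if fixed_lambda is None:
        lmax = lambda_max(X, y, family)
        if lmax <= 0:  # response orthogonal to every predictor
            lam = 0.0
            lambdas = np.array([0.0])
            errs = np.array([np.nan])
        else:
            lambdas = _lambda_grid(lmax, config.lambda_grid_size, config.lambda_min_ratio)
            errs = _cv_errors(X, y, family, lambdas, config)
            lam = float(lambdas[int(np.argmin(errs))])  # ties -> larger lambda
        curve = tuple(zip(map(float, lambdas), map(float, errs)))
    else:
        lam = float(fixed_lambda)

    if family == "gaussian":
        if lam <= 0:
            est = LinearRegression().fit(X, y)
            coef, intercept = est.coef_.copy(), float(est.intercept_)
        else:
            est = Lasso(alpha=lam, max_iter=20000, tol=1e-8).fit(X, y)
            coef, intercept = est.coef_.copy(), float(est.intercept_)
    else:
        coef, intercept = _fit_l1_logistic(X, y, lam)
    return PenalizedFit(coef, intercept, lam, curve)


def _cv_errors(X, y, family, lambdas, config: EstimationConfig) -> np.ndarray:
    n = len(y)
    if family == "gaussian":
        splitter = KFold(config.n_folds, shuffle=True, random_state=config.cv_seed)
        split = splitter.split(X)
    else:
        # keep both outcome classes in every fold; cap folds by minority count
        minority = int(min(np.bincount(y.astype(int), minlength=2)))
        k = min(config.n_folds, minority)
        if k < 2:
            raise EstimationError("too few minority-class cases for cross-validation")
        splitter = StratifiedKFold(k, shuffle=True, random_state=config.cv_seed)
        split = splitter.split(X, y)

    errs = np.zeros(len(lambdas))
    n_folds_used = 0
    for tr, te in split:
        n_folds_used += 1
        if family == "gaussian":
            xm, ym = X[tr].mean(axis=0), y[tr].mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = lasso_path(X[tr] - xm, y[tr] - ym, alphas=lambdas)
            pred = (X[te] - xm) @ coefs + ym
            errs += ((pred - y[te][:, None]) ** 2).mean(axis=0)
        else:
            B, B0 = _logistic_cd_path(X[tr], y[tr], lambdas, tol=1e-5, max_outer=30)
            eta = X[te] @ B.T + B0  # (n_te, L)
            pr = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
            yt = y[te][:, None]
            errs += -(yt * np.log(pr) + (1 - yt) * np.log(1 - pr)).mean(axis=0)
    return errs / n_folds_used


# ---------------------------------------------------------------------------
# Nodewise fitting over the cohort design
# ---------------------------------------------------------------------------

def design_matrix(cohort: CohortTable) -> tuple[np.ndarray, list[str], list[str]]:
    """Nodes-as-columns matrix: items then the binary outcome."""
    Z = np.column_stack([cohort.scores, cohort.outcome.astype(float)])
    labels = cohort.scale.labels + [OUTCOME_LABEL]
    types = ["continuous"] * cohort.scale.n_items + ["categorical"]
    return Z, labels, types


def fit_nodewise(
    cohort: CohortTable,
    node: int,
    config: EstimationConfig = EstimationConfig(),
    fixed_lambda: float | None = None,
) -> NodewiseFit:
    """Regularized regression of one node on all other nodes.

    Symptom nodes use a gaussian family (squared-error loss); the outcome
    node uses a binomial family (logistic deviance) with outcome-stratified
    folds. Constant predictor columns are excluded with a warning.
    """
    Z, labels, _ = design_matrix(cohort)
    m = Z.shape[1]
    if not (0 <= node < m):
        raise ValidationError(f"node index {node} out of range")
    family = "binomial" if node == m - 1 else "gaussian"
    y = Z[:, node]
    others = [j for j in range(m) if j != node]
    X = Z[:, others]

    sds = X.std(axis=0)
    keep = sds > 0
    dropped = tuple(others[k] for k in np.flatnonzero(~keep))
    if dropped:
        warnings.warn(
            f"node {labels[node]}: constant predictors excluded: "
            f"{[labels[d] for d in dropped]}",
            stacklevel=2,
        )
    X = X[:, keep]
    means = X.mean(axis=0)
    sds = sds[keep]
    Xs = (X - means) / sds if config.standardize else X

    coef_std = np.zeros(m)
    coef_raw = np.zeros(m)
    kept_idx = [o for o, k in zip(others, keep) if k]

    if family == "gaussian":
        my, sdy = float(y.mean()), float(y.std())
        if sdy == 0 or X.shape[1] == 0:
            return NodewiseFit(node, family, coef_std, coef_raw, my, np.nan, (), dropped)
        ys = (y - my) / sdy
        fit = cv_lasso(Xs, ys, family, config, fixed_lambda)
        if config.standardize:
            c_std = fit.coef
        else:
            c_std = fit.coef * sds / sdy
        c_raw = c_std * sdy / sds
        intercept = my + sdy * fit.intercept - float(c_raw @ means)
    else:
        if len(np.unique(y)) < 2:
            raise EstimationError("outcome node has a single class")
        fit = cv_lasso(Xs, y.astype(int), family, config, fixed_lambda)
        c_std = fit.coef if config.standardize else fit.coef * sds
        c_raw = c_std / sds
        intercept = fit.intercept - float(c_raw @ means) if config.standardize else fit.intercept

    for k_i, o in enumerate(kept_idx):
        coef_std[o] = c_std[k_i]
        coef_raw[o] = c_raw[k_i]
    return NodewiseFit(
        node, family, coef_std, coef_raw, float(intercept), fit.selected_lambda,
        fit.cv_error_curve, dropped,
    )


def combine_edges(fits: list[NodewiseFit], rule: str = "AND") -> tuple[np.ndarray, np.ndarray]:
    """Merge nodewise coefficient pairs into a signed weighted adjacency.

    AND: edge (i, j) present only if both regressions retain the term;
    weight is the mean of the two standardized magnitudes with their shared
    sign (flagged sign-undefined on disagreement). OR: present if either is
    retained; weight is the mean over both positions (zeros included).
    """
    m = len(fits)
    for f in fits:
        if len(f.coef_std) != m:
            raise ValidationError("nodewise fits have inconsistent dimensions")
    adj = np.zeros((m, m))
    undef = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            bij = fits[i].coef_std[j]
            bji = fits[j].coef_std[i]
            ri, rj = abs(bij) > _EPS, abs(bji) > _EPS
            if rule == "AND":
                if not (ri and rj):
                    continue
                mag = 0.5 * (abs(bij) + abs(bji))
                if np.sign(bij) == np.sign(bji):
                    w = float(np.sign(bij) * mag)
                else:
                    w = float(mag)
                    undef[i, j] = undef[j, i] = True
            else:
                if not (ri or rj):
                    continue
                if ri and rj and np.sign(bij) != np.sign(bji):
                    w = float(0.5 * (abs(bij) + abs(bji)))
                    undef[i, j] = undef[j, i] = True
                else:
                    w = float(0.5 * (bij + bji))
            adj[i, j] = adj[j, i] = w
    return adj, undef


def compute_predictability(model: NetworkModel, cohort: CohortTable) -> np.ndarray:
    """Per-node in-sample predictability in [0, 1].

    Continuous nodes: proportion of variance explained by the nodewise
    prediction (floored at 0). The categorical outcome node: accuracy beyond
    the modal class, normalized to [0, 1]. Zero-variance nodes get 0.
    """
    Z, _, _ = design_matrix(cohort)
    out = np.zeros(model.n_nodes)
    if model.nodewise_fits is None:
        raise ValidationError("model has no nodewise fits")
    for fit in model.nodewise_fits:
        y = Z[:, fit.node]
        eta = fit.intercept_raw + Z @ fit.coef_raw
        if fit.family == "gaussian":
            tss = float(((y - y.mean()) ** 2).sum())
            if tss == 0:
                continue
            rss = float(((y - eta) ** 2).sum())
            out[fit.node] = max(0.0, 1.0 - rss / tss)
        else:
            p1 = float(y.mean())
            modal = max(p1, 1.0 - p1)
            if modal == 1.0:
                continue
            acc = float(((eta >= 0).astype(float) == y).mean())
            out[fit.node] = max(0.0, (acc - modal) / (1.0 - modal))
    return out


def estimate_network(
    cohort: CohortTable, config: EstimationConfig = EstimationConfig()
) -> NetworkModel:
    """Fit the full mixed graphical model (all nodewise fits + edge merge)."""
    if cohort.n_patients < 30:
        raise EstimationError("need at least 30 patients to estimate the network")
    if len(np.unique(cohort.outcome)) < 2:
        raise EstimationError("both outcome classes must be present")
    Z, labels, types = design_matrix(cohort)
    m = Z.shape[1]
    fits = [fit_nodewise(cohort, node, config) for node in range(m)]
    adj, undef = combine_edges(fits, config.edge_rule)
    nz = np.abs(adj[np.triu_indices(m, k=1)])
    nz = nz[nz > 0]
    model = NetworkModel(
        node_labels=labels,
        node_types=types,
        adjacency=adj,
        sign_undefined=undef,
        nodewise_fits=fits,
        predictability=np.zeros(m),
        smallest_retained_weight=float(nz.min()) if nz.size else None,
    )
    model.predictability = compute_predictability(model, cohort)
    return model
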