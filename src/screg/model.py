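"""Poisson model for one (pseudo-)cell on the element catalog.

Observed counts are ``y_i ~ Poisson(L * exp(h(m_i + s_i * delta_i)))``
where ``(m_i, s_i)`` are known locus effects, ``h`` is a cell-specific
monotone technical-bias function fitted on low-variability elements, and
``delta`` is constant within each element cluster (``delta = X beta``)
with a ``N(0, 1)`` prior on each cluster activity ``beta_k``. The cluster
number ``K`` is chosen by cross-validation on held-out elements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import poisson

from screg.compendium import CREHierarchy, LocusEffects, LowVariabilitySet

logger = logging.getLogger(__name__)

BETA_BOUND = 10.0
T_CANDIDATES = tuple(range(1, 7))
_FLAT_LOG_RATE = -20.0


# ---------------------------------------------------------------------------
# monotone bias spline

@dataclass
class BiasSpline:
    """Monotone non-decreasing bias function as an I-spline expansion.

    ``h(x) = alpha0 + sum_t alphas[t] * I_t(x)`` with ``alphas >= 0``. The
    basis functions are integrated spline bumps on ``knots`` (first/last
    knot = training range); outside the training range ``h`` continues
    linearly with the one-sided boundary slope.

    The basis count ``T`` equals ``len(knots) - 1``: interior knots sit at
    the ``t/T`` quantiles of the training abscissae, so a single basis
    (``T=1``) spans the whole range. With degree-1 bumps each basis is a
    unit ramp over one knot interval, which makes the parameter count
    exactly ``T + 1`` (intercept included) as used in the BIC.
    """

    alpha0: float
    alphas: np.ndarray
    knots: np.ndarray
    degree: int = 1
    loglik: float = float("nan")
    bic: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(self.alphas < 0):
            raise ValueError("I-spline coefficients must be nonnegative")
        if len(self.knots) != len(self.alphas) + 1:
            raise ValueError("need len(knots) == T + 1")

    @property
    def T(self) -> int:
        return len(self.alphas)

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Design matrix of the T ramp bases at ``x`` (clipped to range)."""
        x = np.asarray(x, dtype=float)
        lo = self.knots[:-1]
        hi = self.knots[1:]
        return np.clip((x[..., None] - lo) / (hi - lo), 0.0, 1.0)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a, b = self.x_range
        inner = np.clip(x, a, b)
        h = self.alpha0 + self.basis(inner) @ self.alphas
        left_slope = self.alphas[0] / (self.knots[1] - self.knots[0])
        right_slope = self.alphas[-1] / (self.knots[-1] - self.knots[-2])
        h = np.where(x < a, h + left_slope * (x - a), h)
        h = np.where(x > b, h + right_slope * (x - b), h)
        return h

    def to_json(self, path) -> None:
        payload = {
            "alpha0": self.alpha0,
            "alphas": self.alphas.tolist(),
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "T": self.T,
            "x_range": list(self.x_range),
            "loglik": self.loglik,
            "bic": self.bic,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BiasSpline":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            alpha0=payload["alpha0"],
            alphas=np.array(payload["alphas"]),
            knots=np.array(payload["knots"]),
            degree=payload.get("degree", 1),
            loglik=payload.get("loglik", float("nan")),
            bic=payload.get("bic", float("nan")),
        )

    @classmethod
    def identity(cls, x_range: tuple[float, float] = (0.0, 10.0)) -> "BiasSpline":
        """The identity bias function h(x) = x (useful for testing)."""
        a, b = x_range
        return cls(alpha0=a, alphas=np.array([b - a]), knots=np.array([a, b]))


def _spline_knots(x: np.ndarray, T: int) -> np.ndarray | None:
    """Knot vector with interior knots at the t/T quantiles, t=1..T-1."""
    qs = np.quantile(x, np.arange(T + 1) / T)
    qs = np.unique(qs)
    if len(qs) != T + 1:
        return None  # duplicated quantiles: this T is not identifiable
    return qs


def _fit_one_T(y: np.ndarray, x: np.ndarray, L: float, T: int):
    """Constrained Poisson MLE of the spline coefficients at fixed T."""
    knots = _spline_knots(x, T)
    if knots is None:
        return None
    probe = BiasSpline(alpha0=0.0, alphas=np.zeros(T), knots=knots)
    B = probe.basis(x)  # n x T
    ybar = max(y.mean(), 1e-8)

    def negloglik(theta):
        eta = theta[0] + B @ theta[1:]
        ll = float(np.sum(y * eta - L * np.exp(eta)))
        grad_eta = y - L * np.exp(eta)
        grad = np.empty(T + 1)
        grad[0] = grad_eta.sum()
        grad[1:] = B.T @ grad_eta
        return -ll, -grad

    starts = [
        np.concatenate([[knots[0]], np.diff(knots)]),  # identity-like
        np.concatenate([[np.log(ybar / L)], np.zeros(T)]),  # flat at the mean
    ]
    bounds = [(-40.0, 40.0)] + [(0.0, None)] * T
    best = None
    for x0 in starts:
        res = minimize(negloglik, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    loglik = -best.fun
    bic = -2.0 * loglik + (T + 1) * np.log(len(y))
    spline = BiasSpline(
        alpha0=float(best.x[0]),
        alphas=np.maximum(best.x[1:], 0.0),
        knots=knots,
        loglik=loglik,
        bic=bic,
        diagnostics={"T": T, "converged": bool(best.success), "message": str(best.message)},
    )
    return spline, bool(best.success)


def fit_bias_function(
    y: np.ndarray,
    effects: LocusEffects,
    L: float,
    lowvar: LowVariabilitySet | None = None,
    T_candidates: tuple[int, ...] = T_CANDIDATES,
    min_points: int = 10,
) -> BiasSpline:
    """Fit the monotone technical-bias function on low-variability elements.

    For each candidate basis count ``T`` the Poisson log-likelihood
    ``sum_i [y_i h(m_i) - L exp(h(m_i))]`` is maximized over the
    constrained coefficients; the ``T`` minimizing
    ``BIC = -2 loglik + (T+1) log n`` is returned.
    """
    y = np.asarray(y, dtype=float)
    if lowvar is not None:
        idx = lowvar.members
        y = y[idx]
        x = effects.m[idx]
    else:
        x = effects.m
    finite = np.isfinite(x)
    y, x = y[finite], x[finite]
    if len(x) < min_points:
        raise ValueError(f"need >= {min_points} low-variability elements with finite m")
    if L <= 0:
        raise ValueError("library factor must be positive")
    if y.sum() == 0:
        logger.warning("all counts zero on low-variability set: returning flat bias fit")
        knots = _spline_knots(x, 1)
        return BiasSpline(alpha0=_FLAT_LOG_RATE, alphas=np.zeros(1), knots=knots)

    fits, failures = [], {}
    for T in T_candidates:
        out = _fit_one_T(y, x, L, T)
        if out is None:
            failures[T] = "degenerate knots"
            continue
        spline, converged = out
        if converged:
            fits.append(spline)
        else:
            failures[T] = spline.diagnostics.get("message", "did not converge")
    if not fits:
        raise RuntimeError(f"bias-spline optimizer failed at every T: {failures}")
    best = min(fits, key=lambda sp: (sp.bic, sp.T))
    best.diagnostics["failures"] = failures
    return best


def evaluate_bias(spline: BiasSpline, x) -> np.ndarray:
    """Evaluate ``h`` at ``x`` (linear continuation outside the range)."""
    return spline(x)


# ---------------------------------------------------------------------------
# cluster activities

def _beta_objective(beta_grid, y, m, s, spline, L):
    """Vectorized posterior objective over a grid of beta values."""
    eta = spline(m[:, None] + s[:, None] * beta_grid[None, :])
    return (y[:, None] * eta - L * np.exp(eta)).sum(axis=0) - beta_grid**2 / 2.0


def estimate_cluster_activity(
    y: np.ndarray,
    m: np.ndarray,
    s: np.ndarray,
    spline: BiasSpline,
    L: float,
    bound: float = BETA_BOUND,
) -> float:
    """Posterior mode of one cluster's shared activity.

    Maximizes ``sum_i [y_i h(m_i + s_i b) - L exp(h(m_i + s_i b))] - b^2/2``
    over ``b`` in ``[-bound, bound]`` by a coarse grid followed by bounded
    scalar refinement. Clusters where every ``s_i = 0`` carry no activity
    information and return the prior mode 0.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(y) == 0:
        raise ValueError("empty cluster")
    keep = np.isfinite(m)
    y, m, s = y[keep], m[keep], s[keep]
    if len(y) == 0 or np.all(s == 0):
        return 0.0
    grid = np.linspace(-bound, bound, 801)
    vals = _beta_objective(grid, y, m, s, spline, L)
    b0 = grid[int(np.argmax(vals))]
    step = grid[1] - grid[0]
    res = minimize_scalar(
        lambda b: -_beta_objective(np.array([b]), y, m, s, spline, L)[0],
        bounds=(max(b0 - step, -bound), min(b0 + step, bound)),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# cross-validated resolution and reconstruction

@dataclass
class ClusterActivityEstimate:
    """Per-cluster activities at one level plus the element expansion."""

    K: int
    beta: np.ndarray
    delta: np.ndarray


@dataclass
class ReconstructedSignal:
    """Element activities for one pseudo-cell: ``mu = exp(m + s*delta)``."""

    mu: np.ndarray
    mu_sc: np.ndarray
    delta: np.ndarray
    beta: np.ndarray
    chosen_K: int
    provenance: dict = field(default_factory=dict)


def _fit_level_betas(
    y, effects: LocusEffects, spline, L, labels, K, subset=None
) -> np.ndarray:
    """Beta per cluster id 0..K-1 fitted on ``subset`` (default: all)."""
    beta = np.zeros(K)
    members_of = {}
    pool = np.arange(len(labels)) if subset is None else np.asarray(subset)
    for i in pool:
        members_of.setdefault(labels[i], []).append(i)
    for k, members in members_of.items():
        members = np.array(members)
        beta[k] = estimate_cluster_activity(
            y[members], effects.m[members], effects.s[members], spline, L
        )
    return beta


def cross_validate_K(
    y: np.ndarray,
    hierarchy: CREHierarchy,
    effects: LocusEffects,
    spline: BiasSpline,
    L: float,
    candidates: list[int] | None = None,
    train_frac: float = 0.9,
    seed: int | None = 0,
    repeats: int = 1,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster number K by held-out element likelihood.

    Elements are split 90/10 into training and test sets. For each
    candidate level, cluster activities are fitted on the training
    elements (clusters with no training element use the prior mode 0) and
    the median exact Poisson log-likelihood of the test elements is
    scored; the level with the largest median wins, ties going to the
    smaller (better-regularized) K.
    """
    y = np.asarray(y, dtype=float)
    usable = np.flatnonzero(effects.finite_mask())
    if len(usable) < 10:
        raise ValueError("insufficient CREs for CV")
    if candidates is None:
        candidates = list(hierarchy.levels)
    rng = np.random.default_rng(seed)
    scores: dict[int, list[float]] = {K: [] for K in candidates}
    for rep in range(max(1, repeats)):
        if split is not None and rep == 0:
            train, test = np.asarray(split[0]), np.asarray(split[1])
        else:
            perm = rng.permutation(usable)
            n_train = max(1, int(round(train_frac * len(perm))))
            train, test = perm[:n_train], perm[n_train:]
            if len(test) == 0:
                train, test = perm[:-1], perm[-1:]
        for K in candidates:
            labels = hierarchy.assignments[K]
            beta = _fit_level_betas(y, effects, spline, L, labels, K, subset=train)
            eta = spline(effects.m[test] + effects.s[test] * beta[labels[test]])
            ll = poisson.logpmf(y[test], L * np.exp(eta))
            scores[K].append(float(np.median(ll)))
    mean_scores = {K: float(np.mean(v)) for K, v in scores.items()}
    chosen = max(sorted(mean_scores), key=lambda K: (mean_scores[K], -K))
    return chosen, mean_scores


def reconstruct(
    y: np.ndarray,
    hierarchy: CREHierarchy,
    K: int,
    effects: LocusEffects,
    spline: BiasSpline,
    L: float,
    provenance: dict | None = None,
) -> ReconstructedSignal:
    """Estimate element activities at resolution ``K`` for one pseudo-cell.

    ``beta`` is the posterior mode per cluster (fitted on all catalog
    elements), ``delta = X beta``, ``mu = exp(m + s*delta)`` and
    ``mu_sc = exp(h(log mu))``.
    """
    y = np.asarray(y, dtype=float)
    labels = hierarchy.assignments[K]
    beta = _fit_level_betas(y, effects, spline, L, labels, K)
    delta = beta[labels]
    log_mu = effects.m + effects.s * delta
    mu = np.exp(log_mu)
    finite = np.isfinite(log_mu)
    mu_sc = np.zeros_like(mu)
    mu_sc[finite] = np.exp(spline(log_mu[finite]))
    return ReconstructedSignal(
        mu=mu,
        mu_sc=mu_sc,
        delta=delta,
        beta=beta,
        chosen_K=K,
        provenance=provenance or {},
    )
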