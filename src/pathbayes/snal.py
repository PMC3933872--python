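"""Sparse normal / adaptive lasso (SNAL) pathway selection.

After integrating out the SNP effects, y ~ N(X beta, sigma^2 V) with
V = I + a G G'.  Whitening by the inverse Cholesky factor of V gives an
ordinary sparse-regression problem

    y~ = X~ beta + e,    e ~ N(0, lam I),

where lam (the error variance) is the tuning parameter.  Pathway effects
carry an automatic-relevance-determination prior beta ~ N(0, Gamma) with
Gamma = diag(gamma) >= 0, and gamma is estimated by type-II maximum
likelihood: minimizing

    F(gamma) = log|Sigma| + y~' Sigma^{-1} y~,
    Sigma = lam I + X~ Gamma X~'.

F is minimized by iterative reweighting: log|Sigma| is concave in gamma,
so linearizing it at the current iterate and using the variational
identity  y~' Sigma^{-1} y~ = min_beta ||y~ - X~ beta||^2/lam
+ sum beta_j^2/gamma_j  turns each step into an adaptive lasso

    min_beta ||y~ - X~ beta||^2 / lam + 2 sum_j w_j |beta_j|,

with weights w_j = (x_j' Sigma^{-1} x_j)^{1/2}, solved by LARS on columns
rescaled by 1/w_j; the minimizing gamma_j is |beta_j| / w_j.  Each step
minimizes a majorizer of F, so the objective trace is non-increasing.
Larger lam applies more shrinkage: on an orthonormal design the exact
per-coordinate solution is gamma_j = max(0, (x_j'y~)^2 - lam).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from sklearn.linear_model import lars_path_gram

from .hier_model import MarginalModel

# gamma entries below this are hard-zeroed between iterations to keep
# Sigma well-conditioned and the support sparse
GAMMA_FLOOR = 1e-12


@dataclass
class WhitenedProblem:
    """Whitened regression data and the shrinkage tuning parameter.

    lam plays the role of the residual error variance sigma^2 and controls
    ARD shrinkage: larger lam prunes more pathways.
    """

    y_tilde: np.ndarray
    X_tilde: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.y_tilde = np.asarray(self.y_tilde, dtype=float).ravel()
        self.X_tilde = np.asarray(self.X_tilde, dtype=float)
        if self.X_tilde.shape[0] != self.y_tilde.size:
            raise ValueError("y_tilde and X_tilde have inconsistent sample counts")
        if self.lam <= 0:
            raise ValueError("lam must be strictly positive")

    def with_lam(self, lam: float) -> "WhitenedProblem":
        return WhitenedProblem(self.y_tilde, self.X_tilde, lam)


@dataclass
class ARDFit:
    """Result of the iterative reweighted adaptive-lasso fit.

    gamma : estimated prior variances (diagonal of Gamma), >= 0.
    beta_hat : pathway coefficients from the final lasso step.
    selected : indices with gamma > 0 (the associated pathways).
    objective_trace : type-II ML objective at gamma = 0 and after each
        iteration; non-increasing by construction.
    """

    gamma: np.ndarray
    beta_hat: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.gamma > 0)


def whiten(m: MarginalModel, lam: float) -> WhitenedProblem:
    """Whiten the marginal problem by the Cholesky factor of V = I + a G G'.

    Returns y~ = R^{-1} y and X~ = R^{-1} X (triangular solves against the
    lower factor R); under the model the residual y~ - X~ beta then has
    covariance proportional to the identity.
    """
    n = m.n_samples
    V = np.eye(n) + m.hp.a * m.K_snp
    try:
        R = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:  # V >= I, so this indicates NaNs etc.
        raise np.linalg.LinAlgError("whitening matrix is not positive definite") from exc
    y_tilde = solve_triangular(R, m.y, lower=True)
    X_tilde = solve_triangular(R, m.X, lower=True)
    return WhitenedProblem(y_tilde, X_tilde, lam)


def ard_objective(p: WhitenedProblem, gamma: np.ndarray) -> float:
    """Type-II ML objective log|Sigma| + y~' Sigma^{-1} y~ at a given gamma."""
    gamma = np.asarray(gamma, dtype=float)
    if (gamma < 0).any():
        raise ValueError("gamma must be elementwise nonnegative")
    n = p.y_tilde.size
    Sigma = p.lam * np.eye(n) + (p.X_tilde * gamma) @ p.X_tilde.T
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    quad = float(p.y_tilde @ cho_solve(cf, p.y_tilde))
    return logdet + quad


class _GramCache:
    """Sufficient statistics of the whitened problem.

    With M pathways << N individuals, every quantity the reweighting loop
    needs -- the objective, the ARD weights and the LARS subproblem -- is
    a function of X~'X~, X~'y~ and ||y~||^2 alone (Woodbury identity on
    Sigma = lam I + X~ Gamma X~'), so the N-dimensional space is left
    after one O(N M^2) pass.
    """

    def __init__(self, p: WhitenedProblem) -> None:
        self.G = p.X_tilde.T @ p.X_tilde
        self.Xy = p.X_tilde.T @ p.y_tilde
        self.yy = float(p.y_tilde @ p.y_tilde)
        self.n = p.y_tilde.size
        self.Gdiag = np.diag(self.G).copy()

    def _active_factor(self, lam: float, gamma: np.ndarray):
        """Cholesky of B = lam I_s + D^{1/2} G_SS D^{1/2} on the support S."""
        S = np.flatnonzero(gamma > 0)
        d = np.sqrt(gamma[S])
        B = lam * np.eye(S.size) + (d[:, None] * self.G[np.ix_(S, S)]) * d[None, :]
        return S, d, cho_factor(B, lower=True)

    def objective(self, lam: float, gamma: np.ndarray) -> float:
        """log|Sigma| + y~' Sigma^{-1} y~ (equals the dense evaluation)."""
        S, d, cf = self._active_factor(lam, gamma)
        logdet = (self.n - S.size) * np.log(lam) + 2.0 * np.log(np.diag(cf[0])).sum()
        v = d * self.Xy[S]
        quad = (self.yy - float(v @ cho_solve(cf, v))) / lam
        return logdet + quad

    def weights(self, lam: float, gamma: np.ndarray) -> np.ndarray:
        """w_j = (x_j' Sigma^{-1} x_j)^{1/2} for every column j."""
        S, d, cf = self._active_factor(lam, gamma)
        U = d[:, None] * self.G[S, :]
        wsq = (self.Gdiag - np.einsum("ij,ij->j", U, cho_solve(cf, U))) / lam
        return np.sqrt(np.maximum(wsq, 0.0))


def _adaptive_lasso_gram(cache: _GramCache, lam: float, w: np.ndarray) -> np.ndarray:
    """Solve min_beta ||y~ - X~ beta||^2 / lam + 2 sum_j w_j |beta_j| by LARS
    on columns rescaled by 1/w_j, working entirely in the Gram domain."""
    pos = w > 0
    beta = np.zeros(w.size)
    if not pos.any():
        return beta
    wp = w[pos]
    Gw = cache.G[np.ix_(pos, pos)] / np.outer(wp, wp)
    Xyw = cache.Xy[pos] / wp
    # lars_path objective: (1/2n)||y - X theta||^2 + alpha ||theta||_1;
    # matching ||y - X theta||^2 + 2 lam ||theta||_1 gives alpha = lam / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, coefs = lars_path_gram(
            Xy=Xyw, Gram=Gw, n_samples=cache.n, alpha_min=lam / cache.n, method="lasso"
        )
    beta[pos] = coefs[:, -1] / wp
    return beta


def snal_fit(
    p: WhitenedProblem,
    tol: float = 1e-6,
    max_iter: int = 100,
    gamma_init: np.ndarray | None = None,
    _cache: _GramCache | None = None,
) -> ARDFit:
    """Minimize the type-II ML objective by iterative reweighted adaptive
    lasso.

    Starting from gamma = 0 (weights w_j = ||x_j|| / sqrt(lam), i.e. a
    plain lasso first pass) or from ``gamma_init`` (warm start), each
    iteration solves an adaptive lasso, maps beta to gamma_j = |beta_j|/w_j,
    and refreshes the weights at the new Sigma.  Stops when the largest
    absolute change in gamma falls below ``tol``.
    """
    m = p.X_tilde.shape[1]
    cache = _cache if _cache is not None else _GramCache(p)
    gamma = np.zeros(m) if gamma_init is None else np.asarray(gamma_init, dtype=float).copy()
    beta = np.zeros(m)
    trace = [cache.objective(p.lam, gamma)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = cache.weights(p.lam, gamma)
        beta = _adaptive_lasso_gram(cache, p.lam, w)
        new_gamma = np.where(w > 0, np.abs(beta) / np.where(w > 0, w, 1.0), 0.0)
        new_gamma[new_gamma < GAMMA_FLOOR] = 0.0
        trace.append(cache.objective(p.lam, new_gamma))
        delta = np.max(np.abs(new_gamma - gamma))
        gamma = new_gamma
        if delta < tol:
            converged = True
            break
    return ARDFit(
        gamma=gamma,
        beta_hat=beta,
        objective_trace=np.array(trace),
        n_iter=n_iter,
        converged=converged,
    )


def snal_path(
    p: WhitenedProblem,
    lam_grid: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    warm_start: bool = True,
) -> list[ARDFit]:
    """Fit SNAL over a sorted grid of lam values.

    The grid is traversed from the largest (sparsest) value downwards,
    warm-starting each fit from the previous gamma; warm and cold starts
    agree within ``tol`` because every fit descends the same objective.
    Returns fits in the order of the input grid.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if (lam_grid <= 0).any():
        raise ValueError("lam grid must be positive")
    if not np.all(np.diff(lam_grid) >= 0):
        raise ValueError("lam grid must be sorted ascending")
    fits: dict[int, ARDFit] = {}
    cache = _GramCache(p)  # shared: the Gram statistics do not depend on lam
    gamma_prev: np.ndarray | None = None
    for k in reversed(range(lam_grid.size)):
        pk = p.with_lam(float(lam_grid[k]))
        init = gamma_prev if warm_start else None
        fit = snal_fit(pk, tol=tol, max_iter=max_iter, gamma_init=init, _cache=cache)
        fits[k] = fit
        gamma_prev = fit.gamma
    return [fits[k] for k in range(lam_grid.size)]


def selection_scores(fits: list[ARDFit], lam_grid: np.ndarray, n_pathways: int) -> np.ndarray:
    """Per-pathway score for ROC sweeps: the largest lam at which the
    pathway is still selected (0 if never selected).

    Larger scores indicate stronger association; calling pathways positive
    at score >= t sweeps out the SNAL operating points as lam varies.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    scores = np.zeros(n_pathways)
    for lam, fit in zip(lam_grid, fits):
        sel = fit.selected
        scores[sel] = np.maximum(scores[sel], lam)
    return scores
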