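"""Two-level hierarchical model for pathway association.

The phenotype of N individuals is modelled as

    y = X beta + Z u + eps,      Z = G (N x L allele counts),  X = G P,

where P is the binary L x M SNP-pathway membership matrix, u are SNP
effects and beta pathway effects.  SNP and pathway effects are given
zero-mean normal priors with variances proportional to the residual
variance sigma^2:

    u ~ N(0, sigma^2 a I_L),   beta ~ N(0, sigma^2 b I_M),
    eps ~ N(0, sigma^2 I_N),   sigma^2 ~ Scaled-Inv-chi^2(nu0, s0^2).

Integrating u and beta gives y | sigma^2 ~ N(0, sigma^2 C) with the
scale-structure matrix

    C = I_N + a G G' + b X X',

and integrating sigma^2 against its scaled-inverse-chi-square prior gives
the closed-form marginal: an N-variate Student-t with location 0, nu0
degrees of freedom and scale matrix s0^2 C.  The proportional-variance
parameterization is what makes this marginal an exact multivariate t.

Everything downstream (pathway and SNP Bayes factors) reduces to
log-determinants and quadratic forms of C with single columns removed,
which are rank-1 (or small-rank) downdates of its Cholesky factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_formats import PathwayMatrix


@dataclass(frozen=True)
class HyperParams:
    """Hyper-parameters of the hierarchical model.

    a : prior variance factor of SNP effects (diagonal of A = a I)
    b : prior variance factor of pathway effects (diagonal of B = b I)
    nu0 : degrees of freedom of the scaled-inverse-chi-square prior on sigma^2
    s0sq : scale of that prior (mode s0sq*nu0/(nu0+2), mean s0sq*nu0/(nu0-2))
    """

    a: float = 1e-3
    b: float = 1e-3
    nu0: float = 50.0
    s0sq: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "nu0", "s0sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CenteringPolicy:
    """Whether to mean-centre y and the columns of G before modelling.

    The marginal model has zero location and no intercept, so both default
    to True.
    """

    center_y: bool = True
    center_G: bool = True


# ---------------------------------------------------------------------------
# Cholesky rank-1 update / downdate
# ---------------------------------------------------------------------------

def chol_update(L: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Return the lower Cholesky factor of L L' + v v' in O(N^2)."""
    L = np.array(L, dtype=float)
    v = np.array(v, dtype=float)
    n = v.size
    for k in range(n):
        r = np.hypot(L[k, k], v[k])
        c, s = r / L[k, k], v[k] / L[k, k]
        L[k, k] = r
        if k + 1 < n:
            L[k + 1:, k] = (L[k + 1:, k] + s * v[k + 1:]) / c
            v[k + 1:] = c * v[k + 1:] - s * L[k + 1:, k]
    return L


def chol_downdate(L: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Return the lower Cholesky factor of L L' - v v' in O(N^2).

    Raises LinAlgError if the downdated matrix is not positive definite.
    """
    L = np.array(L, dtype=float)
    v = np.array(v, dtype=float)
    n = v.size
    for k in range(n):
        r2 = (L[k, k] - v[k]) * (L[k, k] + v[k])
        if r2 <= 0.0:
            raise np.linalg.LinAlgError("rank-1 downdate lost positive definiteness")
        r = np.sqrt(r2)
        c, s = r / L[k, k], v[k] / L[k, k]
        L[k, k] = r
        if k + 1 < n:
            L[k + 1:, k] = (L[k + 1:, k] - s * v[k + 1:]) / c
            v[k + 1:] = c * v[k + 1:] - s * L[k + 1:, k]
    return L


# ---------------------------------------------------------------------------
# marginal model container
# ---------------------------------------------------------------------------

class MarginalModel:
    """Phenotype, designs and precomputed covariance components.

    Parameters
    ----------
    y : length-N phenotype vector.
    G : N x L genotype design (complete, no missing entries).
    P : L x M binary SNP-pathway membership matrix (PathwayMatrix or array).
    hp : model hyper-parameters.
    centering : mean-centring policy; the zero-location marginal assumes
        centred data, so both flags default to True.
    """

    def __init__(
        self,
        y: np.ndarray,
        G: np.ndarray,
        P: PathwayMatrix | np.ndarray,
        hp: HyperParams,
        centering: CenteringPolicy = CenteringPolicy(),
    ) -> None:
        y = np.asarray(y, dtype=float).ravel()
        G = np.asarray(G, dtype=float)
        if np.isnan(G).any():
            raise ValueError("G contains missing entries; impute first")
        Pmat = P.membership if isinstance(P, PathwayMatrix) else np.asarray(P)
        Pmat = Pmat.astype(float)
        if G.shape[0] != y.size:
            raise ValueError("y and G have inconsistent sample counts")
        if G.shape[1] != Pmat.shape[0]:
            raise ValueError("column count of G must equal row count of P")
        if centering.center_y:
            y = y - y.mean()
        if centering.center_G:
            G = G - G.mean(axis=0)
        self.y = y
        self.G = G
        self.P = Pmat
        self.X = build_design(G, Pmat)
        self.hp = hp
        self.centering = centering
        self.K_snp = G @ G.T
        self.K_path = self.X @ self.X.T
        self._chol_full: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.y.size

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    @property
    def n_pathways(self) -> int:
        return self.P.shape[1]

    def cholesky_full(self) -> np.ndarray:
        """Lower Cholesky factor of the full scale matrix C (cached)."""
        if self._chol_full is None:
            self._chol_full = np.linalg.cholesky(marginal_covariance_scale(self))
        return self._chol_full


def build_design(G: np.ndarray, P: np.ndarray | PathwayMatrix) -> np.ndarray:
    """Pathway design X = G P.

    Entry (n, m) is individual n's total minor-allele count over pathway m's
    member SNPs (a real number once G is centred or imputed).
    """
    G = np.asarray(G, dtype=float)
    Pmat = P.membership if isinstance(P, PathwayMatrix) else np.asarray(P)
    if G.shape[1] != Pmat.shape[0]:
        raise ValueError(
            f"dimension mismatch: G has {G.shape[1]} SNPs, P has {Pmat.shape[0]} rows"
        )
    return G @ Pmat.astype(float)


def marginal_covariance_scale(
    m: MarginalModel,
    drop_pathway: int | None = None,
    drop_snp: int | None = None,
) -> np.ndarray:
    """Scale-structure matrix C = I + a G*G*' + b X*X*' built explicitly.

    With ``drop_pathway=q`` the q-th column of X is removed; with
    ``drop_snp=i`` the i-th column of G is removed together with the i-th
    row of P (so its contribution to X = G P disappears as well).  This is
    the from-scratch construction; Bayes-factor scoring uses equivalent
    rank-1/small-rank Cholesky downdates instead.
    """
    if drop_pathway is not None and drop_snp is not None:
        raise ValueError("give at most one of drop_pathway/drop_snp")
    a, b = m.hp.a, m.hp.b
    n = m.n_samples
    if drop_snp is not None:
        G = np.delete(m.G, drop_snp, axis=1)
        X = build_design(G, np.delete(m.P, drop_snp, axis=0))
        return np.eye(n) + a * (G @ G.T) + b * (X @ X.T)
    if drop_pathway is not None:
        X = np.delete(m.X, drop_pathway, axis=1)
        return np.eye(n) + a * m.K_snp + b * (X @ X.T)
    return np.eye(n) + a * m.K_snp + b * m.K_path


# ---------------------------------------------------------------------------
# multivariate-t marginal log-likelihood
# ---------------------------------------------------------------------------

def mvt_loglik_chol(y: np.ndarray, L: np.ndarray, nu0: float, s0sq: float) -> float:
    """Multivariate-t log-density given the lower Cholesky factor of C."""
    from scipy.linalg import solve_triangular

    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    z = solve_triangular(L, y, lower=True)
    quad = float(z @ z) / s0sq  # y' (s0sq C)^{-1} y
    logdet = 2.0 * np.log(np.diag(L)).sum() + n * np.log(s0sq)
    return float(
        gammaln((nu0 + n) / 2.0)
        - gammaln(nu0 / 2.0)
        - 0.5 * n * np.log(nu0 * np.pi)
        - 0.5 * logdet
        - 0.5 * (nu0 + n) * np.log1p(quad / nu0)
    )


def mvt_loglik(y: np.ndarray, C: np.ndarray, nu0: float, s0sq: float) -> float:
    """Log-density of the N-variate Student-t with location 0, ``nu0``
    degrees of freedom and scale matrix ``s0sq * C``.

    Computed through the Cholesky factor of C; no explicit inverse is
    formed.  This is the marginal likelihood of the hierarchical model
    after integrating SNP effects, pathway effects and the residual
    variance.
    """
    C = np.asarray(C, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "scale matrix is not positive definite; centre the data or add jitter"
        ) from exc
    return mvt_loglik_chol(y, L, nu0, s0sq)
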