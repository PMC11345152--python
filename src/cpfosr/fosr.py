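"""Conjugate Bayesian function-on-scalar regression in the basis space.

Model for the N x R subject-score matrix G with design Z (N x p):

    G = Z gamma* + E*,   rows of E* ~ N_R(0, Sigma_eps) i.i.d.

Conjugate prior:

    gamma* | Sigma_eps ~ MN(g0, L0^{-1}, Sigma_eps)
    Sigma_eps          ~ InvWishart(V0, nu0)

Posterior (closed form):

    Ln = Z'Z + L0
    gn = Ln^{-1} (Z'G + L0 g0)
    nun = nu0 + N
    Vn = V0 + (G - Z gn)'(G - Z gn) + (gn - g0)' L0 (gn - g0)

Sampling is exact two-block composition: draw Sigma_eps from the inverse
Wishart marginal, then gamma* from the matrix normal conditional, so draws
are i.i.d. — no burn-in is needed (burn-in/thinning arguments are accepted
for interface compatibility and default to 0/1).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import invwishart

__all__ = [
    "DesignMatrix",
    "FOSRPrior",
    "FOSRPosterior",
    "PosteriorDraws",
    "default_prior",
    "posterior_params",
    "draw_posterior",
]


@dataclasses.dataclass
class DesignMatrix:
    """N x p design with an explicit leading intercept column."""

    Z: np.ndarray
    column_names: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("design matrix contains non-finite entries")
        n, p = self.Z.shape
        if self.column_names is None:
            self.column_names = ["intercept"] + [f"x{j}" for j in range(1, p)]
        if len(self.column_names) != p:
            raise ValueError("column_names length must equal the column count")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal the row count")
        if n <= p:
            warnings.warn(f"N={n} <= p={p}: design is (near) saturated", UserWarning)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]


def _check_sym_psd(m: np.ndarray, name: str, strict: bool) -> np.ndarray:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(m)
    if strict and eig.min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    if not strict and eig.min() < -1e-10 * max(1.0, abs(eig.max())):
        raise ValueError(f"{name} must be positive semidefinite")
    return m


@dataclasses.dataclass
class FOSRPrior:
    """Matrix-Normal/Inverse-Wishart prior (g0, L0, V0, nu0)."""

    g0: np.ndarray
    L0: np.ndarray
    V0: np.ndarray
    nu0: float

    def __post_init__(self) -> None:
        self.g0 = np.atleast_2d(np.asarray(self.g0, dtype=float))
        self.L0 = _check_sym_psd(self.L0, "L0", strict=False)
        self.V0 = _check_sym_psd(self.V0, "V0", strict=True)
        R = self.V0.shape[0]
        if self.nu0 <= R - 1:
            raise ValueError(f"nu0 must exceed R-1={R - 1} for a proper prior")
        if self.g0.shape != (self.L0.shape[0], R):
            raise ValueError(
                f"g0 shape {self.g0.shape} must be (p={self.L0.shape[0]}, R={R})"
            )


def default_prior(p: int, R: int, l0_scale: float = 1e-6, v0_scale: float = 1.0,
                  nu0: float | None = None) -> FOSRPrior:
    """Weakly informative default: g0=0, L0=l0_scale*I, V0=v0_scale*I, nu0=R+2.

    nu0 = R + 2 is the smallest integer degrees of freedom giving the inverse
    Wishart a finite mean (V0 / (nu0 - R - 1) = V0).
    """
    return FOSRPrior(
        g0=np.zeros((p, R)),
        L0=l0_scale * np.eye(p),
        V0=v0_scale * np.eye(R),
        nu0=float(R + 2 if nu0 is None else nu0),
    )


@dataclasses.dataclass
class FOSRPosterior:
    """Conjugate posterior parameters (gn, Ln, Vn, nun)."""

    gn: np.ndarray
    Ln: np.ndarray
    Vn: np.ndarray
    nun: float
    prior: FOSRPrior | None = None

    @property
    def p(self) -> int:
        return self.gn.shape[0]

    @property
    def R(self) -> int:
        return self.gn.shape[1]

    def sigma_mean(self) -> np.ndarray:
        """Posterior mean of Sigma_eps, Vn/(nun - R - 1); requires nun > R+1."""
        denom = self.nun - self.R - 1
        if denom <= 0:
            raise ValueError("posterior mean of Sigma_eps undefined (nun <= R+1)")
        return self.Vn / denom


@dataclasses.dataclass
class PosteriorDraws:
    """M i.i.d. draws of (gamma*, Sigma_eps) from the joint posterior."""

    gamma_star: np.ndarray  # (M, p, R)
    sigma_eps: np.ndarray  # (M, R, R)
    M: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma_star.shape[0] != self.M or self.sigma_eps.shape[0] != self.M:
            raise ValueError("draw arrays inconsistent with M")


def posterior_params(G: np.ndarray, Z: DesignMatrix | np.ndarray,
                     prior: FOSRPrior) -> FOSRPosterior:
    """Closed-form conjugate update for the basis-space model G = Z gamma* + E*."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    design = Z if isinstance(Z, DesignMatrix) else DesignMatrix(np.asarray(Z))
    Zm = design.Z
    if G.shape[0] != Zm.shape[0]:
        raise ValueError(
            f"row mismatch: G has {G.shape[0]} rows, Z has {Zm.shape[0]}"
        )
    N = Zm.shape[0]
    Ln = Zm.T @ Zm + prior.L0
    rhs = Zm.T @ G + prior.L0 @ prior.g0
    try:
        gn = np.linalg.solve(Ln, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Ln = Z'Z + L0 is singular; the design is rank deficient and the "
            "prior precision L0 does not regularize it"
        ) from exc
    resid = G - Zm @ gn
    dg = gn - prior.g0
    Vn = prior.V0 + resid.T @ resid + dg.T @ prior.L0 @ dg
    Vn = 0.5 * (Vn + Vn.T)
    return FOSRPosterior(gn=gn, Ln=Ln, Vn=Vn, nun=float(prior.nu0 + N), prior=prior)


def draw_posterior(post: FOSRPosterior, M: int, seed: int = 0,
                   burn_in: int = 0, thin: int = 1) -> PosteriorDraws:
    """Sample M i.i.d. (gamma*, Sigma_eps) pairs by composition.

    Sigma_eps ~ InvWishart(Vn, nun); gamma* | Sigma_eps ~ MN(gn, Ln^{-1}, Sigma_eps),
    realised as gn + chol(Ln)^{-T} @ Xi @ chol(Sigma_eps)^T with Xi standard normal.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    p, R = post.p, post.R
    if post.nun <= R - 1:
        raise ValueError(f"improper posterior: nun={post.nun} <= R-1={R - 1}")
    rng = np.random.default_rng(seed)
    total = burn_in + M * thin
    try:
        chol_Ln = np.linalg.cholesky(post.Ln)
    except np.linalg.LinAlgError:
        chol_Ln = np.linalg.cholesky(post.Ln + 1e-10 * np.eye(p))
    sigma = invwishart.rvs(df=post.nun, scale=post.Vn, size=total, random_state=rng)
    sigma = np.asarray(sigma).reshape(total, R, R)
    # keep every `thin`-th draw after burn_in (draws are i.i.d.; this only
    # matters for reproducing a requested MCMC-style schedule)
    keep = slice(burn_in + thin - 1, total, thin)
    sigma = np.ascontiguousarray(sigma[keep])
    chol_sigma = np.linalg.cholesky(sigma + 1e-10 * np.eye(R))
    xi = rng.standard_normal((M, p, R))
    # row factor: solve chol_Ln^T x = xi  (gives row covariance Ln^{-1})
    half = np.linalg.solve(chol_Ln.T[None, :, :], xi)
    gamma = post.gn[None, :, :] + half @ np.swapaxes(chol_sigma, 1, 2)
    return PosteriorDraws(gamma_star=gamma, sigma_eps=sigma, M=M, seed=seed)
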