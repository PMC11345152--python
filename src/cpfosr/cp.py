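"""Canonical polyadic (CP) decomposition and the spatial tensor basis.

The multi-subject contrast tensor ``Y`` (p1 x p2 x p3 x N) is approximated by
a sum of R rank-one tensors,

    Y ~ sum_r lambda_r a1_r o a2_r o a3_r o g_r,

with every factor column (the three spatial modes and the subject scores
g_r alike) normalized to unit length and the component magnitudes absorbed
into the weight vector ``lambda``. The mode-4 unfolding (subjects along
rows) then satisfies ``Y_(4)rows = G @ L`` with the spatial basis

    L = Lambda (A3 (*) A2 (*) A1)^T   of shape (R x Nv),

where ``(*)`` is the Khatri-Rao product and the voxel index runs column-major
(first spatial index fastest). ``P = pinv(L)`` (Nv x R) projects voxel data to
the R-dimensional basis space.

Estimation is alternating least squares (ALS): truncated-SVD (HOSVD-style)
initialization plus seeded random restarts, iterating mode-wise linear
least-squares updates until the relative fit change falls below ``tol``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .tensor import ContrastTensor, khatri_rao, unfold

__all__ = ["CPBasis", "cp_decompose", "build_basis", "project", "reconstruct"]


@dataclasses.dataclass
class CPBasis:
    """A fitted CP tensor basis.

    ``lam`` holds the nonnegative component weights; ``A1, A2, A3`` are the
    spatial factor matrices with unit-norm columns; ``G`` holds per-subject
    scores (unit-norm columns when produced by :func:`cp_decompose`, whose
    magnitudes live in ``lam``; arbitrary scale is accepted). ``L`` (R x Nv)
    and ``P`` (Nv x R) are filled by :func:`build_basis`.
    """

    R: int
    lam: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    A3: np.ndarray
    G: np.ndarray
    fit_rel_error: float
    converged: bool = True
    n_iter: int = 0
    spatial_shape: tuple[int, int, int] | None = None
    mask_flat: np.ndarray | None = None
    L: np.ndarray | None = None
    P: np.ndarray | None = None
    effective_rank: int | None = None

    @property
    def n_voxels(self) -> int:
        if self.mask_flat is not None:
            return int(self.mask_flat.sum())
        return int(np.prod(self.spatial_shape))


def _als_fit(X, R, tol, max_iter, factors):
    """One ALS run; returns (factors, rel_error, n_iter, converged)."""
    K = X.ndim
    unf = [unfold(X, k + 1).T for k in range(K)]  # I_k x prod(rest), rows convention
    norm_x = float(np.linalg.norm(X))
    if norm_x == 0.0:
        zero = [np.zeros_like(f) for f in factors]
        return zero, 0.0, 0, True

    grams = [f.T @ f for f in factors]
    rel_prev = np.inf
    rel = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for n in range(K):
            others_desc = [factors[k] for k in range(K - 1, -1, -1) if k != n]
            kr = khatri_rao(others_desc)
            gram = np.ones((R, R))
            for k in range(K):
                if k != n:
                    gram *= grams[k]
            mttkrp = unf[n] @ kr  # I_n x R
            # least-squares solve against the (possibly singular) gram
            sol, *_ = np.linalg.lstsq(gram.T, mttkrp.T, rcond=None)
            factors[n] = sol.T
            if n < K - 1:
                # rebalance: keep intermediate modes unit-norm for stability
                norms = np.linalg.norm(factors[n], axis=0)
                norms[norms == 0] = 1.0
                factors[n] /= norms
            grams[n] = factors[n].T @ factors[n]
        # fit error via the last-mode MTTKRP identity
        gram_rest = np.ones((R, R))
        for k in range(K - 1):
            gram_rest *= grams[k]
        inner = float(np.sum(factors[K - 1] * mttkrp))
        quad = float(np.sum(gram_rest * grams[K - 1]))
        err2 = max(norm_x**2 - 2.0 * inner + quad, 0.0)
        rel = np.sqrt(err2) / norm_x
        # stop on relative improvement so that exactly low-rank tensors run
        # down to the numerical floor instead of halting mid-decay
        if abs(rel_prev - rel) < tol * max(rel, 0.0) + 1e-15:
            converged = True
            break
        rel_prev = rel
    # the Gram-based error formula cancels catastrophically below ~sqrt(eps);
    # report the exact residual instead (one reconstruction, done once)
    last = factors[K - 1] @ khatri_rao(
        [factors[k] for k in range(K - 2, -1, -1)]).T
    rel = np.linalg.norm(unf[K - 1] - last) / norm_x
    return factors, rel, it, converged


def _init_factors(X, R, rng, kind):
    K = X.ndim
    factors = []
    for k in range(K):
        dim = X.shape[k]
        if kind == "svd":
            mat = unfold(X, k + 1).T  # I_k x rest
            u, s, _ = np.linalg.svd(mat, full_matrices=False)
            ncomp = min(R, u.shape[1])
            f = np.empty((dim, R))
            f[:, :ncomp] = u[:, :ncomp]
            if ncomp < R:
                f[:, ncomp:] = rng.standard_normal((dim, R - ncomp))
        else:
            f = rng.standard_normal((dim, R))
        factors.append(f)
    return factors


def _normalize_cp(factors):
    """Normalize all four factor matrices to unit columns, weights into lam.

    The magnitude split between the weights and the score matrix is
    indeterminate in a CP model, so the canonical convention is used: every
    factor column (spatial modes and subject scores alike) has unit norm and
    lam >= 0 carries the full component magnitude. Spatial sign flips are
    pushed into G; components are sorted by descending weight.
    """
    A1, A2, A3, G = [f.copy() for f in factors]
    R = A1.shape[1]
    lam = np.ones(R)
    for A in (A1, A2, A3, G):
        norms = np.linalg.norm(A, axis=0)
        lam *= norms
        safe = np.where(norms == 0, 1.0, norms)
        A /= safe
    sign_total = np.ones(R)
    for A in (A1, A2, A3):
        idx = np.argmax(np.abs(A), axis=0)
        s = np.sign(A[idx, np.arange(R)])
        s[s == 0] = 1.0
        A *= s
        sign_total *= s
    G = G * sign_total  # (product of three flips) preserves each rank-one term
    order = np.argsort(-lam, kind="stable")
    return lam[order], A1[:, order], A2[:, order], A3[:, order], G[:, order]


def cp_decompose(
    y: ContrastTensor | np.ndarray,
    R: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
) -> CPBasis:
    """Fit a rank-``R`` CP decomposition of a 4D contrast tensor by ALS.

    The first start is HOSVD-style (truncated SVDs of the unfoldings); the
    remaining ``n_restarts - 1`` starts are seeded random. The best run by
    relative Frobenius reconstruction error is returned. Masked-out voxels
    (if the input carries a mask) are zeroed before fitting.
    """
    if R < 1:
        raise ValueError(f"rank must be >= 1, got {R}")
    if isinstance(y, ContrastTensor):
        X = y.masked_data()
        spatial_shape = y.spatial_shape
        mask_flat = y.mask_flat
    else:
        X = np.asarray(y, dtype=float)
        if X.ndim != 4:
            raise ValueError("expected a 4D tensor")
        spatial_shape = X.shape[:3]
        mask_flat = None
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite values")

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_restarts)):
        kind = "svd" if start == 0 else "random"
        init = _init_factors(X, R, rng, kind)
        factors, rel, n_iter, conv = _als_fit(X, R, tol, max_iter, init)
        if best is None or rel < best[1]:
            best = (factors, rel, n_iter, conv)
    factors, rel, n_iter, conv = best
    if not conv:
        warnings.warn(
            f"CP-ALS did not converge within {max_iter} iterations "
            f"(rel. error {rel:.3e})",
            RuntimeWarning,
        )
    lam, A1, A2, A3, G = _normalize_cp(factors)
    n_dead = int(np.sum(lam == 0))
    if n_dead:
        warnings.warn(f"{n_dead} CP component(s) are identically zero", RuntimeWarning)
    cp = CPBasis(
        R=R,
        lam=lam,
        A1=A1,
        A2=A2,
        A3=A3,
        G=G,
        fit_rel_error=float(rel),
        converged=bool(conv),
        n_iter=int(n_iter),
        spatial_shape=tuple(spatial_shape),
        mask_flat=mask_flat,
    )
    return build_basis(cp)


def spatial_basis_full(cp: CPBasis) -> np.ndarray:
    """Full-grid basis Lambda (A3 (*) A2 (*) A1)^T, shape (R, p1*p2*p3)."""
    kr = khatri_rao([cp.A3, cp.A2, cp.A1])  # (p1 p2 p3) x R, mode-1 fastest
    return cp.lam[:, None] * kr.T


def build_basis(cp: CPBasis) -> CPBasis:
    """Fill ``L`` (R x Nv) and its Moore-Penrose pseudoinverse ``P`` (Nv x R).

    With a mask active, only mask voxels enter the linearization. Warns when
    L is row-rank deficient (the projector then exists but L @ P != I).
    """
    L = spatial_basis_full(cp)
    if cp.mask_flat is not None:
        L = L[:, cp.mask_flat]
    P = np.linalg.pinv(L)
    eff = int(np.linalg.matrix_rank(L))
    if eff < cp.R:
        warnings.warn(
            f"basis L is rank deficient: effective rank {eff} < R={cp.R}",
            RuntimeWarning,
        )
    cp.L = L
    cp.P = P
    cp.effective_rank = eff
    return cp


def project(y: ContrastTensor | np.ndarray, cp: CPBasis) -> np.ndarray:
    """Project subject volumes onto the basis: (N x Nv) @ P -> (N x R) scores."""
    if cp.P is None:
        raise ValueError("basis not built; call build_basis first")
    if isinstance(y, ContrastTensor):
        if y.spatial_shape != tuple(cp.spatial_shape):
            raise ValueError(
                f"grid mismatch: tensor {y.spatial_shape} vs basis {cp.spatial_shape}"
            )
        mat = y.subject_matrix()
    else:
        y = np.asarray(y, dtype=float)
        if y.ndim != 4 or y.shape[:3] != tuple(cp.spatial_shape):
            raise ValueError("array dims do not match the basis grid")
        mat = unfold(y, 4).T
        if cp.mask_flat is not None:
            mat = mat[:, cp.mask_flat]
    if mat.shape[1] != cp.L.shape[1]:
        raise ValueError("voxel count mismatch between data and basis")
    return mat @ cp.P


def reconstruct(cp: CPBasis, G: np.ndarray | None = None) -> np.ndarray:
    """Rebuild the 4D tensor from the basis and (optionally new) scores."""
    if cp.L is None:
        raise ValueError("basis not built; call build_basis first")
    if cp.mask_flat is not None:
        raise ValueError("reconstruct to a full grid requires an unmasked basis")
    G = cp.G if G is None else np.asarray(G)
    mat = G @ cp.L  # N x Nv
    from .tensor import fold

    return fold(mat.T, 4, (*cp.spatial_shape, G.shape[0]))
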