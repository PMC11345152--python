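"""K-fold cross-validated selection of the CP rank.

For each fold and candidate rank R:

1. fit the CP factors on the training subjects only;
2. estimate gamma* on the training scores (closed-form posterior mean);
3. predict held-out scores Ghat_test = Z_test gamma*;
4. reconstruct Yhat_test = [[lambda; A1, A2, A3, Ghat_test]] with the
   training lambda and spatial factors;
5. record the Frobenius norm ||Y_test - Yhat_test||.

Per-fold norms are averaged per rank; the selected rank is the argmin with
ties broken toward the smaller rank (parsimony). Folds are random seeded
subject partitions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .cp import cp_decompose, project
from .fosr import DesignMatrix, FOSRPrior, default_prior, posterior_params
from .tensor import ContrastTensor

__all__ = ["CVResult", "cv_rank"]


@dataclasses.dataclass
class CVResult:
    ranks: list[int]
    cv_error: np.ndarray  # aligned with ranks; NaN for skipped ranks
    folds: int
    fold_assignment: np.ndarray  # subject -> fold index
    selected_rank: int
    seed: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"rank": self.ranks, "cv_error": self.cv_error})


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assign[chunk] = f
    return assign


def cv_rank(
    y: ContrastTensor,
    design: DesignMatrix,
    ranks: list[int],
    folds: int = 10,
    seed: int = 0,
    prior: FOSRPrior | None = None,
    aggregate: str = "mean_norm",
    cp_kwargs: dict | None = None,
) -> CVResult:
    """Cross-validate the CP rank on held-out subjects.

    ``aggregate`` is ``"mean_norm"`` (average of per-fold Frobenius norms,
    default) or ``"norm_of_mean"`` (norm of the subject-averaged residual).
    ``cp_kwargs`` tune the per-fold ALS fits (tol, max_iter, n_restarts).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ranks = [int(r) for r in ranks]
    if not ranks:
        raise ValueError("empty rank grid")
    if aggregate not in ("mean_norm", "norm_of_mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    n = y.n_subjects
    if design.n != n:
        raise ValueError("design rows must match subject count")
    rng = np.random.default_rng(seed)
    assign = _fold_assignment(n, folds, rng)
    min_train = min(int((assign != f).sum()) for f in range(folds))
    if min_train < design.p:
        raise ValueError("every fold must leave at least p training subjects")
    cp_kwargs = dict(tol=1e-6, max_iter=200, n_restarts=1) | (cp_kwargs or {})

    errors = np.full((len(ranks), folds), np.nan)
    for f in range(folds):
        train = assign != f
        test = ~train
        y_train = ContrastTensor(
            y.data[..., train], mask=y.mask, affine=y.affine,
            subject_ids=[s for s, t in zip(y.subject_ids, train) if t],
        )
        z_train = design.Z[train]
        z_test = design.Z[test]
        test_mat = y.subject_matrix()[test]  # N_test x Nv
        for i, r in enumerate(ranks):
            if r >= int(train.sum()):
                warnings.warn(
                    f"rank {r} >= training subjects ({int(train.sum())}); skipped",
                    RuntimeWarning,
                )
                continue
            cp = cp_decompose(y_train, r, seed=int(rng.integers(2**31)), **cp_kwargs)
            g_train = project(y_train, cp)
            pr = prior if prior is not None else default_prior(design.p, r)
            post = posterior_params(g_train, DesignMatrix(z_train), pr)
            g_hat = z_test @ post.gn
            resid = test_mat - g_hat @ cp.L
            if aggregate == "mean_norm":
                errors[i, f] = np.linalg.norm(resid)
            else:
                errors[i, f] = np.linalg.norm(resid.mean(axis=0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_error = np.nanmean(errors, axis=1)
    valid = np.isfinite(cv_error)
    if not valid.any():
        raise ValueError("no candidate rank could be evaluated")
    best_err = np.nanmin(cv_error)
    # argmin with ties broken toward the smaller rank
    selected = min(r for r, e in zip(ranks, cv_error) if np.isfinite(e) and e == best_err)
    return CVResult(
        ranks=ranks,
        cv_error=cv_error,
        folds=folds,
        fold_assignment=assign,
        selected_rank=int(selected),
        seed=seed,
    )
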