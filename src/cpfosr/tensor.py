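"""Tensor container and basic multilinear algebra.

Conventions
-----------
Mode indices are 1-based throughout. ``unfold(X, m)`` places the mode-``m``
index along *columns*; the remaining indices are linearized along rows with
the first remaining mode varying fastest. For a 2x3x4 tensor, ``unfold(X, 3)``
is the 6x4 matrix whose column ``k`` holds
``x[0,0,k], x[1,0,k], x[0,1,k], x[1,1,k], x[0,2,k], x[1,2,k]``.

Every voxel linearization in the package uses the same first-index-fastest
(column-major) order: a flattened voxel index satisfies
``v = j1 + p1*j2 + p1*p2*j3`` (zero-based). Volumes written to disk are
re-folded with the identical convention, so maps round-trip exactly.
"""

from __future__ import annotations

import dataclasses
from functools import reduce
from typing import Sequence

import numpy as np
from scipy.linalg import khatri_rao as _khatri_rao_pair

__all__ = [
    "ContrastTensor",
    "unfold",
    "fold",
    "khatri_rao",
    "ravel_voxels",
    "unravel_voxels",
]


def unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization with the mode index along columns.

    Parameters
    ----------
    x : ndarray
        Tensor of any order K >= 1.
    mode : int
        1-based mode to place along columns.

    Returns
    -------
    ndarray of shape (prod(other dims), x.shape[mode-1])
    """
    x = np.asarray(x)
    if not 1 <= mode <= x.ndim:
        raise ValueError(f"mode must be in [1, {x.ndim}], got {mode}")
    moved = np.moveaxis(x, mode - 1, -1)
    return moved.reshape(-1, x.shape[mode - 1], order="F")


def fold(xmat: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Exact inverse of :func:`unfold`: rebuild a tensor of ``shape``."""
    xmat = np.asarray(xmat)
    shape = tuple(int(s) for s in shape)
    if not 1 <= mode <= len(shape):
        raise ValueError(f"mode must be in [1, {len(shape)}], got {mode}")
    rest = [shape[i] for i in range(len(shape)) if i != mode - 1]
    expected = (int(np.prod(rest)), shape[mode - 1])
    if xmat.shape != expected:
        raise ValueError(
            f"matrix shape {xmat.shape} inconsistent with shape={shape}, "
            f"mode={mode} (expected {expected})"
        )
    moved = xmat.reshape(rest + [shape[mode - 1]], order="F")
    return np.moveaxis(moved, -1, mode - 1)


def khatri_rao(factors: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product of matrices sharing a column count.

    Column ``r`` of the result is the Kronecker product of the ``r``-th
    columns of the inputs *in the given order* (later inputs vary fastest,
    the ``numpy.kron`` convention). With factors ``[A3, A2, A1]`` the row
    index runs over voxels with the mode-1 index fastest, matching
    :func:`unfold`'s linearization.
    """
    factors = [np.asarray(f) for f in factors]
    if not factors:
        raise ValueError("need at least one factor")
    ncols = {f.shape[1] for f in factors}
    if len(ncols) != 1:
        raise ValueError(f"factors must share a column count, got {sorted(ncols)}")
    return reduce(_khatri_rao_pair, factors)


def ravel_voxels(vol: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Flatten a 3D volume to a voxel vector (column-major; mask-aware)."""
    flat = np.asarray(vol).reshape(-1, order="F")
    if mask is not None:
        flat = flat[np.asarray(mask, bool).reshape(-1, order="F")]
    return flat


def unravel_voxels(
    values: np.ndarray,
    shape: Sequence[int],
    mask: np.ndarray | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Inverse of :func:`ravel_voxels`; out-of-mask voxels get ``fill``."""
    shape = tuple(shape)
    if mask is None:
        return np.asarray(values).reshape(shape, order="F")
    out = np.full(int(np.prod(shape)), fill, dtype=float)
    out[np.asarray(mask, bool).reshape(-1, order="F")] = values
    return out.reshape(shape, order="F")


@dataclasses.dataclass
class ContrastTensor:
    """Stack of per-subject 3D contrast maps on a common grid.

    Attributes
    ----------
    data : ndarray, shape (p1, p2, p3, N)
        One 3D contrast volume per subject, subjects along the last axis.
    mask : ndarray of bool, shape (p1, p2, p3), optional
        Restricts the active voxel set; default is the full grid.
    affine : ndarray (4, 4), optional
        Voxel-to-world transform carried opaquely from the input volumes.
    subject_ids : list of str
        Identifiers aligned with the subject axis.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (p1,p2,p3,N), got {self.data.ndim}D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != spatial dims {self.data.shape[:3]}"
                )
        if self.affine is None:
            self.affine = np.eye(4)
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(self.data.shape[3])]
        if len(self.subject_ids) != self.data.shape[3]:
            raise ValueError("subject_ids length must equal the subject dimension")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        """Active voxel count Nv (mask-aware)."""
        if self.mask is None:
            return int(np.prod(self.spatial_shape))
        return int(self.mask.sum())

    @property
    def mask_flat(self) -> np.ndarray | None:
        """Column-major flattening of the mask, or None for full grid."""
        if self.mask is None:
            return None
        return self.mask.reshape(-1, order="F")

    def subject_matrix(self) -> np.ndarray:
        """Subjects-by-voxels matrix (N x Nv), mask-aware.

        This is the transpose of ``unfold(data, 4)`` restricted to active
        voxels: the representation in which the function-on-scalar model
        ``Y = Z gamma + E`` is written.
        """
        mat = unfold(self.data, 4).T
        if self.mask is not None:
            mat = mat[:, self.mask_flat]
        return mat

    def masked_data(self) -> np.ndarray:
        """4D array with out-of-mask voxels zeroed (used for CP fitting)."""
        if self.mask is None:
            return self.data
        return np.where(self.mask[..., None], self.data, 0.0)
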