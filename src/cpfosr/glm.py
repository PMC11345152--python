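"""Subject-level voxelwise GLM producing contrast maps.

The BOLD time series at each voxel is modeled as

    y_t(v) = sum_j b_j(v) x_j(t) + e_t(v),

where x_j(t) is the stimulus-j indicator convolved with a canonical
double-gamma hemodynamic response function (HRF). Coefficients are fit by
ordinary least squares voxel-wise, and a contrast map c'B feeds the
multi-subject stage. Errors are treated as i.i.d. — no prewhitening, drift
or motion modeling (stated limitation; this is deliberately the minimal
subject-level engine).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["TaskDesign", "SubjectMaps", "canonical_hrf", "build_design",
           "fit_glm_contrast"]


@dataclasses.dataclass
class TaskDesign:
    X: np.ndarray  # T x J convolved regressors
    regressor_names: list[str]
    TR: float

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class SubjectMaps:
    B: np.ndarray  # J x Nv
    contrast_map: np.ndarray  # (Nv,)
    residual_sd: np.ndarray | None = None


def canonical_hrf(t: np.ndarray, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, ratio: float = 1.0 / 6.0,
                  ) -> np.ndarray:
    """Double-gamma HRF (gamma-pdf peak minus scaled undershoot), max-normalized."""
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, peak_delay) - ratio * _gamma_dist.pdf(t, undershoot_delay)
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    onsets: dict[str, list[tuple[float, float]]],
    T: int,
    TR: float,
    oversample: int = 16,
    hrf_kwargs: dict | None = None,
) -> TaskDesign:
    """Convolve per-stimulus (onset, duration) boxcars with the canonical HRF.

    Parameters
    ----------
    onsets : mapping stimulus name -> list of (onset_s, duration_s).
        A duration of 0 means an instantaneous event. A stimulus with an
        empty event list yields an all-zero column.
    T : number of volumes; TR : sampling interval in seconds.
    """
    if not onsets:
        raise ValueError("at least one stimulus is required")
    if T <= 0 or TR <= 0:
        raise ValueError("T and TR must be positive")
    dt = TR / oversample
    n_fine = T * oversample
    t_fine = np.arange(n_fine) * dt
    hrf = canonical_hrf(np.arange(0, 32.0, dt), **(hrf_kwargs or {}))
    cols = []
    names = []
    total = T * TR
    for name, events in onsets.items():
        box = np.zeros(n_fine)
        for onset, dur in events:
            if not 0 <= onset < total:
                raise ValueError(
                    f"onset {onset}s for stimulus {name!r} outside [0, {total}s)"
                )
            i0 = int(round(onset / dt))
            i1 = max(i0 + 1, int(round((onset + dur) / dt)))  # delta for dur=0
            box[i0:min(i1, n_fine)] = 1.0
        reg = np.convolve(box, hrf)[:n_fine]
        cols.append(reg[::oversample])
        names.append(name)
    X = np.column_stack(cols)
    return TaskDesign(X=X, regressor_names=names, TR=TR)


def fit_glm_contrast(
    data: np.ndarray,
    design: TaskDesign,
    contrast: np.ndarray,
) -> SubjectMaps:
    """Voxelwise OLS of the time series on the task design; contrast = c'B.

    ``data`` is (T, Nv) time-by-voxels, or a 4D (p1, p2, p3, T) volume series
    which is flattened column-major to match the package voxel order.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        T = data.shape[3]
        data = data.reshape(-1, T, order="F").T
    elif data.ndim == 2:
        T = data.shape[0]
    else:
        raise ValueError("data must be (T, Nv) or (p1, p2, p3, T)")
    X = design.X
    if X.shape[0] != T:
        raise ValueError(f"time mismatch: data has {T}, design has {X.shape[0]}")
    J = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < J:
        # name the columns involved in the collinearity via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(X)[1]))
        bad = [design.regressor_names[j] for j in np.argsort(r_diag)[: J - rank]]
        raise ValueError(f"rank-deficient design; collinear columns include {bad}")
    c = np.asarray(contrast, dtype=float).ravel()
    if c.shape[0] != J:
        raise ValueError(f"contrast length {c.shape[0]} != {J} regressors")
    B, _, _, _ = np.linalg.lstsq(X, data, rcond=None)  # J x Nv
    resid = data - X @ B
    dof = max(T - J, 1)
    return SubjectMaps(
        B=B,
        contrast_map=c @ B,
        residual_sd=np.sqrt((resid**2).sum(axis=0) / dof),
    )
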