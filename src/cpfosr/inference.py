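"""Voxel-space inference: back-projection, SimBaS, joint bands, clusters.

Posterior draws of the basis-space coefficients gamma* are mapped to voxel
space through the basis L (gamma = gamma* L). For a contrast vector c the
voxel map is C(v) = c' gamma(v). Simultaneous inference uses the max
standardized deviation statistic per draw,

    z(m) = max_v | C^(m)(v) - Chat(v) | / sd(C(v)),

whose (1-alpha) order statistic q gives joint credible bands
Chat(v) +/- q * sd(v), and the simultaneous band scores

    P_SimBaS(v) = (1/M) sum_m 1{ |Chat(v)|/sd(v) <= z(m) },

the minimum alpha (on the 1/M grid) at which the joint band excludes zero.
Voxels with zero posterior sd cannot be standardized; they are ineligible,
never enter the max, and get P_SimBaS = 1.

Back-projection is streamed over voxel chunks so no M x Nv array is ever
materialized.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .cp import CPBasis
from .fosr import PosteriorDraws
from .tensor import unravel_voxels

__all__ = [
    "BackprojectedStats",
    "SimBaSResult",
    "backproject_stats",
    "simbas_map",
    "joint_bands",
    "flag_clusters",
    "simbas_inference",
]

_CONN_STRUCTURE = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class BackprojectedStats:
    """Per-voxel posterior summaries and per-draw max statistics."""

    contrast: np.ndarray
    c_hat: np.ndarray  # (Nv,) posterior mean
    c_sd: np.ndarray  # (Nv,) posterior sd (ddof=1)
    z_stats: np.ndarray | None  # (M,) max standardized deviation per draw
    eligible: np.ndarray  # (Nv,) bool, c_sd > 0
    degenerate: bool  # True when no voxel could be standardized
    M: int


def backproject_stats(
    draws: PosteriorDraws,
    cp: CPBasis,
    contrast: np.ndarray,
    chunk_size: int = 8192,
) -> BackprojectedStats:
    """Compute Chat, sd and z(m) for contrast c, streaming over voxel chunks.

    Per draw m the voxel map is C^(m) = (c' gamma*^(m)) L. Mean and sd are
    accumulated chunk-wise (sd with denominator M-1); a second chunked pass
    forms z(m) as the running max over eligible voxels.
    """
    if cp.L is None:
        raise ValueError("basis not built; call build_basis first")
    c = np.asarray(contrast, dtype=float).ravel()
    if c.shape[0] != draws.gamma_star.shape[1]:
        raise ValueError(
            f"contrast length {c.shape[0]} != p={draws.gamma_star.shape[1]}"
        )
    M = draws.M
    D = np.einsum("p,mpr->mr", c, draws.gamma_star)  # (M, R) basis-space draws
    L = cp.L
    nv = L.shape[1]
    d_mean = D.mean(axis=0)
    c_hat = d_mean @ L
    c_sd = np.empty(nv)
    z = np.zeros(M)
    any_eligible = False
    for lo in range(0, nv, chunk_size):
        sl = slice(lo, min(lo + chunk_size, nv))
        C = D @ L[:, sl]  # (M, chunk)
        dev = C - c_hat[sl]
        sd = np.sqrt((dev**2).sum(axis=0) / max(M - 1, 1))
        c_sd[sl] = sd
        elig = sd > 0
        if elig.any():
            any_eligible = True
            np.maximum(z, np.abs(dev[:, elig] / sd[elig]).max(axis=1), out=z)
    eligible = c_sd > 0
    degenerate = not any_eligible
    return BackprojectedStats(
        contrast=c,
        c_hat=c_hat,
        c_sd=c_sd,
        z_stats=None if degenerate else z,
        eligible=eligible,
        degenerate=degenerate,
        M=M,
    )


def simbas_map(stats: BackprojectedStats) -> np.ndarray:
    """Simultaneous band scores: P(v) = (1/M) #{m : |Chat(v)|/sd(v) <= z(m)}.

    Ineligible voxels get P = 1 (they can never be flagged).
    """
    nv = stats.c_hat.shape[0]
    p = np.ones(nv)
    if stats.degenerate:
        return p
    z_sorted = np.sort(stats.z_stats)
    t = np.abs(stats.c_hat[stats.eligible]) / stats.c_sd[stats.eligible]
    # #{z >= t} = M - #{z < t}
    count = stats.M - np.searchsorted(z_sorted, t, side="left")
    p[stats.eligible] = count / stats.M
    return p


def joint_bands(stats: BackprojectedStats, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """100(1-alpha)% joint credible band Chat(v) +/- q(1-alpha) sd(v).

    q(1-alpha) is the ceil((1-alpha)M)-th ascending order statistic of the
    z(m); this convention makes the band inversion agree exactly with
    :func:`simbas_map` on the 1/M grid.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if stats.degenerate:
        raise ValueError("degenerate inference: all voxels have zero posterior sd")
    M = stats.M
    if alpha * M < 1.0:
        raise ValueError(
            f"alpha={alpha} is below the 1/M resolution of M={M} draws; "
            f"increase M to at least {math.ceil(1 / alpha)}"
        )
    # ceil((1-alpha)M) == M - floor(alpha*M); snap alpha*M to an integer when
    # it is one up to rounding, so alpha on the 1/M grid hits the exact order
    # statistic and the band inverts to P_SimBaS identically
    am = alpha * M
    k = round(am) if math.isclose(am, round(am), abs_tol=1e-9) else math.floor(am)
    idx = min(max(M - int(k), 1), M)
    q = np.sort(stats.z_stats)[idx - 1]
    return stats.c_hat - q * stats.c_sd, stats.c_hat + q * stats.c_sd


def flag_clusters(
    p_simbas: np.ndarray,
    alpha: float = 0.01,
    min_size: int = 125,
    connectivity: int = 26,
    stat_map: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of {v : P_SimBaS(v) < alpha}, size-thresholded.

    Parameters
    ----------
    p_simbas : 3D array of simultaneous band scores.
    connectivity : one of 6, 18, 26 (3D neighbourhoods).
    stat_map : optional 3D array (e.g. |Chat|/sd) used for cluster peaks.

    Returns
    -------
    (table, labels) : table has one row per retained cluster sorted by size
    descending (columns label, size, peak_i, peak_j, peak_k, peak_stat);
    labels is the relabelled 3D integer map (0 = background).
    """
    p_simbas = np.asarray(p_simbas)
    if p_simbas.ndim != 3:
        raise ValueError("p_simbas must be a 3D volume")
    if connectivity not in _CONN_STRUCTURE:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_STRUCTURE)}")
    structure = ndimage.generate_binary_structure(3, _CONN_STRUCTURE[connectivity])
    flagged = p_simbas < alpha
    raw_labels, n_raw = ndimage.label(flagged, structure=structure)
    rows = []
    out_labels = np.zeros_like(raw_labels)
    if n_raw:
        sizes = ndimage.sum_labels(np.ones_like(raw_labels), raw_labels,
                                   index=np.arange(1, n_raw + 1)).astype(int)
        keep = [(int(s), lab) for lab, s in zip(range(1, n_raw + 1), sizes)
                if s >= min_size]
        keep.sort(key=lambda t: -t[0])
        stat = np.zeros_like(p_simbas) if stat_map is None else np.asarray(stat_map)
        for new_lab, (size, old_lab) in enumerate(keep, start=1):
            comp = raw_labels == old_lab
            out_labels[comp] = new_lab
            idx = np.argmax(np.where(comp, stat, -np.inf))
            pi, pj, pk = np.unravel_index(idx, p_simbas.shape)
            rows.append(
                dict(label=new_lab, size=size, peak_i=int(pi), peak_j=int(pj),
                     peak_k=int(pk), peak_stat=float(stat[pi, pj, pk])),
            )
    table = pd.DataFrame(rows, columns=["label", "size", "peak_i", "peak_j",
                                        "peak_k", "peak_stat"])
    return table, out_labels


@dataclasses.dataclass
class SimBaSResult:
    """Full voxel-space inference for one contrast."""

    contrast: np.ndarray
    alpha: float
    M: int
    c_hat: np.ndarray  # 3D
    c_sd: np.ndarray  # 3D
    p_simbas: np.ndarray  # 3D
    z_stats: np.ndarray | None
    band_lo: np.ndarray  # 3D
    band_hi: np.ndarray  # 3D
    flagged: np.ndarray  # 3D bool: P_SimBaS < alpha
    clusters: pd.DataFrame
    cluster_labels: np.ndarray  # 3D int
    n_ineligible: int
    degenerate: bool

    def n_active_voxels(self) -> int:
        """Voxels inside retained clusters."""
        return int((self.cluster_labels > 0).sum())


def simbas_inference(
    draws: PosteriorDraws,
    cp: CPBasis,
    contrast: np.ndarray,
    alpha: float = 0.01,
    min_size: int = 125,
    connectivity: int = 26,
    chunk_size: int = 8192,
) -> SimBaSResult:
    """End-to-end inference: back-project, score, band, threshold, cluster."""
    stats = backproject_stats(draws, cp, contrast, chunk_size=chunk_size)
    shape = tuple(cp.spatial_shape)
    mask = None if cp.mask_flat is None else cp.mask_flat.reshape(shape, order="F")
    p_flat = simbas_map(stats)
    to_vol = lambda v, fill=0.0: unravel_voxels(v, shape, mask, fill=fill)
    p_vol = to_vol(p_flat, fill=1.0)
    if stats.degenerate:
        lo = hi = np.zeros(p_flat.shape)
    else:
        lo, hi = joint_bands(stats, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stats.eligible, np.abs(stats.c_hat) / stats.c_sd, 0.0)
    table, labels = flag_clusters(
        p_vol, alpha=alpha, min_size=min_size, connectivity=connectivity,
        stat_map=to_vol(t),
    )
    return SimBaSResult(
        contrast=stats.contrast,
        alpha=alpha,
        M=stats.M,
        c_hat=to_vol(stats.c_hat),
        c_sd=to_vol(stats.c_sd),
        p_simbas=p_vol,
        z_stats=stats.z_stats,
        band_lo=to_vol(lo),
        band_hi=to_vol(hi),
        flagged=p_vol < alpha,
        clusters=table,
        cluster_labels=labels,
        n_ineligible=int((~stats.eligible).sum()),
        degenerate=stats.degenerate,
    )
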