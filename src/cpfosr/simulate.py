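"""Synthetic multi-subject contrast tensors with known low-rank truth.

The generator emulates the structure the multi-subject model fits: smooth
unimodal spatial components of exact CP rank R_true (products of 1D Gaussian
bumps with distinct peak locations), subject scores driven by covariates
through G = Z gamma*_true + subject noise, and i.i.d. Gaussian voxel noise:

    Y = fold(G @ L_true, 4) + sigma_voxel * noise.

Default study conditions: a (30, 30, 30) grid, N = 50 subjects, R_true = 4
components, a design with intercept plus one binary covariate, unit-scale
subject-score noise (sigma_subject = 1), and voxel noise set by a target
signal-to-noise ratio SNR = ||signal||_F / ||noise||_F = 5.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cp import CPBasis, build_basis
from .fosr import DesignMatrix
from .tensor import ContrastTensor, fold

__all__ = ["SyntheticTruth", "gen_multisubject", "gen_null"]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth backing a synthetic dataset (regenerable from seed)."""

    cp_true: CPBasis
    gamma_true: np.ndarray  # p x R basis-space coefficients
    gamma_vox_true: np.ndarray  # p x Nv voxel-space coefficient maps
    sigma_subject: float
    sigma_voxel: float
    snr: float  # realized ||signal||_F / ||noise||_F (inf when noise-free)
    seed: int


def _bump_profile(n: int, center: float, width: float) -> np.ndarray:
    x = np.arange(n)
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _spatial_factor(n: int, R: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm columns of smooth bumps with distinct, jittered peaks."""
    centers = (np.arange(R) + 0.5) / R * (n - 1)
    centers = centers + rng.uniform(-0.05, 0.05, size=R) * n
    widths = n / (R + 2) * rng.uniform(0.8, 1.2, size=R)
    cols = np.column_stack(
        [_bump_profile(n, c, w) for c, w in zip(centers, widths)]
    )
    return cols / np.linalg.norm(cols, axis=0)


def gen_multisubject(
    dims: tuple[int, int, int] = (30, 30, 30),
    N: int = 50,
    R_true: int = 4,
    p: int = 2,
    effect_scales: np.ndarray | None = None,
    sigma_subject: float = 1.0,
    sigma_voxel: float | None = None,
    snr: float = 5.0,
    seed: int = 0,
) -> tuple[ContrastTensor, DesignMatrix, SyntheticTruth]:
    """Generate (tensor, design, truth) from the low-rank covariate model.

    ``sigma_voxel`` overrides ``snr`` when given; ``sigma_voxel=0`` (or
    ``snr=inf``) produces a noise-free tensor of exact CP rank R_true.
    The design holds an intercept, a binary covariate, and (for p > 3)
    standardized continuous covariates.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 4:
        raise ValueError("dims must be three integers >= 4")
    if any(R_true > d for d in dims):
        raise ValueError(f"R_true={R_true} exceeds a spatial dimension {dims}")
    if N <= p:
        raise ValueError(f"need N > p, got N={N}, p={p}")
    rng = np.random.default_rng(seed)
    if effect_scales is None:
        effect_scales = np.concatenate([[1.0], 0.5 * np.ones(p - 1)])
    effect_scales = np.asarray(effect_scales, dtype=float)
    if effect_scales.shape != (p,):
        raise ValueError(f"effect_scales must have length p={p}")

    A1 = _spatial_factor(dims[0], R_true, rng)
    A2 = _spatial_factor(dims[1], R_true, rng)
    A3 = _spatial_factor(dims[2], R_true, rng)
    lam = np.linspace(1.6, 0.9, R_true)

    # design: intercept, binary covariate, then standardized continuous ones
    Z = np.ones((N, p))
    names = ["intercept"]
    if p >= 2:
        Z[:, 1] = rng.integers(0, 2, size=N).astype(float)
        names.append("group")
    for j in range(2, p):
        col = rng.standard_normal(N)
        Z[:, j] = (col - col.mean()) / col.std()
        names.append(f"cov{j}")

    gamma_true = effect_scales[:, None] * rng.standard_normal((p, R_true))
    # every component carries population-mean signal (as task-activation
    # components do): signed intercept loadings bounded away from zero
    gamma_true[0] = effect_scales[0] * rng.choice([-1.0, 1.0], R_true) \
        * rng.uniform(0.75, 1.25, R_true)
    G = Z @ gamma_true + sigma_subject * rng.standard_normal((N, R_true))

    cp_true = CPBasis(
        R=R_true, lam=lam, A1=A1, A2=A2, A3=A3, G=G,
        fit_rel_error=0.0, spatial_shape=dims,
    )
    build_basis(cp_true)
    signal = G @ cp_true.L  # N x Nv
    signal_norm = np.linalg.norm(signal)
    nv = signal.shape[1]
    if sigma_voxel is None:
        if not np.isfinite(snr):
            sigma_voxel = 0.0
        else:
            # E||noise||_F^2 = sigma^2 * Nv * N; match the target SNR in expectation
            sigma_voxel = signal_norm / (snr * np.sqrt(nv * N))
    sigma_voxel = float(sigma_voxel)
    noise = sigma_voxel * rng.standard_normal(signal.shape)
    noise_norm = np.linalg.norm(noise)
    data = fold((signal + noise).T, 4, (*dims, N))

    tensor = ContrastTensor(data)
    design = DesignMatrix(Z, column_names=names, subject_ids=tensor.subject_ids)
    truth = SyntheticTruth(
        cp_true=cp_true,
        gamma_true=gamma_true,
        gamma_vox_true=gamma_true @ cp_true.L,
        sigma_subject=float(sigma_subject),
        sigma_voxel=sigma_voxel,
        snr=float(signal_norm / noise_norm) if noise_norm > 0 else float("inf"),
        seed=seed,
    )
    return tensor, design, truth


def gen_null(
    dims: tuple[int, int, int] = (30, 30, 30),
    N: int = 50,
    R_true: int = 4,
    seed: int = 0,
    intercept_scale: float = 1.0,
    **kwargs,
) -> tuple[ContrastTensor, DesignMatrix, SyntheticTruth]:
    """Dataset whose covariate effects are exactly zero (intercept only).

    Used for family-wise error and simultaneous-coverage simulations: the
    true map of every non-intercept covariate is identically zero.
    """
    p = kwargs.pop("p", 2)
    scales = np.concatenate([[intercept_scale], np.zeros(p - 1)])
    return gen_multisubject(
        dims=dims, N=N, R_true=R_true, p=p, effect_scales=scales, seed=seed,
        **kwargs,
    )
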