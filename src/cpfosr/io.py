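"""NIfTI and table I/O, run configuration, and the persisted model container.

Conventions: volumes are NIfTI-1 (.nii / .nii.gz) read with nibabel; tables
are delimited text (TSV by default) whose first column is ``subject_id``;
the intercept column is added automatically when building the design.
Every volume written re-folds the internal column-major voxel linearization,
so write-then-read round-trips bit-exactly for finite values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cp import CPBasis, build_basis
from .fosr import DesignMatrix, FOSRPosterior, PosteriorDraws
from .tensor import ContrastTensor

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_covariates",
    "assemble_tensor",
    "save_model",
    "load_model",
]

_CONFIG_KEYS = {
    "ranks": str,
    "folds": int,
    "rank": int,
    "M": int,
    "alpha": float,
    "min_size": int,
    "connectivity": int,
    "l0_scale": float,
    "v0_scale": float,
    "nu0": float,
    "seed": int,
    "cp_tol": float,
    "cp_max_iter": int,
    "cp_restarts": int,
}


@dataclasses.dataclass
class RunConfig:
    """Flat key=value run configuration with provenance hashing."""

    ranks: str = "2,3,4,5,6,8"
    folds: int = 10
    rank: int = 4
    M: int = 2000
    alpha: float = 0.01
    min_size: int = 125
    connectivity: int = 26
    l0_scale: float = 1e-6
    v0_scale: float = 1.0
    nu0: float = -1.0  # <0 means "use R + 2"
    seed: int = 0
    cp_tol: float = 1e-8
    cp_max_iter: int = 500
    cp_restarts: int = 3

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values = {}
        for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{line_no}: unknown config key {key!r}")
            values[key] = _CONFIG_KEYS[key](val)
        return cls(**values)

    def rank_grid(self) -> list[int]:
        return [int(r) for r in self.ranks.split(",") if r.strip()]

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def write_resolved(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data, img.affine


def write_volume(path: str | Path, data: np.ndarray,
                 affine: np.ndarray | None = None) -> None:
    """Write a volume as NIfTI-1 with the given affine (identity default)."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_covariates(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a covariate table; first column must be ``subject_id``."""
    table = pd.read_csv(path, sep=sep)
    if table.columns[0] != "subject_id":
        raise ValueError(
            f"{path}: first column must be 'subject_id', got {table.columns[0]!r}"
        )
    table["subject_id"] = table["subject_id"].astype(str)
    return table


def design_from_table(table: pd.DataFrame) -> DesignMatrix:
    """Build a design with a leading intercept from a covariate table."""
    covs = table.drop(columns=["subject_id"])
    Z = np.column_stack([np.ones(len(table)), covs.to_numpy(dtype=float)])
    return DesignMatrix(
        Z,
        column_names=["intercept"] + list(covs.columns),
        subject_ids=list(table["subject_id"]),
    )


def assemble_tensor(
    volume_paths: dict[str, str | Path] | list[str | Path],
    covariate_table: str | Path | pd.DataFrame,
    mask: str | Path | None = None,
) -> tuple[ContrastTensor, DesignMatrix]:
    """Stack per-subject volumes into a 4D tensor aligned with the covariates.

    ``volume_paths`` maps subject_id -> path (or is a list of paths whose file
    stems are the subject IDs). Subject order follows the covariate table;
    missing or unmatched IDs raise with the offending names. Non-finite voxels
    are masked out (intersected with any explicit mask).
    """
    if not isinstance(covariate_table, pd.DataFrame):
        covariate_table = read_covariates(covariate_table)
    if isinstance(volume_paths, dict):
        by_id = {str(k): Path(v) for k, v in volume_paths.items()}
    else:
        by_id = {}
        for path in volume_paths:
            path = Path(path)
            stem = path.name.removesuffix(".gz").removesuffix(".nii")
            by_id[stem] = path
    ids = list(covariate_table["subject_id"])
    missing = [s for s in ids if s not in by_id]
    if missing:
        raise ValueError(f"covariate rows without a volume: {missing}")
    extra = [s for s in by_id if s not in set(ids)]
    if extra:
        raise ValueError(f"volumes without a covariate row: {sorted(extra)}")

    vols = []
    affine = None
    shape = None
    for sid in ids:
        data, aff = read_volume(by_id[sid])
        if shape is None:
            shape, affine = data.shape, aff
        elif data.shape != shape or not np.allclose(aff, affine, atol=1e-6):
            raise ValueError(f"grid mismatch for volume {by_id[sid]}")
        vols.append(data)
    data4d = np.stack(vols, axis=-1)

    mask_arr = None
    if mask is not None:
        mask_arr, _ = read_volume(mask)
        mask_arr = mask_arr > 0
    finite = np.all(np.isfinite(data4d), axis=-1)
    if not finite.all():
        n_bad = int((~finite).sum())
        import logging

        logging.getLogger(__name__).warning(
            "masking out %d voxels with non-finite values", n_bad
        )
        np.nan_to_num(data4d, copy=False)
        mask_arr = finite if mask_arr is None else (mask_arr & finite)

    tensor = ContrastTensor(data4d, mask=mask_arr, affine=affine, subject_ids=ids)
    return tensor, design_from_table(covariate_table)


def save_model(path: str | Path, cp: CPBasis, post: FOSRPosterior,
               draws: PosteriorDraws, config: RunConfig,
               affine: np.ndarray | None = None,
               column_names: list[str] | None = None) -> None:
    """Persist the fitted model to a single .npz container (see README)."""
    np.savez_compressed(
        str(path),
        lam=cp.lam, A1=cp.A1, A2=cp.A2, A3=cp.A3, G=cp.G,
        fit_rel_error=cp.fit_rel_error,
        spatial_shape=np.asarray(cp.spatial_shape),
        mask_flat=(np.zeros(0, bool) if cp.mask_flat is None else cp.mask_flat),
        gn=post.gn, Ln=post.Ln, Vn=post.Vn, nun=post.nun,
        gamma_star=draws.gamma_star, sigma_eps=draws.sigma_eps,
        draw_seed=-1 if draws.seed is None else draws.seed,
        affine=np.eye(4) if affine is None else affine,
        column_names=np.asarray(column_names or [], dtype=object),
        config_text=config.to_text(),
        config_hash=config.digest(),
        version=_package_version(),
    )


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns (cp, post, draws, meta)."""
    with np.load(str(path), allow_pickle=True) as z:
        mask_flat = z["mask_flat"]
        cp = CPBasis(
            R=int(z["lam"].shape[0]), lam=z["lam"], A1=z["A1"], A2=z["A2"],
            A3=z["A3"], G=z["G"], fit_rel_error=float(z["fit_rel_error"]),
            spatial_shape=tuple(int(d) for d in z["spatial_shape"]),
            mask_flat=None if mask_flat.size == 0 else mask_flat,
        )
        build_basis(cp)
        post = FOSRPosterior(gn=z["gn"], Ln=z["Ln"], Vn=z["Vn"],
                             nun=float(z["nun"]))
        draws = PosteriorDraws(
            gamma_star=z["gamma_star"], sigma_eps=z["sigma_eps"],
            M=int(z["gamma_star"].shape[0]),
            seed=None if int(z["draw_seed"]) < 0 else int(z["draw_seed"]),
        )
        meta = {
            "affine": z["affine"],
            "column_names": list(z["column_names"]),
            "config_text": str(z["config_text"]),
            "config_hash": str(z["config_hash"]),
            "version": str(z["version"]),
        }
    return cp, post, draws, meta


def _package_version() -> str:
    from . import __version__

    return __version__


def write_cluster_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_sidecar(path: str | Path, config: RunConfig, **extra) -> None:
    payload = {"config_hash": config.digest(), "version": _package_version()}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
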