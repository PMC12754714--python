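"""Readers and writers: NIfTI/GIFTI images, covariate tables, archives."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .domain import SpatialDomain
from .kernel import LowRankBasis
from .summary import EffectSummary

MAP_TYPES = ("mean", "sd", "lower", "upper", "p_plus", "es", "active")


@dataclass
class VolumeGeometry:
    shape: tuple
    affine: np.ndarray


def read_images(
    paths, mask_path, use_mm_coords: bool = False
) -> tuple[np.ndarray, SpatialDomain, VolumeGeometry]:
    """Load volumetric data: per-participant 3-D NIfTIs or one 4-D NIfTI.

    Applies the binary mask and flattens to an N×V matrix.  All images must
    share the mask's grid and affine; offenders are named.  Returns
    (Y, domain, geometry); ``Y`` is the raw matrix — pair it with a
    covariate table to build a :class:`RegressionDataset`.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("empty mask")
    affine = mask_img.affine
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        _check_grid(img, mask.shape, affine, str(paths))
        vols = np.asarray(img.dataobj, dtype=float)
        if vols.ndim != 4:
            raise ValueError("single-file input must be a 4-D volume")
        Y = vols[mask].T  # (N, V)
    else:
        rows = []
        bad = []
        for p in paths:
            img = nib.load(str(p))
            try:
                _check_grid(img, mask.shape, affine, str(p))
            except ValueError:
                bad.append(str(p))
                continue
            rows.append(np.asarray(img.dataobj, dtype=float)[mask])
        if bad:
            raise ValueError(f"grid/affine mismatch for participant file(s): {bad}")
        Y = np.stack(rows)
    idx = np.argwhere(mask).astype(float)
    if use_mm_coords:
        homog = np.c_[idx, np.ones(len(idx))]
        idx = (homog @ affine.T)[:, :3]
    domain = SpatialDomain.from_coords(
        idx,
        voxel_ids=np.ravel_multi_index(tuple(np.argwhere(mask).T), mask.shape),
        grid_shape=mask.shape,
    )
    return Y, domain, VolumeGeometry(shape=mask.shape, affine=affine)


def _check_grid(img, shape, affine, name: str) -> None:
    if img.shape[: len(shape)] != shape or not np.allclose(img.affine, affine, atol=1e-6):
        raise ValueError(f"grid/affine mismatch: {name}")


def read_surface(func_paths, coord_path) -> tuple[np.ndarray, SpatialDomain]:
    """Load per-vertex GIFTI data arrays plus a coordinate file (one hemisphere)."""
    coords_img = nib.load(str(coord_path))
    coords = np.asarray(coords_img.darrays[0].data, dtype=float)
    rows = []
    for p in func_paths:
        img = nib.load(str(p))
        vals = np.asarray(img.darrays[0].data, dtype=float)
        if vals.shape[0] != coords.shape[0]:
            raise ValueError(f"vertex count mismatch: {p}")
        rows.append(vals)
    domain = SpatialDomain.from_coords(coords)
    return np.stack(rows), domain


def read_covariates(
    path, image_ids, id_column: str = "participant_id", standardize: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Covariate table (CSV/TSV) matched against the image participant order.

    Returns the design matrix with a leading all-ones intercept; non-intercept
    columns are standardized by default (effects are then on the SD scale).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"covariate table lacks id column {id_column!r}")
    df = df.set_index(id_column)
    missing = [i for i in image_ids if i not in df.index]
    if missing:
        raise ValueError(f"covariates missing for participants: {missing}")
    df = df.loc[list(image_ids)]
    if df.isna().any().any():
        raise ValueError("missing covariate values are not supported")
    cols = list(df.columns)
    Xc = df.to_numpy(dtype=float)
    if standardize and Xc.size:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = (Xc - Xc.mean(axis=0)) / sd
    X = np.column_stack([np.ones(len(df)), Xc])
    return X, ["intercept"] + cols


def write_maps(
    summary: EffectSummary,
    domain: SpatialDomain,
    geometry: VolumeGeometry,
    out_dir,
    covariate_names: list[str] | None = None,
    nan_background: bool = False,
) -> list[Path]:
    """One NIfTI per map type per covariate: ``<covariate>_<maptype>.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = covariate_names or [f"cov{j}" for j in range(summary.n_covariates)]
    fill = np.nan if nan_background else 0.0
    written = []
    for j, name in enumerate(names):
        for map_type in MAP_TYPES:
            vals = getattr(summary, map_type)[j]
            if map_type == "es":
                vals = np.clip(vals, -1.0, 1.0)
            if map_type == "active":
                vals = vals.astype(np.int16)
                vol = domain.unmask(vals, fill=0).astype(np.int16)
            else:
                vol = domain.unmask(vals.astype(float), fill=fill)
            vol = vol.reshape(geometry.shape)
            img = nib.Nifti1Image(vol, geometry.affine)
            path = out_dir / f"{name}_{map_type}.nii.gz"
            nib.save(img, str(path))
            written.append(path)
    return written


def write_surface_maps(
    summary: EffectSummary, out_dir, covariate_names: list[str] | None = None
) -> list[Path]:
    """One GIFTI functional file per map type per covariate (one hemisphere)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = covariate_names or [f"cov{j}" for j in range(summary.n_covariates)]
    written = []
    for j, name in enumerate(names):
        for map_type in MAP_TYPES:
            vals = getattr(summary, map_type)[j]
            if map_type == "es":
                vals = np.clip(vals, -1.0, 1.0)
            arr = nib.gifti.GiftiDataArray(np.asarray(vals, dtype=np.float32))
            img = nib.gifti.GiftiImage(darrays=[arr])
            path = out_dir / f"{name}_{map_type}.func.gii"
            nib.save(img, str(path))
            written.append(path)
    return written


def save_basis(path, basis: LowRankBasis) -> None:
    np.savez_compressed(
        path,
        inducing_indices=basis.inducing_indices,
        Psi=basis.Psi,
        eigenvalues=basis.eigenvalues,
        inducing_indices_eta=basis.inducing_indices_eta,
        Psi_eta=basis.Psi_eta,
        eigenvalues_eta=basis.eigenvalues_eta,
    )


def load_basis(path) -> LowRankBasis:
    with np.load(path) as z:
        return LowRankBasis(
            inducing_indices=z["inducing_indices"],
            Psi=z["Psi"],
            eigenvalues=z["eigenvalues"],
            inducing_indices_eta=z["inducing_indices_eta"],
            Psi_eta=z["Psi_eta"],
            eigenvalues_eta=z["eigenvalues_eta"],
        )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_manifest(path, config: dict) -> None:
    """Run manifest: config, seeds and versions, for reproducibility."""
    import bisreg

    manifest = dict(config)
    manifest["versions"] = {
        "bisreg": bisreg.__version__,
        "numpy": np.__version__,
        "nibabel": nib.__version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
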