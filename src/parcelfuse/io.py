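"""Serialization: voxel spaces, fitted models and atlas exports.

Plain-text TSV for anything tabular (coordinates, pairings, lookup tables,
concentrations), a compressed array container (``.npz``) for matrices, and
NIfTI only at the atlas-export boundary when a volume geometry is supplied.
Every writer here has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .arrangement import Arrangement
from .emission import VmfEmission
from .fusion import FusedModel
from .spaces import VoxelSpace


def save_space(space: VoxelSpace, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        space.coords, columns=[f"coord_{i}" for i in range(space.coords.shape[1])]
    )
    df["hemisphere"] = space.hemisphere
    df["mirror"] = space.mirror
    df.to_csv(path / "space.tsv", sep="\t", index=False)


def load_space(path) -> VoxelSpace:
    df = pd.read_csv(Path(path) / "space.tsv", sep="\t")
    coord_cols = [c for c in df.columns if c.startswith("coord_")]
    return VoxelSpace(
        coords=df[coord_cols].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        mirror=df["mirror"].to_numpy(dtype=int),
    )


def save_model(model: FusedModel, path, space_saved: bool = True) -> None:
    """Write a fitted model to a directory (eta + per-dataset emissions)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "eta.npz", eta=model.arrangement.eta)
    meta = {
        "symmetric": model.arrangement.symmetric,
        "hemisphere_locked": model.arrangement.hemisphere_locked,
        "K": model.K,
        "datasets": sorted(model.emissions.keys()),
        "fit_info": _jsonable(model.fit_info),
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    if model.arrangement.space is not None and space_saved:
        save_space(model.arrangement.space, path)
    for ds_id, emi in model.emissions.items():
        np.savez_compressed(
            path / f"emission_{ds_id}.npz",
            kappa=emi.kappa,
            **{f"V{n}": v for n, v in enumerate(emi.V)},
        )
        # human-readable sidecar (the npz is authoritative for round-trips)
        _, k_df = emi.to_frames()
        k_df.to_csv(path / f"kappa_{ds_id}.tsv", sep="\t", index=False)


def load_model(path) -> FusedModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    eta = np.load(path / "eta.npz")["eta"]
    space = load_space(path) if (path / "space.tsv").exists() else None
    arr = Arrangement(
        eta,
        symmetric=meta["symmetric"],
        hemisphere_locked=meta["hemisphere_locked"],
        space=space,
    )
    emissions = {}
    for ds_id in meta["datasets"]:
        with np.load(path / f"emission_{ds_id}.npz") as npz:
            kappa = npz["kappa"]
            V = [npz[f"V{n}"] for n in range(len(npz.files) - 1)]
        emissions[ds_id] = VmfEmission(
            meta["K"], [v.shape[1] for v in V], V=V, kappa=kappa
        )
    return FusedModel(arrangement=arr, emissions=emissions, fit_info=meta["fit_info"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def grid_geometry(space: VoxelSpace, spacing: float = 1.0) -> dict:
    """Volume geometry for a planar grid space: voxel ijk indices, shape
    and an affine, enough to export NIfTI maps of synthetic worlds."""
    coords = space.coords
    mins = coords.min(axis=0)
    ijk2 = np.rint((coords - mins) / spacing).astype(int)
    ijk = np.column_stack([ijk2, np.zeros(len(ijk2), dtype=int)])
    shape = tuple(ijk.max(axis=0) + 1)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = spacing
    affine[:2, 3] = mins
    return {"ijk": ijk, "shape": shape, "affine": affine}


def export_atlas(
    model: FusedModel,
    out_dir,
    hierarchy=None,
    geometry: dict | None = None,
) -> dict:
    """Export probabilistic maps, the winner label map and the lookup table.

    With ``geometry`` (``ijk`` per voxel, ``shape``, ``affine``) the maps
    are additionally written as a 4-D probability NIfTI and a label NIfTI.
    Returns the mapping of artifact names to file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prob = model.group_prob()
    labels = np.argmax(prob, axis=0)
    np.savez_compressed(out_dir / "prob_maps.npz", prob=prob)
    pd.DataFrame({"voxel": np.arange(labels.size), "label": labels}).to_csv(
        out_dir / "labels.tsv", sep="\t", index=False
    )
    if hierarchy is not None:
        hierarchy.to_lookup_table().to_csv(out_dir / "lookup.tsv", sep="\t", index=False)
        (out_dir / "merge_tree.json").write_text(
            json.dumps(_jsonable(hierarchy.merge_tree))
        )
    else:
        pd.DataFrame(
            {
                "index": np.arange(model.K),
                "name": [f"P{k}" for k in range(model.K)],
                "R": 0.5,
                "G": 0.5,
                "B": 0.5,
            }
        ).to_csv(out_dir / "lookup.tsv", sep="\t", index=False)
    files = {
        "prob_maps": out_dir / "prob_maps.npz",
        "labels": out_dir / "labels.tsv",
        "lookup": out_dir / "lookup.tsv",
    }
    if geometry is not None:
        ijk = np.asarray(geometry["ijk"])
        if ijk.shape[0] != prob.shape[1]:
            raise ValueError("geometry voxel count does not match the model")
        shape = tuple(geometry["shape"])
        vol = np.zeros(shape + (model.K,), dtype=np.float32)
        lab_vol = np.zeros(shape, dtype=np.int16)
        idx = tuple(ijk.T)
        for k in range(model.K):
            vol[..., k][idx] = prob[k]
        lab_vol[idx] = labels + 1  # 0 stays background
        affine = np.asarray(geometry["affine"])
        nib.save(nib.Nifti1Image(vol, affine), out_dir / "prob_maps.nii")
        nib.save(nib.Nifti1Image(lab_vol, affine), out_dir / "labels.nii")
        files["prob_nifti"] = out_dir / "prob_maps.nii"
        files["label_nifti"] = out_dir / "labels.nii"
    return files


def read_labels(path) -> np.ndarray:
    return pd.read_csv(Path(path), sep="\t").sort_values("voxel")["label"].to_numpy()
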