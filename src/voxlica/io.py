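"""Serialization: NIfTI volumes, GMT gene sets, TSV tables, JSON bundles.

All formats are standard and text-or-NIfTI only; volumes are written
uncompressed (plain ``.nii``) so that a re-run with the same seed
produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .linked_ica import LinkedDecomposition, LinkedModelConfig
from .synthetic import AnnotationMap, GroundTruth
from .types import AnnotationVolume, VolumeStack, VoxelMask

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_annotation",
    "load_annotation",
    "write_gmt",
    "read_gmt",
    "save_decomposition",
    "load_decomposition",
    "save_ground_truth",
    "load_ground_truth",
]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    # pin mutable header fields so identical data give identical bytes
    img.header.set_sform(np.eye(4), code=1)
    img.header.set_qform(np.eye(4), code=1)
    return img


def save_volume(vol: VolumeStack, path: str | Path) -> Path:
    """Write a 4D stack as NIfTI (spatial axes first, features last) plus a
    sidecar text file with the feature ids."""
    path = Path(path)
    data = np.moveaxis(vol.data, 0, -1)    # (nx, ny, nz, R)
    nib.save(_nifti(data), str(path))
    sidecar = path.with_suffix("").with_suffix(".features.txt")
    sidecar.write_text("\n".join(vol.feature_ids) + "\n")
    return path


def load_volume(path: str | Path, background_value: float = -1.0) -> VolumeStack:
    path = Path(path)
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if data.ndim == 3:
        data = data[..., None]
    sidecar = path.with_suffix("").with_suffix(".features.txt")
    ids = sidecar.read_text().split() if sidecar.exists() else None
    return VolumeStack(data=np.moveaxis(data, -1, 0), feature_ids=ids,
                       background_value=background_value)


def save_int_volume(data: np.ndarray, path: str | Path) -> Path:
    """Write an integer-coded 3D volume (e.g. thresholded or dominance
    maps) as NIfTI."""
    nib.save(_nifti(np.asarray(data).astype(np.int8)), str(path))
    return Path(path)


def save_mask(mask: VoxelMask, path: str | Path) -> Path:
    nib.save(_nifti(mask.grid.astype(np.uint8)), str(path))
    return Path(path)


def load_mask(path: str | Path) -> VoxelMask:
    grid = np.asanyarray(nib.load(str(path)).dataobj)
    return VoxelMask(grid=grid > 0)


def save_annotation(annot: AnnotationVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(_nifti(annot.region_id.astype(np.int32)), str(path))
    names = {str(k): v for k, v in sorted(annot.region_names.items())}
    path.with_suffix("").with_suffix(".names.json").write_text(
        json.dumps(names, indent=1, sort_keys=True) + "\n"
    )
    return path


def load_annotation(path: str | Path) -> AnnotationVolume:
    path = Path(path)
    region_id = np.asanyarray(nib.load(str(path)).dataobj).astype(int)
    names_path = path.with_suffix("").with_suffix(".names.json")
    names = {}
    if names_path.exists():
        names = {int(k): v for k, v in json.loads(names_path.read_text()).items()}
    return AnnotationVolume(region_id=region_id, region_names=names)


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(annot: AnnotationMap, path: str | Path) -> Path:
    """GMT format: one line per term — term, description, then gene ids,
    all tab-separated."""
    path = Path(path)
    lines = []
    for term in sorted(annot.terms):
        desc = annot.term_names.get(term, term)
        genes = "\t".join(sorted(annot.terms[term]))
        lines.append(f"{term}\t{desc}\t{genes}")
    # final line records the universe so the map round-trips
    lines.append("_UNIVERSE_\tall genes\t" + "\t".join(sorted(annot.universe)))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationMap:
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, genes = parts[0], parts[1], frozenset(parts[2:])
        if term == "_UNIVERSE_":
            universe = set(genes) if universe is None else universe
            continue
        terms[term] = genes
        names[term] = desc
        seen |= genes
    if universe is None:
        universe = seen
    return AnnotationMap(terms=terms, universe=frozenset(universe), term_names=names)


# ---------------------------------------------------------------------------
# decomposition bundles


def save_decomposition(decomp: LinkedDecomposition, outdir: str | Path) -> Path:
    """Directory bundle: H as 4D NIfTI (components as volumes, through the
    mask when available), X^k/W^k as TSV with feature labels, config and
    free-energy trace as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if decomp.mask is not None:
        data = np.full((decomp.L,) + decomp.mask.grid.shape, 0.0)
        data[:, decomp.mask.grid] = decomp.H
        nib.save(_nifti(np.moveaxis(data, 0, -1)), str(outdir / "spatial_maps.nii"))
        save_mask(decomp.mask, outdir / "mask.nii")
    np.savetxt(outdir / "H.tsv", decomp.H, delimiter="\t")

    for k, (Xk, Wk) in enumerate(zip(decomp.X, decomp.W)):
        name = decomp.modality_names[k]
        df = pd.DataFrame(Xk, index=decomp.feature_ids[k],
                          columns=[f"comp{i}" for i in range(decomp.L)])
        df.index.name = "feature"
        df.to_csv(outdir / f"X_{name}.tsv", sep="\t")
        pd.DataFrame({"component": np.arange(decomp.L), "weight": Wk}).to_csv(
            outdir / f"W_{name}.tsv", sep="\t", index=False
        )
        pd.DataFrame({
            "feature": decomp.feature_ids[k],
            "row_mean": decomp.row_means[k],
            "row_std": decomp.row_stds[k],
        }).to_csv(outdir / f"scaling_{name}.tsv", sep="\t", index=False)

    meta = {
        "config": {
            "L": decomp.config.L,
            "max_iter": decomp.config.max_iter,
            "rel_tol": decomp.config.rel_tol,
            "seed": decomp.config.seed,
            "dof_scale": decomp.config.dof_scale
            if np.isscalar(decomp.config.dof_scale)
            else list(decomp.config.dof_scale),
            "mog_components": decomp.config.mog_components,
            "init": decomp.config.init,
            "standardize": decomp.config.standardize,
        },
        "converged": bool(decomp.converged),
        "n_iterations": int(decomp.free_energy_trace.size),
        "free_energy_trace": decomp.free_energy_trace.tolist(),
        "component_order": decomp.component_order.tolist(),
        "noise_precision": [float(b) for b in decomp.noise_precision],
        "explained_variance": decomp.explained_variance.tolist(),
        "modality_names": decomp.modality_names,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return outdir


def load_decomposition(outdir: str | Path) -> LinkedDecomposition:
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    cfg_kwargs = dict(meta["config"])
    if isinstance(cfg_kwargs.get("dof_scale"), list):
        cfg_kwargs["dof_scale"] = tuple(cfg_kwargs["dof_scale"])
    config = LinkedModelConfig(**cfg_kwargs)
    H = np.loadtxt(outdir / "H.tsv", delimiter="\t", ndmin=2)
    X, W, feat_ids, means, stds = [], [], [], [], []
    for name in meta["modality_names"]:
        df = pd.read_csv(outdir / f"X_{name}.tsv", sep="\t", index_col=0)
        X.append(df.to_numpy())
        feat_ids.append([str(i) for i in df.index])
        W.append(pd.read_csv(outdir / f"W_{name}.tsv", sep="\t")["weight"].to_numpy())
        sc = pd.read_csv(outdir / f"scaling_{name}.tsv", sep="\t")
        means.append(sc["row_mean"].to_numpy())
        stds.append(sc["row_std"].to_numpy())
    mask = load_mask(outdir / "mask.nii") if (outdir / "mask.nii").exists() else None
    return LinkedDecomposition(
        H=H, X=X, W=W,
        noise_precision=meta["noise_precision"],
        free_energy_trace=np.asarray(meta["free_energy_trace"]),
        component_order=np.asarray(meta["component_order"], dtype=int),
        converged=meta["converged"],
        explained_variance=np.asarray(meta["explained_variance"]),
        modality_names=list(meta["modality_names"]),
        feature_ids=feat_ids,
        row_means=means,
        row_stds=stds,
        config=config,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# ground truth bundles


def save_ground_truth(truth: GroundTruth, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "H_true.tsv", truth.H_true, delimiter="\t")
    for k, (Xk, Wk) in enumerate(zip(truth.X_true, truth.W_true)):
        np.savetxt(outdir / f"X_true_{k}.tsv", Xk, delimiter="\t")
        np.savetxt(outdir / f"W_true_{k}.tsv", Wk, delimiter="\t")
    meta = {
        "seed": truth.seed,
        "noise_sd": [float(s) for s in truth.noise_sd],
        "n_modalities": len(truth.X_true),
        "L": int(truth.L),
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return outdir


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    meta = json.loads((outdir / "truth.json").read_text())
    H = np.loadtxt(outdir / "H_true.tsv", delimiter="\t", ndmin=2)
    X = [np.loadtxt(outdir / f"X_true_{k}.tsv", delimiter="\t", ndmin=2)
         for k in range(meta["n_modalities"])]
    W = [np.atleast_1d(np.loadtxt(outdir / f"W_true_{k}.tsv", delimiter="\t"))
         for k in range(meta["n_modalities"])]
    return GroundTruth(H_true=H, X_true=X, W_true=W,
                       noise_sd=meta["noise_sd"], seed=meta["seed"])
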