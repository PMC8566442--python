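"""Volumetric preprocessing: downsampling, masking, flattening, imputation.

Mirrors the preparation applied to the Allen expression-energy and
projection-density volumes before factorization: trilinear downsampling
of the finer modality onto the coarser grid, removal of background
voxels (sentinel -1) through a shared mask, row-major flattening of the
three spatial axes into one voxel axis, region-mean imputation of
missing in-mask entries, and feature subsetting (e.g. injection groups).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .types import AnnotationVolume, ModalityMatrix, VolumeStack, VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "downsample",
    "build_mask",
    "flatten",
    "unflatten",
    "impute_missing",
    "subset_features",
]


def downsample(vol: VolumeStack, factor: int) -> VolumeStack:
    """Downsample each feature volume by trilinear interpolation at the
    coarse-grid cell centers.

    Background voxels are excluded from the interpolation support: the
    8 trilinear weights are renormalized over non-sentinel corners, and a
    coarse cell whose support is entirely background stays sentinel.
    Output dims are ``ceil(dim / factor)``; trailing partial cells sample
    at coordinates clipped to the grid.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return VolumeStack(
            data=vol.data.copy(), feature_ids=list(vol.feature_ids),
            background_value=vol.background_value, axis_order=vol.axis_order,
            voxel_size_um=vol.voxel_size_um,
        )

    dims = vol.grid_shape
    out_dims = tuple(math.ceil(d / factor) for d in dims)
    # coarse cell c covers fine cells [c*f, (c+1)*f); its centre in fine
    # index coordinates is c*f + (f-1)/2, clipped into the grid
    centers = [
        np.clip(np.arange(n_out) * factor + (factor - 1) / 2.0, 0, d - 1)
        for n_out, d in zip(out_dims, dims)
    ]
    cx, cy, cz = np.meshgrid(*centers, indexing="ij")

    lo = [np.floor(c).astype(int) for c in (cx, cy, cz)]
    hi = [np.minimum(l + 1, d - 1) for l, d in zip(lo, dims)]
    frac = [c - l for c, l in zip((cx, cy, cz), lo)]

    sent = vol.background_value
    out = np.full((vol.n_features,) + out_dims, sent)
    for r in range(vol.n_features):
        grid = vol.data[r]
        acc = np.zeros(out_dims)
        wsum = np.zeros(out_dims)
        for bx in (0, 1):
            for by in (0, 1):
                for bz in (0, 1):
                    ix = hi[0] if bx else lo[0]
                    iy = hi[1] if by else lo[1]
                    iz = hi[2] if bz else lo[2]
                    w = (
                        (frac[0] if bx else 1 - frac[0])
                        * (frac[1] if by else 1 - frac[1])
                        * (frac[2] if bz else 1 - frac[2])
                    )
                    vals = grid[ix, iy, iz]
                    ok = (vals != sent) & (w > 0)
                    acc += np.where(ok, w * vals, 0.0)
                    wsum += np.where(ok, w, 0.0)
        covered = wsum > 0
        out[r][covered] = acc[covered] / wsum[covered]

    return VolumeStack(
        data=out, feature_ids=list(vol.feature_ids),
        background_value=sent, axis_order=vol.axis_order,
        voxel_size_um=vol.voxel_size_um * factor,
    )


def build_mask(vol: VolumeStack) -> VoxelMask:
    """Mask of voxels where *any* feature is non-sentinel (the shared
    brain mask convention: a cell missing for one gene but expressed for
    another is inside the brain)."""
    grid = np.any(vol.data != vol.background_value, axis=0)
    if not grid.any():
        raise ValueError("volume is entirely background; empty mask")
    return VoxelMask(grid=grid)


def flatten(vol: VolumeStack, mask: VoxelMask, modality_name: str = "") -> ModalityMatrix:
    """Row-major flattening of the in-mask cells of each feature volume.

    ``values[r, j]`` is feature ``r`` at the j-th in-mask cell in C order
    (index increases fastest along the last, Right-Left, axis).
    """
    if vol.grid_shape != mask.grid.shape:
        raise ValueError(
            f"volume grid {vol.grid_shape} does not match mask grid "
            f"{mask.grid.shape}"
        )
    values = vol.data[:, mask.grid]        # boolean indexing is C-ordered
    return ModalityMatrix(
        values=values, feature_ids=list(vol.feature_ids),
        modality_name=modality_name or "modality", mask=mask,
    )


def unflatten(mat: ModalityMatrix, background_value: float = -1.0) -> VolumeStack:
    """Inverse of :func:`flatten`: restore the 4D stack, background filled
    with the sentinel."""
    data = np.full((mat.n_features,) + mat.mask.grid.shape, background_value)
    data[:, mat.mask.grid] = mat.values
    return VolumeStack(data=data, feature_ids=list(mat.feature_ids),
                       background_value=background_value)


def impute_missing(
    mat: ModalityMatrix,
    annot: AnnotationVolume,
    missing_value: float = -1.0,
) -> ModalityMatrix:
    """Replace missing entries by the feature's mean over expressed voxels
    of the same anatomical region.

    A region where a feature has no expressed voxel at all falls back to
    the feature's global in-mask mean (logged as a warning). Non-missing
    entries are never altered; with no missing entries this is the
    identity.
    """
    labels = annot.labels_for(mat.mask)    # (N,) region id per voxel
    values = mat.values.copy()
    missing = values == missing_value
    if not missing.any():
        return ModalityMatrix(values=values, feature_ids=list(mat.feature_ids),
                              modality_name=mat.modality_name, mask=mat.mask)

    import warnings as _warnings

    masked = np.where(missing, np.nan, values)
    global_mean = np.nanmean(masked, axis=1)          # (R,)
    for g in np.unique(labels[missing.any(axis=0)]):
        cols = labels == g
        sub = masked[:, cols]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            region_mean = np.nanmean(sub, axis=1)     # (R,), nan if empty
        empty = np.isnan(region_mean)
        if empty.any():
            logger.warning(
                "region %s has no expressed voxel for %d feature(s); "
                "falling back to global mean", g, int(empty.sum()),
            )
            region_mean[empty] = global_mean[empty]
        fill = np.broadcast_to(region_mean[:, None], sub.shape)
        block = values[:, cols]
        block[missing[:, cols]] = fill[missing[:, cols]]
        values[:, cols] = block

    return ModalityMatrix(values=values, feature_ids=list(mat.feature_ids),
                          modality_name=mat.modality_name, mask=mat.mask)


def subset_features(mat: ModalityMatrix, ids: list[str]) -> ModalityMatrix:
    """Restrict and reorder rows to ``ids`` (e.g. one injection group)."""
    index = {fid: r for r, fid in enumerate(mat.feature_ids)}
    unknown = [fid for fid in ids if fid not in index]
    if unknown:
        raise KeyError(f"unknown feature ids: {unknown}")
    rows = [index[fid] for fid in ids]
    return ModalityMatrix(values=mat.values[rows].copy(), feature_ids=list(ids),
                          modality_name=mat.modality_name, mask=mat.mask)
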