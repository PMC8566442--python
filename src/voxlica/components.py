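"""Post-hoc analysis of factorization components.

Covers the interpretation steps applied to fitted spatial maps:
1/99-percentile thresholding, modality-dominance labelling of selected
voxels, selection of components with a non-zero contribution from every
modality, Pearson cross-correlation between factorizations (significance
at p < 0.004 by default), per-region voxel summaries, and the
matched-recovery score used to compare estimated maps against planted
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import AnnotationVolume, VoxelMask

__all__ = [
    "ThresholdedMap",
    "DominanceMap",
    "CrossCorrelationTable",
    "threshold_map",
    "select_components_of_interest",
    "dominance_labels",
    "cross_correlate",
    "region_summary",
    "matched_recovery_score",
]


@dataclass
class ThresholdedMap:
    """Voxels beyond the low/high percentile cuts of one spatial map.

    Values inside the percentile band are treated as zero; the negative
    set holds voxels strictly below the low cut, the positive set voxels
    strictly above the high cut.
    """

    component_id: int
    low_cut: float
    high_cut: float
    negative_voxels: np.ndarray            # sorted voxel indices
    positive_voxels: np.ndarray
    z_scored: bool = False

    @property
    def selected_voxels(self) -> np.ndarray:
        return np.sort(np.concatenate([self.negative_voxels, self.positive_voxels]))

    @property
    def n_selected(self) -> int:
        return self.negative_voxels.size + self.positive_voxels.size


def threshold_map(
    map_values: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    component_id: int = 0,
    z_scored: bool = False,
) -> ThresholdedMap:
    """Threshold a spatial map at the given percentiles (default 1 and 99).

    Percentile cuts use the linear-interpolation convention between order
    statistics. Warns for N < 100 (the tail percentiles then select
    almost nothing) and for constant maps (both sets empty).
    """
    v = np.asarray(map_values, dtype=float).ravel()
    if v.size < 100:
        warnings.warn(
            f"map has only {v.size} voxels; 1/99-percentile cuts are "
            "barely meaningful", stacklevel=2,
        )
    low_cut, high_cut = np.percentile(v, [low_pct, high_pct])
    if np.ptp(v) == 0:
        warnings.warn("constant map: nothing survives thresholding", stacklevel=2)
        empty = np.array([], dtype=int)
        return ThresholdedMap(component_id, float(low_cut), float(high_cut),
                              empty, empty, z_scored)
    return ThresholdedMap(
        component_id=component_id,
        low_cut=float(low_cut),
        high_cut=float(high_cut),
        negative_voxels=np.flatnonzero(v < low_cut),
        positive_voxels=np.flatnonzero(v > high_cut),
        z_scored=z_scored,
    )


def select_components_of_interest(decomp, floor: float = 0.01) -> list[int]:
    """Components with a non-zero contribution from every modality.

    A component qualifies if its relative modality contribution (its
    explained-variance row, normalized to sum 1) exceeds ``floor`` in
    each modality. ``floor=0`` returns every component with any variance.
    """
    ev = np.asarray(decomp.explained_variance, dtype=float)  # (L, K)
    totals = ev.sum(axis=1, keepdims=True)
    selected = []
    for i in range(ev.shape[0]):
        if totals[i, 0] <= 0:
            continue
        rel = ev[i] / totals[i, 0]
        if np.all(rel > floor) if floor > 0 else True:
            selected.append(i)
    return selected


@dataclass
class DominanceMap:
    """Which modality's reconstruction energy drives each selected voxel."""

    component_id: int
    voxel_indices: np.ndarray
    labels: np.ndarray                     # strings: shared / <name>_dominated
    dominance_ratio_cut: float
    modality_names: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))


def dominance_labels(
    decomp,
    component: int,
    thresholded: ThresholdedMap,
    ratio_cut: float = 2.0,
) -> DominanceMap:
    """Label each thresholded voxel by the dominant modality.

    Per-voxel reconstruction energy of modality k for component i is
    ``e_k(j) = sum_r (X^k_{r,i} W^k_i H_{i,j})^2``. A voxel is labelled
    ``<modality>_dominated`` when that modality's energy exceeds the
    other's by more than ``ratio_cut``-fold, else ``shared``. Voxels with
    zero energy in both modalities are dropped with a warning.
    """
    if len(decomp.X) != 2:
        raise ValueError("dominance labelling is defined for two modalities")
    idx = thresholded.selected_voxels
    h = decomp.H[component, idx]           # (V,)
    energies = []
    for Xk, Wk in zip(decomp.X, decomp.W):
        coef = float(np.sum((Xk[:, component] * Wk[component]) ** 2))
        energies.append(coef * h**2)       # (V,)
    e1, e2 = energies
    both_zero = (e1 == 0) & (e2 == 0)
    if both_zero.any():
        warnings.warn(
            f"{int(both_zero.sum())} voxel(s) with zero energy in both "
            "modalities dropped", stacklevel=2,
        )
        keep = ~both_zero
        idx, e1, e2 = idx[keep], e1[keep], e2[keep]

    names = tuple(getattr(decomp, "modality_names", None) or ("gene", "projection"))
    labels = np.full(idx.shape, "shared", dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        labels[(e2 == 0) | (e1 / np.maximum(e2, 1e-300) > ratio_cut)] = (
            f"{names[0]}_dominated"
        )
        labels[(e1 == 0) | (e2 / np.maximum(e1, 1e-300) > ratio_cut)] = (
            f"{names[1]}_dominated"
        )
    # a voxel can't be dominated by both; zero-vs-zero was dropped above
    return DominanceMap(
        component_id=component, voxel_indices=idx, labels=labels.astype(str),
        dominance_ratio_cut=ratio_cut, modality_names=names,
    )


@dataclass
class CrossCorrelationTable:
    """Pairwise Pearson correlations between two factorizations."""

    rho: np.ndarray                        # (A, B)
    p: np.ndarray                          # (A, B)
    alpha: float = 0.004

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.p < self.alpha) & np.isfinite(self.rho)

    def best_matches(self) -> np.ndarray:
        """For each row, the column with the largest |rho| (nan-safe)."""
        r = np.where(np.isfinite(self.rho), np.abs(self.rho), -1.0)
        return np.argmax(r, axis=1)


def cross_correlate(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    alpha: float = 0.004,
) -> CrossCorrelationTable:
    """Pearson rho and two-sided p for every pair of rows of two matrices.

    Rows are compared along their shared axis (spatial maps over voxels,
    or coefficient vectors over features). Zero-variance rows yield NaN
    entries (correlation undefined), reported as missing.
    """
    A = np.atleast_2d(np.asarray(maps_a, dtype=float))
    B = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"matrices disagree along the correlation axis: {A.shape[1]} vs "
            f"{B.shape[1]}"
        )
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(Ac, axis=1)
    sb = np.linalg.norm(Bc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Ac @ Bc.T) / np.outer(sa, sb)
    rho = np.where(np.outer(sa > 0, sb > 0), rho, np.nan)
    rho = np.clip(rho, -1.0, 1.0, out=rho)

    # two-sided p via the exact null distribution of Pearson's r
    # (r ~ Beta on [-1, 1] with shape (n-2)/2 under independence)
    p = np.full_like(rho, np.nan)
    if n > 2:
        ab = (n - 2) / 2.0
        finite = np.isfinite(rho)
        p[finite] = 2.0 * stats.beta.sf(np.abs(rho[finite]), ab, ab, loc=-1, scale=2)
        p = np.clip(p, 0.0, 1.0)
    return CrossCorrelationTable(rho=rho, p=p, alpha=alpha)


def region_summary(
    thresholded: ThresholdedMap,
    annot: AnnotationVolume,
    mask: VoxelMask,
) -> pd.DataFrame:
    """Selected-voxel counts per anatomical region.

    Returns a table of (region_id, region_name, n_selected_voxels,
    region_voxels, pct_of_region_volume), one row per region containing
    at least one selected voxel.
    """
    labels = annot.labels_for(mask)
    sel = thresholded.selected_voxels
    rows = []
    if sel.size:
        sel_labels = labels[sel]
        for g in np.unique(sel_labels):
            n_sel = int((sel_labels == g).sum())
            n_region = int((labels == g).sum())
            rows.append((
                int(g), annot.region_names.get(int(g), str(g)), n_sel, n_region,
                100.0 * n_sel / n_region,
            ))
    return pd.DataFrame(
        rows,
        columns=["region_id", "region_name", "n_selected_voxels",
                 "region_voxels", "pct_of_region_volume"],
    )


def thresholded_to_volume(
    thresholded: ThresholdedMap, mask: VoxelMask
) -> np.ndarray:
    """Integer-coded 3D volume of a thresholded map: 0 none, 1 positive,
    -1 negative (background also 0)."""
    flat = np.zeros(mask.n_voxels, dtype=np.int8)
    flat[thresholded.positive_voxels] = 1
    flat[thresholded.negative_voxels] = -1
    vol = np.zeros(mask.grid.shape, dtype=np.int8)
    vol[mask.grid] = flat
    return vol


def dominance_to_volume(dom: DominanceMap, mask: VoxelMask) -> np.ndarray:
    """Integer-coded 3D volume of a dominance map: 0 unselected, 1 shared,
    2 first-modality dominated, 3 second-modality dominated."""
    codes = {"shared": 1,
             f"{dom.modality_names[0]}_dominated": 2,
             f"{dom.modality_names[1]}_dominated": 3}
    flat = np.zeros(mask.n_voxels, dtype=np.int8)
    for idx, label in zip(dom.voxel_indices, dom.labels):
        flat[idx] = codes[label]
    vol = np.zeros(mask.grid.shape, dtype=np.int8)
    vol[mask.grid] = flat
    return vol


def matched_recovery_score(
    estimated_maps: np.ndarray,
    true_maps: np.ndarray,
) -> tuple[list[tuple[int, int]], np.ndarray, float]:
    """Optimal one-to-one matching of estimated to true spatial maps.

    Uses the Hungarian algorithm on the |Pearson rho| matrix (sign and
    permutation are not identifiable in ICA). Returns the matching as
    (estimated, true) index pairs, per-pair |rho|, and their mean.
    Rectangular inputs are allowed; the smaller side is fully matched.
    """
    table = cross_correlate(estimated_maps, true_maps)
    score = np.where(np.isfinite(table.rho), np.abs(table.rho), 0.0)
    rows, cols = optimize.linear_sum_assignment(-score)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    rhos = score[rows, cols]
    return pairs, rhos, float(rhos.mean())
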