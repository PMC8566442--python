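"""Synthetic voxel-linked multimodal datasets with planted ground truth.

Generates data from the same generative model the factorization assumes:

    Y^k = X^k diag(W^k) H + E^k

where ``H`` (L x N) holds shared sparse spatial sources over in-mask
voxels, ``X^k`` (R_k x L) the per-feature coefficients of modality ``k``,
``W^k`` non-negative per-component modality weights and ``E^k`` i.i.d.
Gaussian noise scaled to a target signal-to-noise ratio. Sources are sums
of 1-3 Gaussian blobs on the grid, hard-thresholded to a sparse active
fraction — sparse, spatially contiguous and super-Gaussian, which is what
an ICA-style prior needs to separate them.

The generator also emits a brain-like ellipsoidal mask (background -1),
a Voronoi toy parcellation, optional missing entries (-1) inside the
mask of modality 1, and a toy gene-annotation universe with planted
enriched terms, so every downstream stage can be tested without any
external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import BACKGROUND, AnnotationVolume, ModalityMatrix, VolumeStack, VoxelMask

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "AnnotationMap",
    "generate_linked_dataset",
    "generate_annotation_universe",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic linked dataset.

    Defaults are the reference conditions used throughout the test
    harness: a 12 x 10 x 10 grid with 80% of cells inside the mask
    (N = 960 voxels), L = 5 shared sources, 60 gene-like and 30
    injection-like features, SNR 10 per modality, 10% of voxels active
    per source, and 0.8% missing entries in modality 1 (the fraction the
    gene-expression volumes actually carry).
    """

    grid_dims: tuple[int, int, int] = (12, 10, 10)
    mask_fill: float = 0.8
    L: int = 5
    R: tuple[int, ...] = (60, 30)
    snr: float | tuple[float, ...] = 10.0
    source_sparsity: float = 0.1
    missing_fraction: float = 0.008
    n_regions: int = 6
    seed: int = 0
    #: (component, modality) pairs whose weight is forced to zero, creating
    #: modality-unique sources. Default plants one gene-only component.
    unique_components: tuple[tuple[int, int], ...] = ((4, 1),)
    #: optional constant added to the emitted matrices (realism knob: real
    #: expression/projection data are non-negative; the model does not care).
    shift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be three positive integers")
        if not 0.0 < self.mask_fill <= 1.0:
            raise ValueError("mask_fill must be in (0, 1]")
        if self.L < 1 or any(r < 1 for r in self.R):
            raise ValueError("L and all feature counts must be positive")
        if self.L > min(self.R):
            raise ValueError(
                f"model order L={self.L} exceeds the smallest feature count "
                f"{min(self.R)}"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0.0 < self.source_sparsity <= 1.0:
            raise ValueError("source_sparsity must be in (0, 1]")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        for comp, mod in self.unique_components:
            if not (0 <= comp < self.L) or not (0 <= mod < len(self.R)):
                raise ValueError(f"unique component ({comp},{mod}) out of range")

    @property
    def snr_per_modality(self) -> tuple[float, ...]:
        if np.isscalar(self.snr):
            return tuple(float(self.snr) for _ in self.R)
        if len(self.snr) != len(self.R):
            raise ValueError("snr must be scalar or one value per modality")
        return tuple(float(s) for s in self.snr)


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset.

    ``H_true`` rows are unit-norm; ``W_true`` entries are >= 0 with zeros
    marking modality-unique sources. ``clean`` holds the noise-free
    ``X^k diag(W^k) H`` matrices and ``noisy`` the emitted ``clean + E^k``
    (before any shift), so tests can check the generative identity and
    empirical SNR without re-deriving them.
    """

    H_true: np.ndarray                     # (L, N)
    X_true: list[np.ndarray]               # [(R_k, L)]
    W_true: list[np.ndarray]               # [(L,)]
    noise_sd: list[float]
    seed: int
    clean: list[np.ndarray] = field(default_factory=list)
    noisy: list[np.ndarray] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.H_true.shape[0]

    def signal_to_noise(self, k: int) -> float:
        """Empirical SNR of modality k: var(signal) / var(noise)."""
        noise = self.noisy[k] - self.clean[k]
        nv = float(np.var(noise))
        if nv == 0.0:
            return math.inf
        return float(np.var(self.clean[k]) / nv)


def _ellipsoid_mask(dims: tuple[int, int, int], fill: float) -> np.ndarray:
    """Brain-like contiguous mask: the `fill` fraction of cells closest to
    the grid centre under per-axis scaled distance."""
    nx, ny, nz = dims
    axes = [np.arange(n) - (n - 1) / 2.0 for n in dims]
    sx, sy, sz = [max(n / 2.0, 0.5) for n in dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    dist = (gx / sx) ** 2 + (gy / sy) ** 2 + (gz / sz) ** 2
    n_in = max(1, int(round(fill * nx * ny * nz)))
    cut = np.partition(dist.ravel(), n_in - 1)[n_in - 1]
    mask = dist <= cut
    # ties at the cut could overshoot; trim deterministically
    if mask.sum() > n_in:
        extra = np.flatnonzero((dist == cut).ravel())[: mask.sum() - n_in]
        flat = mask.ravel()
        flat[extra] = False
        mask = flat.reshape(dims)
    return mask


#: cap on pairwise spatial correlation between planted sources; sources
#: stacking on the same voxels are not mutually independent, so no
#: factorization could tell them apart (the fixtures must stay
#: identifiable to serve as a recovery harness)
_MAX_SOURCE_CORR = 0.3


def _blob_sources(
    mask: VoxelMask, L: int, sparsity: float, rng: np.random.Generator
) -> np.ndarray:
    """L unit-norm sparse sources: 1-3 Gaussian blobs each, thresholded to
    the top `sparsity` fraction of in-mask voxels, signed at random.

    Blob configurations are redrawn (bounded retries) until each source's
    spatial correlation with every earlier source stays below the
    distinguishability cap, emulating anatomically distinct structures.
    """
    dims = mask.grid.shape
    coords = mask.coords.astype(float)     # (N, 3)
    N = coords.shape[0]
    n_active = max(2, int(round(sparsity * N)))
    H = np.zeros((L, N))
    for i in range(L):
        best_row, best_corr = None, np.inf
        for _ in range(100):
            field_vals = np.zeros(N)
            for _ in range(rng.integers(1, 4)):
                centre = coords[rng.integers(0, N)]
                sigma = rng.uniform(0.08, 0.2) * max(dims)
                d2 = np.sum((coords - centre) ** 2, axis=1)
                field_vals += rng.uniform(0.5, 1.5) * np.exp(-d2 / (2.0 * sigma**2))
            # exactly n_active voxels survive; argpartition breaks ties
            # deterministically (grid symmetry can duplicate blob values)
            keep = np.argpartition(field_vals, N - n_active)[N - n_active:]
            row = np.zeros(N)
            row[keep] = field_vals[keep]
            row /= np.linalg.norm(row)
            if i == 0:
                best_row = row
                break
            corr = float(np.max(np.abs(
                (H[:i] - H[:i].mean(axis=1, keepdims=True)) @ (row - row.mean())
                / (np.std(H[:i], axis=1) * np.std(row) * N)
            )))
            if corr < best_corr:
                best_row, best_corr = row, corr
            if corr < _MAX_SOURCE_CORR:
                break
        sign = -1.0 if rng.random() < 0.5 else 1.0
        H[i] = sign * best_row
    return H


def _voronoi_parcellation(
    mask: VoxelMask, n_regions: int, rng: np.random.Generator
) -> AnnotationVolume:
    coords = mask.coords.astype(float)
    seeds = coords[rng.choice(coords.shape[0], size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1) + 1     # region ids 1..n_regions
    grid = np.zeros(mask.grid.shape, dtype=int)
    grid[mask.grid] = labels
    names = {g: f"region_{g}" for g in range(1, n_regions + 1)}
    return AnnotationVolume(region_id=grid, region_names=names)


def generate_linked_dataset(
    spec: SyntheticSpec,
) -> tuple[list[VolumeStack], VoxelMask, AnnotationVolume, GroundTruth]:
    """Generate one voxel-linked multimodal dataset.

    Returns one 4D :class:`VolumeStack` per modality (background -1, a
    ``missing_fraction`` of in-mask modality-1 entries also -1), the
    shared mask, a toy parcellation and the planted :class:`GroundTruth`.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = VoxelMask(_ellipsoid_mask(spec.grid_dims, spec.mask_fill))
    N = mask.n_voxels

    H = _blob_sources(mask, spec.L, spec.source_sparsity, rng)
    X = [rng.standard_normal((r, spec.L)) for r in spec.R]
    W = [np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=spec.L)) for _ in spec.R]
    for comp, mod in spec.unique_components:
        W[mod][comp] = 0.0

    snrs = spec.snr_per_modality
    clean, noisy, noise_sds = [], [], []
    for k, (Xk, Wk) in enumerate(zip(X, W)):
        S = Xk @ (Wk[:, None] * H)                      # (R_k, N)
        if math.isinf(snrs[k]):
            sd = 0.0
        else:
            sd = float(np.sqrt(np.var(S) / snrs[k]))
        E = sd * rng.standard_normal(S.shape) if sd > 0 else np.zeros_like(S)
        clean.append(S)
        noisy.append(S + E)
        noise_sds.append(sd)

    truth = GroundTruth(
        H_true=H, X_true=X, W_true=W, noise_sd=noise_sds, seed=spec.seed,
        clean=clean, noisy=noisy,
    )

    volumes: list[VolumeStack] = []
    for k, Yk in enumerate(noisy):
        vals = Yk + spec.shift
        if k == 0 and spec.missing_fraction > 0:
            n_missing = int(round(spec.missing_fraction * vals.size))
            flat_idx = rng.choice(vals.size, size=n_missing, replace=False)
            vals = vals.copy()
            vals.ravel()[flat_idx] = BACKGROUND
        data = np.full((spec.R[k],) + spec.grid_dims, BACKGROUND)
        data[:, mask.grid] = vals
        prefix = "gene" if k == 0 else "inj"
        ids = [f"{prefix}{r:04d}" for r in range(spec.R[k])]
        volumes.append(VolumeStack(data=data, feature_ids=ids))

    annot = _voronoi_parcellation(mask, spec.n_regions, rng)
    return volumes, mask, annot, truth


# ---------------------------------------------------------------------------
# toy annotation universe for enrichment testing


@dataclass
class AnnotationMap:
    """Flat term -> gene-set mapping over an explicit gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )


def generate_annotation_universe(
    n_genes: int,
    n_terms: int,
    planted: list[tuple[str, set[str]]] | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 20),
    gene_ids: list[str] | None = None,
) -> AnnotationMap:
    """Toy gene-annotation universe with exactly-as-stated planted terms.

    Non-planted terms are random gene sets with sizes drawn uniformly
    from ``size_range``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene{r:04d}" for r in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    universe = frozenset(gene_ids)

    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    planted = planted or []
    for term, genes in planted:
        genes = frozenset(genes)
        if not genes <= universe:
            raise ValueError(f"planted term {term!r} uses genes outside the universe")
        terms[term] = genes
        names[term] = f"planted term {term}"

    lo, hi = size_range
    if not 1 <= lo <= hi <= n_genes:
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= n_genes")
    n_random = n_terms - len(planted)
    if n_random < 0:
        raise ValueError("more planted terms than n_terms")
    gene_arr = np.asarray(gene_ids)
    for t in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(gene_arr[rng.choice(n_genes, size=size, replace=False)])
        term = f"TERM{t:04d}"
        terms[term] = members
        names[term] = f"random term {t}"
    return AnnotationMap(terms=terms, universe=universe, term_names=names)


def flatten_truth_matrices(
    truth: GroundTruth, mask: VoxelMask, names: tuple[str, ...] = ("gene", "proj")
) -> list[ModalityMatrix]:
    """Convenience: the emitted noisy matrices wrapped as ModalityMatrix
    (no missing entries, no shift) — the exact inputs the factorizations
    see after preprocessing a dataset generated with missing_fraction=0."""
    out = []
    for k, Yk in enumerate(truth.noisy):
        prefix = "gene" if k == 0 else "inj"
        ids = [f"{prefix}{r:04d}" for r in range(Yk.shape[0])]
        out.append(
            ModalityMatrix(values=Yk.copy(), feature_ids=ids,
                           modality_name=names[k] if k < len(names) else f"mod{k}",
                           mask=mask)
        )
    return out
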