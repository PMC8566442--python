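"""Core spatial containers shared across the pipeline.

The pipeline operates on feature-by-voxel matrices derived from 4D
volumetric stacks (features x 3D grid). Voxels outside the brain carry a
background sentinel (-1 by convention of the Allen atlas volumes); a
boolean :class:`VoxelMask` plus a row-major flattening map make the
volume <-> matrix conversion invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Background sentinel used by the Allen-style volumes this package consumes.
BACKGROUND = -1.0

#: Axis order of the Allen CCF volumes: x = Posterior-Anterior,
#: y = Inferior-Superior, z = Right-Left.
PIR_AXES = ("posterior-anterior", "inferior-superior", "right-left")


@dataclass
class VolumeStack:
    """A 4D stack: ``data[r, x, y, z]`` holds feature ``r``'s intensity.

    Background voxels hold exactly ``background_value`` for every feature.
    """

    data: np.ndarray                       # (R, nx, ny, nz)
    feature_ids: list[str] | None = None
    background_value: float = BACKGROUND
    axis_order: tuple[str, str, str] = PIR_AXES
    voxel_size_um: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:            # single feature convenience
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"VolumeStack.data must be 4D, got {self.data.ndim}D")
        if self.data.shape[0] < 1:
            raise ValueError("VolumeStack needs at least one feature")
        if self.feature_ids is None:
            self.feature_ids = [f"f{r}" for r in range(self.data.shape[0])]
        if len(self.feature_ids) != self.data.shape[0]:
            raise ValueError("feature_ids length does not match data")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class VoxelMask:
    """Boolean brain mask plus a bijection voxel index <-> grid coordinate.

    The flattening order is row-major (C order): the voxel index increases
    fastest along the last (Right-Left) axis.
    """

    grid: np.ndarray                       # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("VoxelMask.grid must be 3D")
        # coordinates of in-mask cells in C order: the index_map
        self.coords = np.argwhere(self.grid)          # (n_voxels, 3), row-major

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def index_of(self, x: int, y: int, z: int) -> int:
        """Voxel index of an in-mask grid cell."""
        flat = np.flatnonzero(self.grid.ravel(order="C"))
        lin = np.ravel_multi_index((x, y, z), self.grid.shape)
        pos = np.searchsorted(flat, lin)
        if pos >= flat.size or flat[pos] != lin:
            raise KeyError(f"cell ({x},{y},{z}) is outside the mask")
        return int(pos)

    def coordinate_of(self, index: int) -> tuple[int, int, int]:
        x, y, z = self.coords[index]
        return int(x), int(y), int(z)

    def same_grid(self, other: "VoxelMask") -> bool:
        return self.grid.shape == other.grid.shape and bool(
            np.array_equal(self.grid, other.grid)
        )


@dataclass
class ModalityMatrix:
    """A features x voxels matrix tied to the shared :class:`VoxelMask`."""

    values: np.ndarray                     # (R_k, N)
    feature_ids: list[str]
    modality_name: str
    mask: VoxelMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None]
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"matrix has {self.values.shape[1]} voxels, mask has "
                f"{self.mask.n_voxels}"
            )
        if len(self.feature_ids) != self.values.shape[0]:
            raise ValueError("feature_ids length does not match values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class AnnotationVolume:
    """Integer parcellation over the grid; 0 is reserved for background."""

    region_id: np.ndarray                  # (nx, ny, nz) int
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.ndim != 3:
            raise ValueError("region_id must be 3D")

    def labels_for(self, mask: VoxelMask) -> np.ndarray:
        """Region id of every in-mask voxel, in voxel-index order."""
        if self.region_id.shape != mask.grid.shape:
            raise ValueError("annotation grid does not match mask grid")
        labels = self.region_id[mask.grid]
        missing = set(np.unique(labels)) - set(self.region_names)
        if missing:
            raise ValueError(f"in-mask region ids without names: {sorted(missing)}")
        return labels
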