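"""Motor-network ROI atlas: loading, validation, and sphere voxelization.

The default atlas is the 20-region executive motor network (bilateral M1,
SMA, dorsal/ventral premotor, superior parietal, postcentral gyrus, thalamus,
basal ganglia, and cerebellar regions) defined as 5 mm diameter spheres
around published MNI coordinates.  Node order in every downstream matrix and
graph follows the atlas row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RoiEntry",
    "RoiAtlas",
    "GridSpec",
    "load_atlas",
    "build_sphere_masks",
    "masks_to_nifti",
    "KNOWN_ABBREVIATIONS",
    "SphereOverlapError",
]

KNOWN_ABBREVIATIONS = frozenset(
    {"SCb", "M1", "Th", "SPL", "SMA", "PMd", "PMv", "DN", "AICb", "PCG", "BG"}
)

_SIDES = frozenset({"L", "R"})
_MAX_MNI_MM = 120.0


class SphereOverlapError(ValueError):
    """Two ROI spheres claim the same voxel."""


@dataclass(frozen=True)
class RoiEntry:
    """One atlas row: a named ROI with an MNI center and sphere diameter."""

    id: int
    region: str
    abbreviation: str
    side: str
    mni: tuple[int, int, int]
    sphere_diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.abbreviation not in KNOWN_ABBREVIATIONS:
            raise ValueError(
                f"ROI {self.id}: unknown abbreviation {self.abbreviation!r}"
            )
        if self.side not in _SIDES:
            raise ValueError(f"ROI {self.id}: side must be 'L' or 'R', got {self.side!r}")
        if len(self.mni) != 3 or any(abs(c) > _MAX_MNI_MM for c in self.mni):
            raise ValueError(f"ROI {self.id}: MNI coordinate out of range: {self.mni}")
        if not self.sphere_diameter_mm > 0:
            raise ValueError(f"ROI {self.id}: sphere diameter must be positive")

    @property
    def label(self) -> str:
        """Compact node label, e.g. ``M1_L``."""
        return f"{self.abbreviation}_{self.side}"


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered collection of ROI entries; defines node identity and order."""

    entries: tuple[RoiEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"entry ids must be unique and contiguous from 1, got {ids}")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels (abbreviation + side) in atlas")

    @property
    def n_rois(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of MNI centers in mm."""
        return np.array([e.mni for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return self.n_rois

    def __iter__(self):
        return iter(self.entries)


def load_atlas(source: str | Path | pd.DataFrame | None = None) -> RoiAtlas:
    """Load an ROI atlas from a CSV (columns id,region,abbreviation,side,x,y,z).

    With no ``source`` the packaged 20-region motor atlas is returned.
    Row order is preserved and becomes the node order of all graphs.
    """
    if source is None:
        with resources.files("motorgraph.data").joinpath("motor_atlas.csv").open() as fh:
            df = pd.read_csv(fh)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    required = ["id", "region", "abbreviation", "side", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"atlas table missing columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate atlas ids: {dupes}")
    for axis in ("x", "y", "z"):
        if not np.issubdtype(pd.to_numeric(df[axis], errors="coerce").dtype, np.number) \
                or pd.to_numeric(df[axis], errors="coerce").isna().any():
            raise ValueError(f"non-numeric coordinate in column {axis!r}")

    entries = tuple(
        RoiEntry(
            id=int(row.id),
            region=str(row.region),
            abbreviation=str(row.abbreviation),
            side=str(row.side),
            mni=(int(row.x), int(row.y), int(row.z)),
        )
        for row in df.itertuples()
    )
    return RoiAtlas(entries=entries)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid in MNI space.

    ``origin`` is the MNI coordinate (mm) of the center of voxel (0, 0, 0);
    voxel centers are ``origin + index * voxel_size_mm`` along each axis.
    """

    origin: tuple[float, float, float]
    voxel_size_mm: float | tuple[float, float, float]
    shape: tuple[int, int, int]

    @property
    def voxel_sizes(self) -> np.ndarray:
        v = self.voxel_size_mm
        if np.isscalar(v):
            return np.full(3, float(v))
        return np.asarray(v, dtype=float)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_sizes)
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center MNI coordinates."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.voxel_sizes[d]
            for d in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


def build_sphere_masks(atlas: RoiAtlas, grid: GridSpec) -> np.ndarray:
    """Voxelize atlas spheres onto ``grid`` as an integer label volume.

    A voxel is labeled ``k`` iff its center lies within
    ``sphere_diameter_mm / 2`` (closed ball) of entry ``k``'s MNI center;
    label 0 is background.  Raises :class:`SphereOverlapError` if two spheres
    claim the same voxel (the default atlas is disjoint at 5 mm diameter).
    """
    centers = grid.voxel_centers().reshape(-1, 3)
    labels = np.zeros(centers.shape[0], dtype=np.int32)
    for entry in atlas:
        radius = entry.sphere_diameter_mm / 2.0
        d = np.linalg.norm(centers - np.asarray(entry.mni, dtype=float), axis=1)
        inside = d <= radius
        if not inside.any():
            warnings.warn(
                f"ROI {entry.id} ({entry.label}): no voxel center within "
                f"{radius:g} mm; mask is empty",
                stacklevel=2,
            )
            continue
        clash = inside & (labels != 0)
        if clash.any():
            other = sorted(set(labels[clash].tolist()))
            raise SphereOverlapError(
                f"ROI {entry.id} overlaps ROI(s) {other} on this grid"
            )
        labels[inside] = entry.id
    return labels.reshape(grid.shape)


def masks_to_nifti(label_volume: np.ndarray, grid: GridSpec):
    """Wrap a label volume in a NIfTI-1 image carrying the grid's affine."""
    import nibabel as nib

    return nib.Nifti1Image(label_volume.astype(np.int16), grid.affine())
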