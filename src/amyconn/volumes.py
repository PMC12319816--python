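"""Volume containers and NIfTI/TSV input-output.

All stages of the pipeline operate on three in-memory containers: an
integer-labeled region volume (:class:`LabeledVolume`), per-subject
streamline endpoint-count volumes (:class:`EndpointMap`), and per-subject
streamline density volumes (:class:`DensityMap`).  Volumes are read and
written as NIfTI-1 via nibabel; label tables are external TSV files so that
region definitions stay diffable.

No resampling, registration, or smoothing is performed anywhere: every
volume entering a joint computation must already share one voxel grid, and
geometry mismatches raise :class:`GeometryError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabeledVolume",
    "EndpointMap",
    "DensityMap",
    "FormatError",
    "GeometryError",
    "read_labeled_volume",
    "read_endpoint_map",
    "read_density_map",
    "write_volume",
    "write_label_table",
]

_INT_TOL = 1e-6


class FormatError(ValueError):
    """A volume's values violate the container's contract."""


class GeometryError(ValueError):
    """Two volumes that must share a grid do not."""


def _check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "volume") -> None:
    if a.shape != b.shape:
        raise GeometryError(f"{what} grids differ: {a.shape} vs {b.shape}")


@dataclass
class LabeledVolume:
    """Integer-labeled 3D grid: 0 is background, every other value is a region.

    ``label_table`` maps label integer -> (region_name, hemisphere_tag).
    """

    values: np.ndarray
    label_table: dict[int, tuple[str, str]]
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"labeled volume must be 3D, got {self.values.ndim}D")
        present = set(np.unique(self.values).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise FormatError(f"labels present in volume but absent from table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def labels_present(self) -> list[int]:
        return sorted(set(np.unique(self.values).tolist()) - {0})

    def region_names(self) -> list[str]:
        """Unique region names in label order."""
        seen: list[str] = []
        for lab in sorted(self.label_table):
            name = self.label_table[lab][0]
            if name not in seen:
                seen.append(name)
        return seen

    def mask(self, label: int) -> np.ndarray:
        return self.values == label

    def find_label(self, region_name: str, hemisphere_tag: str | None = None) -> int:
        for lab, (name, hemi) in self.label_table.items():
            if name == region_name and (hemisphere_tag is None or hemi == hemisphere_tag):
                return lab
        raise KeyError(f"region {region_name!r} (hemisphere {hemisphere_tag!r}) not in label table")


@dataclass
class EndpointMap:
    """Per-subject 3D grid of non-negative integer streamline-endpoint counts."""

    counts: np.ndarray
    subject_id: str
    hemisphere_tag: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 3:
            raise FormatError(f"endpoint map must be 3D, got {arr.ndim}D")
        if np.any(arr < 0):
            raise FormatError("endpoint map contains negative values")
        rounded = np.rint(arr)
        if np.any(np.abs(arr - rounded) > _INT_TOL):
            raise FormatError("endpoint map contains non-integer values")
        self.counts = rounded.astype(np.int64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape


@dataclass
class DensityMap:
    """Per-subject 3D grid of non-negative streamline-density values.

    ``seeding_attempts`` is the number of streamline-generation trials that
    produced the map; density sums are normalized by it downstream.
    """

    values: np.ndarray
    subject_id: str
    seeding_attempts: int = 1
    hemisphere_tag: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise FormatError(f"density map must be 3D, got {arr.ndim}D")
        if np.any(arr < 0):
            raise FormatError("density map contains negative values")
        if self.seeding_attempts <= 0:
            raise FormatError("seeding_attempts must be a positive integer")
        self.values = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


# ---------------------------------------------------------------------------
# readers / writers


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_label_table(path: str | Path) -> dict[int, tuple[str, str]]:
    """Read a TSV with columns region, hemisphere, label_int (n_voxels optional)."""
    df = pd.read_csv(path, sep="\t")
    required = {"region", "hemisphere", "label_int"}
    if not required.issubset(df.columns):
        raise FormatError(f"label table {path} missing columns {required - set(df.columns)}")
    return {
        int(row.label_int): (str(row.region), str(row.hemisphere))
        for row in df.itertuples()
    }


def read_labeled_volume(
    path: str | Path,
    label_table_path: str | Path,
    reference_shape: tuple[int, ...] | None = None,
) -> LabeledVolume:
    """Read and validate a labeled ROI/atlas volume.

    Raises :class:`FormatError` if voxel values are not integers (beyond a
    1e-6 tolerance) or carry labels absent from the table, and
    :class:`GeometryError` if ``reference_shape`` is given and differs.
    """
    data, zooms = _load_nifti(path)
    rounded = np.rint(data)
    if np.any(np.abs(data - rounded) > _INT_TOL):
        raise FormatError(f"{path}: non-integer label values")
    values = rounded.astype(np.int64)
    if reference_shape is not None and tuple(values.shape) != tuple(reference_shape):
        raise GeometryError(f"{path}: shape {values.shape} != reference {tuple(reference_shape)}")
    table = read_label_table(label_table_path)
    return LabeledVolume(values=values, label_table=table, voxel_dims=zooms)


def read_endpoint_map(
    path: str | Path,
    subject_id: str,
    hemisphere_tag: str = "",
    reference_shape: tuple[int, ...] | None = None,
) -> EndpointMap:
    data, _ = _load_nifti(path)
    if reference_shape is not None and tuple(data.shape) != tuple(reference_shape):
        raise GeometryError(f"{path}: shape {data.shape} != reference {tuple(reference_shape)}")
    return EndpointMap(counts=data, subject_id=subject_id, hemisphere_tag=hemisphere_tag)


def read_density_map(
    path: str | Path,
    subject_id: str,
    seeding_attempts: int,
    hemisphere_tag: str = "",
    reference_shape: tuple[int, ...] | None = None,
) -> DensityMap:
    data, _ = _load_nifti(path)
    if reference_shape is not None and tuple(data.shape) != tuple(reference_shape):
        raise GeometryError(f"{path}: shape {data.shape} != reference {tuple(reference_shape)}")
    return DensityMap(
        values=data,
        subject_id=subject_id,
        seeding_attempts=seeding_attempts,
        hemisphere_tag=hemisphere_tag,
    )


def write_volume(
    array: np.ndarray,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 3D array as NIfTI-1 with a diagonal affine from voxel_dims."""
    arr = np.asarray(array)
    affine = np.diag(list(voxel_dims) + [1.0])
    if arr.dtype.kind in "ib":
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float64)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_label_table(
    label_table: dict[int, tuple[str, str]],
    path: str | Path,
    n_voxels: dict[int, int] | None = None,
) -> None:
    rows = []
    for lab in sorted(label_table):
        name, hemi = label_table[lab]
        row = {"region": name, "hemisphere": hemi, "label_int": lab}
        if n_voxels is not None:
            row["n_voxels"] = n_voxels.get(lab, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
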