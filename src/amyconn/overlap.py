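"""Group endpoint maps, chance-level thresholding, and Dice colocalization.

Dice is offered in two modes.  ``volume3d`` is the ordinary 3D overlap
coefficient.  ``collapse2d`` first projects both binary masks along the
third array axis (a pixel is set if any voxel in its column is set) and
computes Dice on the resulting 2D images — replicating a quirk of the
original analysis pipeline, where volumes were flattened on load before the
overlap was taken.  collapse2d is the default for fidelity; volume3d is the
geometrically meaningful choice and is recommended for new work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .endpoints import PoissonNull
from .volumes import EndpointMap, GeometryError

__all__ = ["OverlapResult", "group_endpoint_map", "threshold_binarize", "dice"]


@dataclass
class OverlapResult:
    region_name: str
    dice: float
    mode: str
    threshold_used: int | None = None


def group_endpoint_map(maps: list[EndpointMap]) -> np.ndarray:
    """Voxelwise mean endpoint count across subjects."""
    if not maps:
        raise ValueError("need at least one endpoint map")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise GeometryError(f"endpoint map grids differ: {m.shape} vs {shape}")
    return np.mean([m.counts for m in maps], axis=0)


def threshold_binarize(values: np.ndarray, null: PoissonNull) -> np.ndarray:
    """Binary mask of voxels whose value strictly exceeds the null's critical count."""
    return np.asarray(values) > null.critical_count


def _collapse(mask: np.ndarray, axis: int) -> np.ndarray:
    return np.asarray(mask, dtype=bool).any(axis=axis)


def dice(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    mode: str = "collapse2d",
    region_name: str = "",
    threshold_used: int | None = None,
    collapse_axis: int = 2,
) -> OverlapResult:
    """Dice coefficient 2|A∩B| / (|A| + |B|) between two binary masks.

    In ``collapse2d`` mode both masks are first flattened along
    ``collapse_axis`` (default: the third array axis) by a column-wise
    any().  Two empty masks give Dice 0 with a warning.
    """
    A = np.asarray(mask_a, dtype=bool)
    B = np.asarray(mask_b, dtype=bool)
    if A.shape != B.shape:
        raise GeometryError(f"mask grids differ: {A.shape} vs {B.shape}")
    if mode == "collapse2d":
        A = _collapse(A, collapse_axis)
        B = _collapse(B, collapse_axis)
    elif mode != "volume3d":
        raise ValueError("mode must be 'collapse2d' or 'volume3d'")
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 0", stacklevel=2)
        value = 0.0
    else:
        value = 2.0 * int((A & B).sum()) / denom
    return OverlapResult(region_name=region_name, dice=value, mode=mode, threshold_used=threshold_used)
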