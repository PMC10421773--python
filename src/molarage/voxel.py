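"""T2 signal-intensity thresholding and voxel-count volumetry.

Voxels of a 3-D T2 intensity grid are partitioned into three tooth
tissues by inclusive intensity thresholds:

* 0-63    hard tooth tissue (dentine + enamel + cementum)
* 64-100  low signal soft tissue (LSST, believed predentine)
* >=101   high signal soft tissue (HSST, believed pulp)

Volumes are voxel counts times the voxel volume, reported in ml (cm^3).
The tooth mask separating tooth from background is caller-supplied;
no automatic tooth detection is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HARD_MAX",
    "LSST_MAX",
    "IntensityGrid",
    "ToothVolumes",
    "classify_voxel",
    "classify_array",
    "measure_volumes",
    "voxels_per_ml",
    "load_grid",
]

# Inclusive upper bounds of the two lower intensity bands.
HARD_MAX = 63
LSST_MAX = 100

_LABELS = ("hard", "lsst", "hsst")


@dataclass(frozen=True)
class ToothVolumes:
    """Segmented tissue volumes for one tooth, in ml."""

    hard: float
    hsst: float
    lsst: float

    def __post_init__(self) -> None:
        for name in ("hard", "hsst", "lsst"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} volume must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.hard + self.hsst + self.lsst


@dataclass(frozen=True)
class IntensityGrid:
    """A 3-D grid of non-negative integer T2 intensities with isotropic voxels."""

    values: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("intensity grid must be a non-empty 3-D array")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)):
                raise ValueError("intensities must be finite")
            warnings.warn(
                "non-integer intensities floored to integers", stacklevel=3
            )
            values = np.floor(values).astype(np.int64)
        if values.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "values", values)
        if not (np.isfinite(self.voxel_size_mm) and self.voxel_size_mm > 0):
            raise ValueError("voxel_size_mm must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0


def classify_voxel(intensity: int) -> str:
    """Label a single voxel intensity as ``hard``, ``lsst`` or ``hsst``.

    Bounds are inclusive: 0-63 hard, 64-100 lsst, >=101 hsst.
    """
    if intensity != int(intensity):
        warnings.warn("non-integer intensity floored", stacklevel=2)
    intensity = int(np.floor(intensity))
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    if intensity <= HARD_MAX:
        return "hard"
    if intensity <= LSST_MAX:
        return "lsst"
    return "hsst"


def classify_array(values: np.ndarray) -> np.ndarray:
    """Vectorised voxel labelling; returns an object array of label strings."""
    values = np.asarray(values)
    if not np.issubdtype(values.dtype, np.integer):
        warnings.warn("non-integer intensities floored to integers", stacklevel=2)
        values = np.floor(values).astype(np.int64)
    if values.size and values.min() < 0:
        raise ValueError("intensities must be non-negative")
    out = np.full(values.shape, "hsst", dtype=object)
    out[values <= LSST_MAX] = "lsst"
    out[values <= HARD_MAX] = "hard"
    return out


def measure_volumes(grid: IntensityGrid, mask: np.ndarray | None = None) -> ToothVolumes:
    """Count labelled voxels inside ``mask`` and convert to ml.

    ``mask`` (boolean, same shape as the grid) delineates the tooth; when
    omitted every voxel is counted.  Per-tissue volumes sum exactly to the
    masked voxel count times the voxel volume.
    """
    values = grid.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid shape {values.shape}"
            )
        values = values[mask]
    vv = grid.voxel_volume_ml
    n_hard = int(np.count_nonzero(values <= HARD_MAX))
    n_soft_low = int(np.count_nonzero(values <= LSST_MAX)) - n_hard
    n_soft_high = values.size - n_hard - n_soft_low
    return ToothVolumes(hard=n_hard * vv, hsst=n_soft_high * vv, lsst=n_soft_low * vv)


def voxels_per_ml(voxel_size_mm: float) -> float:
    """Number of isotropic voxels of the given edge length in 1 ml."""
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    return 1000.0 / voxel_size_mm**3


def load_grid(path: str | Path) -> IntensityGrid:
    """Load an intensity grid from NIfTI (needs nibabel) or a JSON container.

    The JSON container holds ``voxel_size_mm`` and ``values`` as a nested
    list — a portable plain-text exchange format for toy phantoms.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"}:
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError("only isotropic voxels are supported")
        return IntensityGrid(np.asarray(img.dataobj), float(zooms[0]))
    with open(path) as fh:
        doc = json.load(fh)
    return IntensityGrid(np.asarray(doc["values"]), float(doc["voxel_size_mm"]))
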