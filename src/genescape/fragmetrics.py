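"""FRAGSTATS-style class metrics on binary habitat rasters.

Patches are 8-connected components (the FRAGSTATS default adjacency).
Reported metrics follow FRAGSTATS conventions: PLAND and LPI in percent of
landscape area, AREA_MN in hectares, PD in patches per 100 ha, GYRATE in
meters (mean distance of cell centers to the patch centroid; a single-cell
patch has GYRATE 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Patch", "ClassMetrics", "label_patches", "class_metrics"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Patch:
    patch_id: int
    cell_indices: np.ndarray  # (n_cells, 2) array of (row, col)
    area: float  # m^2
    centroid: tuple[float, float]  # (x, y) in meters
    gyrate: float  # m

    @property
    def n_cells(self) -> int:
        return len(self.cell_indices)


@dataclass
class ClassMetrics:
    pland: float  # % of landscape
    area_mn: float  # mean patch area, ha
    np_: int  # number of patches
    pd: float  # patches per 100 ha
    lpi: float  # largest patch area / landscape area * 100
    gyrate_mn: float  # mean radius of gyration, m

    def as_dict(self) -> dict[str, float]:
        return {
            "pland": self.pland,
            "area_mn": self.area_mn,
            "np": self.np_,
            "pd": self.pd,
            "lpi": self.lpi,
            "gyrate_mn": self.gyrate_mn,
        }


def label_patches(habitat: np.ndarray, cell_size: float = 1.0) -> list[Patch]:
    """8-connected components of a binary habitat raster, as Patch records."""
    habitat = np.asarray(habitat).astype(bool)
    labels, n = ndimage.label(habitat, structure=_EIGHT)
    patches: list[Patch] = []
    if n == 0:
        return patches
    n_rows = habitat.shape[0]
    for pid in range(1, n + 1):
        rows, cols = np.nonzero(labels == pid)
        # cell-center coordinates with origin at the lower-left corner
        xs = (cols + 0.5) * cell_size
        ys = (n_rows - rows - 0.5) * cell_size
        cx, cy = xs.mean(), ys.mean()
        gyr = float(np.mean(np.hypot(xs - cx, ys - cy)))
        patches.append(
            Patch(
                patch_id=pid,
                cell_indices=np.column_stack([rows, cols]),
                area=float(len(rows)) * cell_size**2,
                centroid=(float(cx), float(cy)),
                gyrate=gyr,
            )
        )
    return patches


def class_metrics(patches: list[Patch], landscape_area: float, cell_size: float) -> ClassMetrics:
    """Aggregate patch records into FRAGSTATS-style class metrics."""
    if not landscape_area > 0:
        raise ValueError("landscape_area must be positive")
    area_ha = landscape_area / 1e4
    if not patches:
        return ClassMetrics(pland=0.0, area_mn=float("nan"), np_=0, pd=0.0, lpi=float("nan"), gyrate_mn=float("nan"))
    areas = np.array([p.area for p in patches])
    return ClassMetrics(
        pland=float(areas.sum() / landscape_area * 100.0),
        area_mn=float(areas.mean() / 1e4),
        np_=len(patches),
        pd=float(len(patches) / area_ha * 100.0),
        lpi=float(areas.max() / landscape_area * 100.0),
        gyrate_mn=float(np.mean([p.gyrate for p in patches])),
    )


def habitat_class_metrics(habitat: np.ndarray, cell_size: float) -> ClassMetrics:
    """Convenience: label + aggregate in one call."""
    habitat = np.asarray(habitat).astype(bool)
    area = habitat.size * cell_size**2
    return class_metrics(label_patches(habitat, cell_size), area, cell_size)
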