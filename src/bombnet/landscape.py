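"""Fragmentation covariates: shape complexity, isolation, buffer composition.

* Shape complexity is the perimeter-to-area ratio (m/ha): more edge per
  unit area means a more complex, more fragmented patch outline.
* Isolation is the mean distance (m) to the k nearest forest patches
  (default k = 5); patches connected to other forest through corridors are
  assigned isolation 0.
* Buffer composition is the percentage of each land-cover class inside a
  disc (default radius 500 m, roughly a bumblebee foraging bout) centred
  on the sampling transect, computed from a plain-text class-code grid by
  a cell-centre membership rule — or passed through from user-supplied
  precomputed fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PatchGeometry

__all__ = [
    "LandscapeCovariates",
    "CoverGrid",
    "shape_complexity",
    "patch_isolation",
    "buffer_composition",
    "covariate_table",
    "DEFAULT_K_NEIGHBOURS",
    "DEFAULT_BUFFER_RADIUS_M",
]

log = logging.getLogger(__name__)

DEFAULT_K_NEIGHBOURS = 5
DEFAULT_BUFFER_RADIUS_M = 500.0


@dataclass(frozen=True)
class LandscapeCovariates:
    """Per-patch fragmentation covariates used as model predictors."""

    patch_id: str
    size: float                 # ha
    perimeter: float            # m
    shape_complexity: float     # m per ha
    isolation: float            # m
    pct_forest_500m: float      # 0..100
    pct_cropland_500m: float    # 0..100


def shape_complexity(geometry: PatchGeometry) -> float:
    """Patch perimeter / patch size, in metres per hectare."""
    return geometry.perimeter / geometry.size


def patch_isolation(
    patches: Sequence[PatchGeometry],
    k: int = DEFAULT_K_NEIGHBOURS,
    distances: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Mean distance of each patch to its k closest patches, in metres.

    An explicit pairwise distance matrix (labelled DataFrame, metres) is
    authoritative when given; otherwise Euclidean centroid-to-centroid
    distances are used.  Corridor-connected patches get isolation 0
    regardless of distances.  With fewer than k neighbours available the
    mean is over those present (logged).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ids = [p.patch_id for p in patches]
    if distances is not None:
        dmat = distances.loc[ids, ids].to_numpy(dtype=float)
    else:
        missing = [p.patch_id for p in patches if p.centroid is None]
        if missing:
            raise ValueError(f"no distance matrix and no centroid for: {missing}")
        xy = np.array([p.centroid for p in patches])
        diff = xy[:, None, :] - xy[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=2))

    out: dict[str, float] = {}
    for i, patch in enumerate(patches):
        if patch.corridor_connected:
            out[patch.patch_id] = 0.0
            continue
        others = np.delete(dmat[i], i)
        if others.size == 0:
            raise ValueError(f"patch {patch.patch_id} has no other patch to measure against")
        if others.size < k:
            log.warning(
                "patch %s has only %d neighbours (< k=%d); using all of them",
                patch.patch_id, others.size, k,
            )
        nearest = np.sort(others)[: min(k, others.size)]
        out[patch.patch_id] = float(nearest.mean())
    return out


@dataclass(frozen=True)
class CoverGrid:
    """Plain-text land-cover raster: class codes on a regular grid.

    ``codes[r, c]`` is the class of the cell whose centre is at
    ``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``
    in metres; row 0 is the southern edge.
    """

    codes: np.ndarray            # 2-D array of string class codes
    cell_size: float             # metres
    origin: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def read_text(cls, path, cell_size: float, origin=(0.0, 0.0)) -> "CoverGrid":
        """Read a whitespace-separated class-code matrix (one row per line)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    rows.append(line.split())
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged grid rows (widths {sorted(widths)})")
        return cls(np.array(rows, dtype=object), float(cell_size), tuple(origin))

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.codes.shape
        xs = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def buffer_composition(
    grid: CoverGrid,
    point: tuple[float, float],
    radius: float = DEFAULT_BUFFER_RADIUS_M,
    classes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Percentage of each land-cover class within ``radius`` of ``point``.

    A cell belongs to the disc when its centre does.  Raises when part of
    the disc lies outside the grid extent (reporting the missing area
    fraction estimated from the disc/extent overlap).  ``classes`` forces
    zero entries for classes absent from the buffer.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    px, py = point
    nr, nc = grid.codes.shape
    x0, y0 = grid.origin
    x1 = x0 + nc * grid.cell_size
    y1 = y0 + nr * grid.cell_size
    if px - radius < x0 or px + radius > x1 or py - radius < y0 or py + radius > y1:
        # crude bound on the uncovered disc area via the clipped bounding box
        cov_x = min(px + radius, x1) - max(px - radius, x0)
        cov_y = min(py + radius, y1) - max(py - radius, y0)
        covered = max(cov_x, 0.0) * max(cov_y, 0.0)
        missing = max(0.0, 1.0 - covered / (2 * radius) ** 2)
        raise ValueError(
            f"buffer disc exits grid extent; >= {missing:.0%} of the bounding box uncovered"
        )
    X, Y = grid.cell_centres()
    inside = (X - px) ** 2 + (Y - py) ** 2 <= radius**2
    n_inside = int(inside.sum())
    if n_inside == 0:
        # radius smaller than one cell: the containing cell decides
        col = min(int((px - x0) / grid.cell_size), nc - 1)
        row = min(int((py - y0) / grid.cell_size), nr - 1)
        counts = {str(grid.codes[row, col]): 1}
        n_inside = 1
    else:
        labels, freq = np.unique(grid.codes[inside].astype(str), return_counts=True)
        counts = dict(zip(labels.tolist(), freq.tolist()))
    pct = {cls: 100.0 * n / n_inside for cls, n in counts.items()}
    for cls in classes or ():
        pct.setdefault(cls, 0.0)
    return pct


def covariate_table(
    patches: Sequence[PatchGeometry],
    k: int = DEFAULT_K_NEIGHBOURS,
    distances: pd.DataFrame | None = None,
    buffer_pcts: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Join all landscape covariates into one per-patch table.

    Buffer percentages come from ``buffer_pcts`` (patch -> class -> %) when
    supplied, else from each patch's stored ``cover_fractions``; forest and
    cropland default to 0 when the class is absent.
    """
    isolation = patch_isolation(patches, k=k, distances=distances)
    rows = []
    for p in sorted(patches, key=lambda p: p.patch_id):
        if buffer_pcts is not None and p.patch_id in buffer_pcts:
            pct = dict(buffer_pcts[p.patch_id])
        elif p.cover_fractions:
            pct = {cls: 100.0 * f for cls, f in p.cover_fractions.items()}
        else:
            pct = {}
        rows.append(
            {
                "patch": p.patch_id,
                "size_ha": p.size,
                "perimeter_m": p.perimeter,
                "shape_complexity": shape_complexity(p),
                "isolation_m": isolation[p.patch_id],
                "pct_forest_500m": pct.get("forest", 0.0),
                "pct_cropland_500m": pct.get("cropland", 0.0),
            }
        )
    return pd.DataFrame(rows)
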