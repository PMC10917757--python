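"""Grid data model, zonal aggregation and area-matched mask adjustment.

A :class:`Grid` is a single-band raster: a 2-D array with a nodata sentinel,
a pixel area in hectares (default 1 ha, i.e. 100 m resolution) and a
transform tag shared by all co-registered grids of a scene. Grids are read
and written as single-band TIFF files with the georeferencing stored in a
JSON tag, so scenes round-trip losslessly without a GIS stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

__all__ = ["Grid", "zonal_stats", "adjust_mask_to_area", "read_grid", "write_grid"]


@dataclass
class Grid:
    """A co-registered single-band raster."""

    values: np.ndarray
    nodata: float = np.nan
    pixel_area: float = 1.0                       # ha per pixel
    transform: Tuple[float, float, float] = (0.0, 0.0, 100.0)  # x0, y0, res (m)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.pixel_area <= 0:
            raise ValueError("pixel area must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        """Boolean mask of data pixels (not nodata, finite)."""
        v = self.values
        if np.isnan(self.nodata) if isinstance(self.nodata, float) else False:
            return np.isfinite(v) if np.issubdtype(v.dtype, np.floating) else np.ones(v.shape, bool)
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def like(self, values: np.ndarray, nodata=np.nan) -> "Grid":
        """New grid sharing this grid's registration.

        ``nodata`` defaults to NaN (the convention for computed float
        grids) rather than inheriting the source sentinel: derived layers
        rarely share the nodata semantics of e.g. an integer zone map.
        """
        return Grid(
            values,
            nodata=nodata,
            pixel_area=self.pixel_area,
            transform=self.transform,
        )

    def copy(self) -> "Grid":
        return Grid(
            self.values.copy(), nodata=self.nodata,
            pixel_area=self.pixel_area, transform=self.transform,
        )


def require_coregistered(*grids: Grid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValueError(f"grid shapes differ: {g.shape} vs {ref.shape}")
        if not np.allclose(g.transform, ref.transform):
            raise ValueError("grid transforms differ; grids are not co-registered")
        if g.pixel_area != ref.pixel_area:
            raise ValueError("pixel areas differ")


def zonal_stats(
    value_grid: Grid, zone_map: Grid, mask: Optional[Grid] = None
) -> pd.DataFrame:
    """Per-zone sum, mean, count and area of a value grid.

    Zones are the positive integer ids of ``zone_map``; pixels outside any
    zone (id <= 0 or nodata), nodata value pixels and masked-out pixels are
    excluded. Zones whose every pixel is excluded appear with count 0 and an
    ``empty`` flag; their mean is NaN.
    """
    grids = [value_grid, zone_map] + ([mask] if mask is not None else [])
    require_coregistered(*grids)

    zones = np.asarray(zone_map.values)
    zvalid = zone_map.valid() & (zones > 0)
    include = zvalid & value_grid.valid()
    if mask is not None:
        include &= mask.valid() & (mask.values != 0)

    zone_ids = np.unique(zones[zvalid]).astype(int)
    zmax = int(zone_ids.max()) if zone_ids.size else 0
    z = zones[include].astype(int)
    v = np.asarray(value_grid.values, dtype=float)[include]
    sums = np.bincount(z, weights=v, minlength=zmax + 1)
    counts = np.bincount(z, minlength=zmax + 1)

    rows = []
    for zid in zone_ids:
        n = int(counts[zid])
        rows.append(
            {
                "zone": int(zid),
                "sum": sums[zid] if n else 0.0,
                "mean": sums[zid] / n if n else np.nan,
                "count": n,
                "area_ha": n * value_grid.pixel_area,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows).set_index("zone")


def _rank_order(cover: np.ndarray, idx: np.ndarray, ascending: bool) -> np.ndarray:
    """Order candidate pixels by tree cover, ties broken by row-major index
    (ascending) so the result is reproducible bit-for-bit."""
    key = cover if ascending else -cover
    return idx[np.lexsort((idx, key))]


def adjust_mask_to_area(
    forest_mask: Grid,
    tree_cover: Grid,
    exclusion: Optional[Grid],
    targets: Mapping[int, float],
    zone_map: Grid,
) -> Tuple[Grid, pd.DataFrame]:
    """Force the mapped forest area of every zone to match a target area.

    Where the mask maps more forest than the statistic, forest pixels with
    the lowest tree cover are converted to non-forest; where it maps less,
    non-forest pixels with the highest tree cover — outside the exclusion
    layer (trees in urban/agricultural context) — are converted to forest.
    The adjusted area is within one pixel of the target in every zone.
    Pixels outside any zone are unchanged; pixels never move between zones.

    Returns the adjusted mask and a per-zone report with the achieved area
    and an ``exhausted`` flag for zones whose target was unattainable (all
    candidate pixels used up); those zones carry the best achievable area.
    """
    grids = [forest_mask, tree_cover, zone_map] + (
        [exclusion] if exclusion is not None else []
    )
    require_coregistered(*grids)

    out = np.asarray(forest_mask.values).astype(np.uint8).copy()
    zones = np.asarray(zone_map.values)
    cover = np.asarray(tree_cover.values, dtype=float)
    excl = (
        (np.asarray(exclusion.values) != 0) if exclusion is not None
        else np.zeros(out.shape, bool)
    )
    pa = forest_mask.pixel_area
    flat_zone = zones.ravel()
    flat_out = out.ravel()
    flat_cover = cover.ravel()
    flat_excl = excl.ravel()

    records = []
    for zid, target in sorted(targets.items()):
        if target < 0:
            raise ValueError(f"zone {zid}: negative target area")
        in_zone = np.flatnonzero(flat_zone == zid)
        n_now = int(flat_out[in_zone].sum())
        n_target = target / pa
        delta = int(np.round(n_now - n_target))
        exhausted = False
        if delta > 0:  # shrink: drop lowest-cover forest pixels
            cand = in_zone[flat_out[in_zone] == 1]
            order = _rank_order(flat_cover[cand], cand, ascending=True)
            flat_out[order[:delta]] = 0
        elif delta < 0:  # grow: add highest-cover eligible non-forest pixels
            cand = in_zone[(flat_out[in_zone] == 0) & (~flat_excl[in_zone])]
            order = _rank_order(flat_cover[cand], cand, ascending=False)
            need = -delta
            if order.size < need:
                exhausted = True
                need = order.size
            flat_out[order[:need]] = 1
        n_final = int(flat_out[in_zone].sum())
        records.append(
            {
                "zone": int(zid),
                "target_ha": float(target),
                "initial_ha": n_now * pa,
                "achieved_ha": n_final * pa,
                "abs_diff_ha": abs(n_final * pa - target),
                "exhausted": exhausted,
            }
        )

    report = pd.DataFrame(records).set_index("zone")
    return forest_mask.like(flat_out.reshape(out.shape), nodata=255), report


def write_grid(path, grid: Grid) -> None:
    """Write a grid as a single-band TIFF with JSON georeferencing tag."""
    meta = {
        "nodata": None if (isinstance(grid.nodata, float) and np.isnan(grid.nodata))
        else float(grid.nodata),
        "pixel_area_ha": grid.pixel_area,
        "transform": list(grid.transform),
    }
    values = grid.values
    if values.dtype == np.uint8 or values.dtype == bool:
        values = values.astype(np.uint8)
    else:
        values = values.astype(np.float32)
    tifffile.imwrite(str(path), values, description=json.dumps(meta))


def read_grid(path) -> Grid:
    """Read a grid written by :func:`write_grid`."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    nodata = meta.get("nodata")
    return Grid(
        values,
        nodata=np.nan if nodata is None else nodata,
        pixel_area=meta.get("pixel_area_ha", 1.0),
        transform=tuple(meta.get("transform", (0.0, 0.0, 100.0))),
    )
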