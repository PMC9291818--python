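"""Mosaic assembly of acquisition tiles and N2-adsorption QC.

Overlapping acquisitions of the same sample area are not independent
replicates — the first raster alters the surface — so overlap pixels are
taken from the tile whose centre is nearest (ties broken by acquisition
order), never averaged or summed. A contribution map records the source
tile of every canvas pixel; non-overlap pixels are copied verbatim.

The QC screen targets the bias caused by N2 of natural isotopic abundance
adsorbing onto previously rastered areas: for every tile measured after a
neighbour, the mean at%15N of its re-measured strip is compared against a
matched interior band by a one-sided rank-sum test; significantly depressed
strips are flagged. Pre-sputtered tiles (the instrumental remedy) are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .scene import TileGrid
from .stack_io import IonCountStack

__all__ = ["MosaicLayout", "assemble_mosaic", "adsorption_qc", "overlap_px_from_um"]


def overlap_px_from_um(overlap_um: float, pixel_size_um: float) -> int:
    """Overlap in pixels, round-half-up from micrometres."""
    return int(np.floor(overlap_um / pixel_size_um + 0.5))


@dataclass
class MosaicLayout:
    """Placement of a rows x cols tile grid on the mosaic canvas.

    ``overlap_px`` may be given directly or derived from ``overlap_um``
    through the pixel size (round-half-up). Acquisition order is row-major.
    """

    rows: int
    cols: int
    tile_px: int
    pixel_size_um: float
    overlap_px: int | None = None
    overlap_um: float | None = None
    pre_sputtered: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.overlap_px is None:
            if self.overlap_um is None:
                self.overlap_px = 0
            else:
                self.overlap_px = overlap_px_from_um(self.overlap_um, self.pixel_size_um)
        if self.overlap_um is None:
            self.overlap_um = self.overlap_px * self.pixel_size_um
        if not self.pre_sputtered:
            self.pre_sputtered = [False] * self.n_tiles
        if len(self.pre_sputtered) != self.n_tiles:
            raise ValueError("pre_sputtered length != number of tiles")
        if not (0 <= self.overlap_px < self.tile_px):
            raise ValueError("overlap_px must be in [0, tile_px)")

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    @property
    def step(self) -> int:
        return self.tile_px - self.overlap_px

    def offsets(self) -> list[tuple[int, int]]:
        return [(r * self.step, c * self.step)
                for r in range(self.rows) for c in range(self.cols)]

    def canvas_shape(self) -> tuple[int, int]:
        return ((self.rows - 1) * self.step + self.tile_px,
                (self.cols - 1) * self.step + self.tile_px)

    @classmethod
    def from_grid(cls, grid: TileGrid, pixel_size_um: float) -> "MosaicLayout":
        return cls(rows=grid.rows, cols=grid.cols, tile_px=grid.tile_px,
                   pixel_size_um=pixel_size_um, overlap_px=grid.overlap_px,
                   pre_sputtered=grid.sputter_flags())

    def to_dict(self) -> dict:
        shape = self.canvas_shape()
        return {
            "rows": self.rows, "cols": self.cols, "tile_px": self.tile_px,
            "pixel_size_um": self.pixel_size_um, "overlap_px": self.overlap_px,
            "overlap_um": self.overlap_um, "pre_sputtered": list(self.pre_sputtered),
            # spans follow the stitching arithmetic (tiles minus overlaps),
            # recorded explicitly so nominal field-of-view figures are never
            # silently substituted
            "canvas_px": list(shape),
            "canvas_um": [s * self.pixel_size_um for s in shape],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MosaicLayout":
        return cls(rows=d["rows"], cols=d["cols"], tile_px=d["tile_px"],
                   pixel_size_um=d["pixel_size_um"], overlap_px=d.get("overlap_px"),
                   overlap_um=d.get("overlap_um"),
                   pre_sputtered=list(d.get("pre_sputtered", [])))


def contribution_map(layout: MosaicLayout) -> np.ndarray:
    """Source tile index per canvas pixel under the nearest-tile-centre rule.

    Ties go to the tile acquired first (lower index).
    """
    shape = layout.canvas_shape()
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    best = np.full(shape, -1, dtype=np.int32)
    best_d = np.full(shape, np.inf)
    half = (layout.tile_px - 1) / 2.0
    for idx, (oy, ox) in enumerate(layout.offsets()):
        inside = (yy >= oy) & (yy < oy + layout.tile_px) & (xx >= ox) & (xx < ox + layout.tile_px)
        d = np.hypot(yy - (oy + half), xx - (ox + half))
        take = inside & (d < best_d - 1e-9)
        best[take] = idx
        best_d[take] = d[take]
    return best


def assemble_mosaic(
    tiles: list[IonCountStack], layout: MosaicLayout
) -> tuple[IonCountStack, np.ndarray]:
    """Stitch tiles to a canvas stack; returns (canvas, contribution map)."""
    if len(tiles) != layout.n_tiles:
        raise ValueError(f"expected {layout.n_tiles} tiles, got {len(tiles)}")
    species = tiles[0].species
    px = tiles[0].pixel_size_um
    for t in tiles:
        if t.species != species:
            raise ValueError("tiles have inconsistent species sets")
        if not np.isclose(t.pixel_size_um, px):
            raise ValueError("tiles have inconsistent pixel sizes")
        if t.shape != (layout.tile_px, layout.tile_px):
            raise ValueError(f"tile shape {t.shape} != layout tile_px {layout.tile_px}")
    contrib = contribution_map(layout)
    shape = layout.canvas_shape()
    counts = {sp: np.zeros(shape, dtype=np.uint32) for sp in species}
    for idx, ((oy, ox), tile) in enumerate(zip(layout.offsets(), tiles)):
        sl = (slice(oy, oy + layout.tile_px), slice(ox, ox + layout.tile_px))
        own = contrib[sl] == idx
        for sp in species:
            counts[sp][sl][own] = tile.counts[sp][own]
    canvas = IonCountStack(
        counts=counts, pixel_size_um=px, dwell_ms=tiles[0].dwell_ms,
        planes=tiles[0].planes, stage_offset_um=(0.0, 0.0),
        pre_sputtered=all(t.pre_sputtered for t in tiles), order_index=0,
    )
    return canvas, contrib


def adsorption_qc(
    at15n_pct: np.ndarray,
    layout: MosaicLayout,
    contrib: np.ndarray | None = None,
    alpha: float = 0.01,
    min_pixels: int = 20,
) -> pd.DataFrame:
    """Screen re-measured strips for the N2-adsorption at%15N depression.

    For every non-pre-sputtered tile whose footprint overlaps an earlier
    tile, the canvas pixels this tile contributed inside that overlap (its
    re-measured strip) are compared against a matched interior band of equal
    width by a one-sided Mann-Whitney test (strip below interior). Returns
    one row per testable tile: pixel counts, strip/interior means, effect
    (strip mean - interior mean, at%), p-value and flag. Layouts without
    overlap yield an empty report.
    """
    if contrib is None:
        contrib = contribution_map(layout)
    offsets = layout.offsets()
    footprints = []
    shape = layout.canvas_shape()
    for oy, ox in offsets:
        fp = np.zeros(shape, dtype=bool)
        fp[oy:oy + layout.tile_px, ox:ox + layout.tile_px] = True
        footprints.append(fp)
    rows = []
    earlier = np.zeros(shape, dtype=bool)
    any_overlap = np.zeros(shape, dtype=bool)
    for idx in range(layout.n_tiles):
        for j in range(idx):
            any_overlap |= footprints[idx] & footprints[j]
    for idx in range(layout.n_tiles):
        if idx > 0:
            earlier |= footprints[idx - 1]
        if idx == 0:
            continue
        if layout.pre_sputtered[idx]:
            continue
        own = contrib == idx
        strip = own & earlier & footprints[idx]
        if not strip.any():
            continue
        width = max(1, int(np.ceil(layout.overlap_px / 2)))
        # matched interior band: own non-overlap pixels within `width` of the strip
        dist = ndimage.distance_transform_edt(~strip)
        band = own & ~any_overlap & (dist <= width)
        s_vals = at15n_pct[strip]
        b_vals = at15n_pct[band]
        s_vals = s_vals[np.isfinite(s_vals)]
        b_vals = b_vals[np.isfinite(b_vals)]
        if s_vals.size < min_pixels or b_vals.size < min_pixels:
            continue
        stat = stats.mannwhitneyu(s_vals, b_vals, alternative="less")
        effect = float(s_vals.mean() - b_vals.mean())
        rows.append({
            "tile": idx, "n_strip": int(s_vals.size), "n_interior": int(b_vals.size),
            "strip_mean": float(s_vals.mean()), "interior_mean": float(b_vals.mean()),
            "effect": effect, "p_value": float(stat.pvalue),
            "flagged": bool(stat.pvalue < alpha),
        })
    return pd.DataFrame(
        rows, columns=["tile", "n_strip", "n_interior", "strip_mean",
                       "interior_mean", "effect", "p_value", "flagged"],
    )
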